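"""Self-contained synthetic experiments exercising the full method.

These drive the headline properties of the predictor at desk scale:

* :func:`learnability_experiment` — template-less two-stage prediction
  on a corpus with informative emissions must beat the analytic
  singlet Bayes baseline (the best any classifier can do from a single
  residue identity), demonstrating that the window encoding and the
  two-phase networks actually exploit context.
* :func:`similarity_bin_experiment` — mean test Q8 as a function of
  template similarity, one independently trained model per similarity
  level exactly as in similarity-subset benchmarking: better templates
  must yield better predictions, and high-similarity templates a large
  margin over template-less prediction.

Problem sizes are chosen for single-CPU runs in minutes; both functions
are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import EvalReport
from .model import SS8Results, TemplateSS8Model
from .network import TrainingRun
from .synthetic import (
    CorpusBundle,
    GeneratorConfig,
    generate_corpus,
    generate_template,
    singlet_bayes_rate,
)
from .templates import TemplateTrack

__all__ = [
    "learnability_experiment",
    "similarity_bin_experiment",
    "LearnabilityResult",
    "SimilarityBinResult",
]

#: Similarity levels probed by the binned experiment (0 = no template).
DEFAULT_SIMILARITY_LEVELS = (0.0, 0.25, 0.5, 0.75, 0.95)


def _default_runs() -> tuple[TrainingRun, TrainingRun]:
    # stage 2 is a much smaller network; it trains reliably with a hotter
    # learning rate, which it needs to escape the smoothed majority-state
    # optimum and preserve short segments (G, B, S)
    run1 = TrainingRun(epochs=100, early_stop_patience=10, lr_decay=0.985)
    run2 = TrainingRun(
        epochs=150, learning_rate=0.05, early_stop_patience=15, lr_decay=0.99
    )
    return run1, run2


@dataclass
class LearnabilityResult:
    """Outcome of the template-less learnability experiment."""

    test_q8: float
    test_sov8: float
    bayes_baseline: float  # singlet Bayes rate, percent
    report: EvalReport
    results: SS8Results

    @property
    def margin(self) -> float:
        """Points of Q8 above the singlet Bayes baseline."""
        return self.test_q8 - self.bayes_baseline


def learnability_experiment(
    seed: int = 0,
    n_chains: int = 200,
    chain_length: int = 100,
    run1: TrainingRun | None = None,
    run2: TrainingRun | None = None,
) -> LearnabilityResult:
    """Train the two-stage model without templates and compare its test
    Q8 against the analytic singlet Bayes baseline.

    Uses the generator defaults (sharp family-grouped emissions, noisy
    profiles) with fixed-length chains and a 5/1/1-proportioned chain
    split.
    """
    cfg = GeneratorConfig(
        n_chains=n_chains,
        length_range=(chain_length, chain_length),
        template_coverage=0.0,
        seed=seed,
    )
    bundle = generate_corpus(cfg)
    model = TemplateSS8Model.from_corpus(bundle)
    d1, d2 = _default_runs()
    # unstacked stage-2 training keeps the experiment to minutes; the
    # hot stage-2 learning rate is what preserves short segments here
    results = model.fit(
        run1=run1 or d1, run2=run2 or d2, seed=seed, stacked_stage2=False
    )
    report = results.evaluate()
    return LearnabilityResult(
        test_q8=report.overall_q8,
        test_sov8=report.overall_sov8,
        bayes_baseline=100.0 * singlet_bayes_rate(cfg),
        report=report,
        results=results,
    )


@dataclass
class SimilarityBinResult:
    """Outcome of the per-similarity-level training experiment."""

    levels: tuple[float, ...]
    q8_by_level: list[float]
    reports: list[EvalReport] = field(default_factory=list)

    @property
    def non_decreasing(self) -> bool:
        return all(b >= a for a, b in zip(self.q8_by_level, self.q8_by_level[1:]))

    @property
    def top_gain(self) -> float:
        """Q8 points the best-template level adds over template-less."""
        return self.q8_by_level[-1] - self.q8_by_level[0]


def similarity_bin_experiment(
    seed: int = 0,
    levels: tuple[float, ...] = DEFAULT_SIMILARITY_LEVELS,
    n_chains: int = 350,
    chain_length: int = 70,
    n_test: int = 60,
    n_val: int = 40,
    run1: TrainingRun | None = None,
    run2: TrainingRun | None = None,
) -> SimilarityBinResult:
    """Mean test Q8 per template-similarity level, one model per level.

    A single chain corpus is generated once; each similarity level then
    receives its own template tracks (full coverage, error rate
    1 - similarity) and its own independently trained model, exactly as
    in similarity-subset benchmarking. Keeping the chains, the split and
    the network seeds identical across levels pairs the comparison, so
    level differences reflect template information, not chain sampling.
    """
    base = GeneratorConfig(
        n_chains=n_chains,
        length_range=(chain_length, chain_length),
        template_coverage=0.0,
        seed=seed,
    )
    bundle = generate_corpus(base)
    ids = bundle.chain_ids
    test, val, train = (
        ids[:n_test],
        ids[n_test : n_test + n_val],
        ids[n_test + n_val :],
    )
    d1, d2 = _default_runs()

    q8s: list[float] = []
    reports: list[EvalReport] = []
    for li, sim in enumerate(levels):
        if sim > 0:
            tcfg = GeneratorConfig(
                n_chains=n_chains,
                length_range=base.length_range,
                template_similarity=sim,
                template_coverage=1.0,
                seed=seed,
            )
            trng = np.random.default_rng(seed * 1000 + li)
            templates = {
                c.chain_id: generate_template(c.ss8, tcfg, trng)
                for c in bundle.chains
            }
        else:
            templates = {
                c.chain_id: TemplateTrack.empty(len(c)) for c in bundle.chains
            }
        level_bundle = CorpusBundle(base, bundle.chains, bundle.profiles, templates)
        model = TemplateSS8Model.from_corpus(level_bundle)
        import dataclasses

        r1 = dataclasses.replace(run1 or d1, history=[])
        r2 = dataclasses.replace(run2 or d2, history=[])
        results = model.fit(
            train_ids=train, val_ids=val, test_ids=test,
            run1=r1, run2=r2, seed=seed, stacked_stage2=False,
        )
        report = results.evaluate(test)
        q8s.append(report.overall_q8)
        reports.append(report)
    return SimilarityBinResult(tuple(levels), q8s, reports)
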