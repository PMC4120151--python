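"""Model/Results interface tying the whole method together.

:class:`TemplateSS8Model` holds a labeled corpus (chains, profiles,
optional template tracks) and the method's configuration. ``fit()``
performs the full training procedure — context count tables from the
training chains only, potential scaling, stage-1 window encoding,
two-phase network training with early stopping on a validation set —
and returns a :class:`SS8Results` carrying everything needed to predict
and evaluate. ``cross_validate`` repeats the fit over rotating folds.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import N_SS8, SS8_ORDER, ss8_to_indices
from .context import (
    ContextCountTables,
    ContextScaler,
    OffsetConfig,
    PotentialTables,
    accumulate_counts,
    build_potentials,
    context_score_profile,
)
from .encoding import EncoderConfig, encode_chain_stage1, encode_chain_stage2
from .evaluation import EvalReport, evaluate_predictions, make_cv_folds
from .io import ChainRecord, ProfileMatrix
from .network import Network, NetworkSpec, TrainingRun, argmax_states, init_network, train_network
from .synthetic import CorpusBundle
from .templates import TemplateTrack

__all__ = [
    "TemplateSS8Model",
    "SS8Results",
    "PredictionResult",
    "CVResult",
    "cross_validate",
]

DEFAULT_HIDDEN_STAGE1 = 225
DEFAULT_HIDDEN_STAGE2 = 68


@dataclass
class PredictionResult:
    """Per-chain prediction: normalized L x 8 distribution + state string."""

    chain_id: str
    probs: np.ndarray
    states: str


class TemplateSS8Model:
    """Template-based 8-state secondary-structure predictor (untrained).

    Parameters
    ----------
    chains : list of ChainRecord
        Labeled corpus chains (``ss8`` required).
    profiles : dict
        chain_id -> ProfileMatrix, same lengths as the chains.
    templates : dict, optional
        chain_id -> TemplateTrack; missing/None entries mean the pure
        context-score path for that chain.
    encoder, offsets
        Window and context-offset configuration.
    hidden1, hidden2 : int
        Hidden-layer widths of the two phases.
    alpha, rt : float
        Pseudocount per (state, context) cell and the energy unit of the
        mean-force potentials.
    """

    def __init__(
        self,
        chains: list[ChainRecord],
        profiles: dict[str, ProfileMatrix],
        templates: dict[str, TemplateTrack] | None = None,
        *,
        encoder: EncoderConfig | None = None,
        offsets: OffsetConfig | None = None,
        hidden1: int = DEFAULT_HIDDEN_STAGE1,
        hidden2: int = DEFAULT_HIDDEN_STAGE2,
        alpha: float = 1.0,
        rt: float = 1.0,
    ):
        for chain in chains:
            if chain.ss8 is None:
                raise ValueError(f"{chain.chain_id}: training chain lacks ss8 labels")
            if chain.chain_id not in profiles:
                raise ValueError(f"{chain.chain_id}: no profile supplied")
            if len(profiles[chain.chain_id]) != len(chain):
                raise ValueError(f"{chain.chain_id}: profile length mismatch")
        self.chains = chains
        self.profiles = profiles
        self.templates = templates or {}
        self.encoder = encoder or EncoderConfig()
        self.offsets = offsets or OffsetConfig()
        self.hidden1 = hidden1
        self.hidden2 = hidden2
        self.alpha = alpha
        self.rt = rt
        self._by_id = {c.chain_id: c for c in chains}

    @classmethod
    def from_corpus(cls, bundle: CorpusBundle, **kwargs) -> "TemplateSS8Model":
        """Build a model from a :class:`CorpusBundle`."""
        return cls(bundle.chains, bundle.profiles, bundle.templates, **kwargs)

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def template_for(self, chain_id: str) -> TemplateTrack | None:
        track = self.templates.get(chain_id)
        if track is not None and not track.present.any():
            return None
        return track

    # -- fitting ----------------------------------------------------------

    def _default_split(
        self, seed: int
    ) -> tuple[list[str], list[str], list[str]]:
        """Seeded 5/1/1-proportioned chain split (train/validation/test)."""
        ids = list(self.chain_ids)
        rng = np.random.default_rng(seed)
        rng.shuffle(ids)
        n = len(ids)
        n_test = max(1, n // 7)
        n_val = max(1, n // 7)
        test = ids[:n_test]
        val = ids[n_test : n_test + n_val]
        train = ids[n_test + n_val :]
        return train, val, test

    def fit(
        self,
        train_ids: list[str] | None = None,
        val_ids: list[str] | None = None,
        test_ids: list[str] | None = None,
        run1: TrainingRun | None = None,
        run2: TrainingRun | None = None,
        seed: int = 0,
        class_weights: bool = False,
        stacked_stage2: bool = True,
    ) -> "SS8Results":
        """Train both phases and return the fitted results.

        Context count tables, the potential scaler, and both networks are
        derived from the training chains only; the validation chains
        drive early stopping. When no split is given, a seeded
        5/1/1-proportioned chain split is drawn.

        With ``stacked_stage2`` (default), the refinement network is
        trained on *out-of-sample* stage-1 outputs: the training chains
        are split in half, a temporary stage-1 network trained on each
        half predicts the other half, and those predictions form the
        stage-2 training inputs. This matches the probability
        distribution stage 2 will see at test time; feeding it the full
        network's own training-set outputs (which are overconfident)
        systematically degrades refinement.
        """
        if train_ids is None:
            train_ids, auto_val, auto_test = self._default_split(seed)
            val_ids = val_ids or auto_val
            test_ids = test_ids or auto_test
        if not train_ids or not val_ids:
            raise ValueError("need non-empty training and validation chain sets")
        run1 = run1 or TrainingRun()
        # the small refinement network needs a hotter learning rate to
        # escape the smoothed majority-state optimum
        run2 = run2 or TrainingRun(learning_rate=0.05, lr_decay=0.995)

        train_corpus = [
            (self._by_id[cid], self.profiles[cid]) for cid in train_ids
        ]
        tables = accumulate_counts(train_corpus, self.offsets)
        potentials = build_potentials(tables, rt=self.rt, alpha=self.alpha)

        raw_scores = {
            cid: context_score_profile(self._by_id[cid], potentials)
            for cid in set(train_ids) | set(val_ids)
        }
        scaler = ContextScaler().fit(
            np.vstack([raw_scores[cid] for cid in train_ids])
        )

        feat_cache: dict[str, np.ndarray] = {}

        def stage1_features(cid: str) -> np.ndarray:
            if cid not in feat_cache:
                chain = self._by_id[cid]
                feat_cache[cid] = encode_chain_stage1(
                    chain,
                    self.profiles[cid],
                    self.template_for(cid),
                    scaler.transform(raw_scores[cid]),
                    self.encoder,
                )
            return feat_cache[cid]

        def stage1_xy(ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
            feats, labels = [], []
            for cid in ids:
                chain = self._by_id[cid]
                mask = chain.determined_mask
                feats.append(stage1_features(cid)[mask])
                labels.append(ss8_to_indices(chain.ss8)[mask])
            return np.vstack(feats), np.concatenate(labels)

        X_train, y_train = stage1_xy(train_ids)
        X_val, y_val = stage1_xy(val_ids)

        weights = None
        if class_weights:
            freq = np.bincount(y_train, minlength=N_SS8).astype(float)
            weights = freq.sum() / np.maximum(freq, 1.0) / N_SS8

        net1 = init_network(
            NetworkSpec(self.encoder.stage1_row_width, self.hidden1, seed=seed)
        )
        train_network(
            net1, X_train, y_train, run1, X_val, y_val,
            seed=seed + 1, class_weights=weights,
        )

        def stage2_xy(
            ids: list[str], net_by_chain: dict | None = None
        ) -> tuple[np.ndarray, np.ndarray]:
            feats, labels = [], []
            for cid in ids:
                chain = self._by_id[cid]
                net = net_by_chain[cid] if net_by_chain else net1
                probs1 = net.predict_proba(stage1_features(cid))
                F2 = encode_chain_stage2(probs1, self.encoder)
                mask = chain.determined_mask
                feats.append(F2[mask])
                labels.append(ss8_to_indices(chain.ss8)[mask])
            return np.vstack(feats), np.concatenate(labels)

        # Stage-2 training inputs: out-of-sample stage-1 predictions from
        # two half-corpus networks, so the refinement network sees the
        # probability distribution it will face at test time rather than
        # the full network's overconfident training-set outputs.
        net_by_chain = None
        if stacked_stage2 and len(train_ids) >= 4:
            net_by_chain = {}
            halves = (list(train_ids[0::2]), list(train_ids[1::2]))
            for hi, half in enumerate(halves):
                Xh, yh = stage1_xy(half)
                net_h = init_network(
                    NetworkSpec(
                        self.encoder.stage1_row_width, self.hidden1, seed=seed + 10 + hi
                    )
                )
                train_network(
                    net_h, Xh, yh, dataclasses.replace(run1, history=[]),
                    X_val, y_val, seed=seed + 20 + hi, class_weights=weights,
                )
                for cid in halves[1 - hi]:
                    net_by_chain[cid] = net_h

        X2_train, y2_train = stage2_xy(train_ids, net_by_chain)
        X2_val, y2_val = stage2_xy(val_ids)
        net2 = init_network(
            NetworkSpec(self.encoder.stage2_row_width, self.hidden2, seed=seed + 2)
        )
        train_network(
            net2, X2_train, y2_train, run2, X2_val, y2_val,
            seed=seed + 3, class_weights=weights,
        )

        return SS8Results(
            model=self,
            encoder=self.encoder,
            tables=tables,
            potentials=potentials,
            scaler=scaler,
            net1=net1,
            net2=net2,
            run1=run1,
            run2=run2,
            train_ids=list(train_ids),
            val_ids=list(val_ids),
            test_ids=list(test_ids or []),
            seed=seed,
        )


@dataclass
class SS8Results:
    """A fitted predictor: potentials, scaler and both trained networks."""

    encoder: EncoderConfig
    potentials: PotentialTables
    scaler: ContextScaler
    net1: Network
    net2: Network
    run1: TrainingRun
    run2: TrainingRun
    model: TemplateSS8Model | None = None
    tables: ContextCountTables | None = None
    train_ids: list[str] = field(default_factory=list)
    val_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)
    seed: int = 0

    # -- prediction -------------------------------------------------------

    def stage1_probs(
        self,
        chain: ChainRecord,
        profile: ProfileMatrix,
        template: TemplateTrack | None = None,
    ) -> np.ndarray:
        raw = context_score_profile(chain, self.potentials)
        F1 = encode_chain_stage1(
            chain, profile, template, self.scaler.transform(raw), self.encoder
        )
        return self.net1.predict_proba(F1)

    def predict_chain(
        self,
        chain: ChainRecord,
        profile: ProfileMatrix,
        template: TemplateTrack | None = None,
    ) -> PredictionResult:
        """Run the full two-phase pipeline on one chain."""
        if len(profile) != len(chain):
            raise ValueError(f"{chain.chain_id}: profile length mismatch")
        probs1 = self.stage1_probs(chain, profile, template)
        F2 = encode_chain_stage2(probs1, self.encoder)
        probs2 = self.net2.predict_proba(F2)
        probs2 = probs2 / probs2.sum(axis=1, keepdims=True)
        states = "".join(SS8_ORDER[i] for i in argmax_states(probs2))
        return PredictionResult(chain.chain_id, probs2, states)

    def predict(self, chain_ids: list[str]) -> dict[str, PredictionResult]:
        """Predict corpus chains by id (model must be attached)."""
        if self.model is None:
            raise RuntimeError("results not attached to a corpus model")
        out = {}
        for cid in chain_ids:
            chain = self.model._by_id[cid]
            out[cid] = self.predict_chain(
                chain, self.model.profiles[cid], self.model.template_for(cid)
            )
        return out

    def evaluate(self, chain_ids: list[str] | None = None) -> EvalReport:
        """Score predictions against the corpus labels (default: test set)."""
        ids = chain_ids or self.test_ids
        if not ids:
            raise ValueError("no chains to evaluate")
        preds = self.predict(ids)
        return evaluate_predictions(
            [preds[cid].states for cid in ids],
            [self.model._by_id[cid].ss8 for cid in ids],
            [self.model._by_id[cid].determined_mask for cid in ids],
        )

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary."""
        buf = _io.StringIO()
        spec1, spec2 = self.net1.spec, self.net2.spec
        print("Template-based 8-state secondary structure predictor", file=buf)
        print("=" * 56, file=buf)
        print(
            f"stage 1: {spec1.input_width} -> {spec1.hidden_width} -> "
            f"{spec1.output_width}  ({self.net1.n_parameters:,} parameters)",
            file=buf,
        )
        print(
            f"stage 2: {spec2.input_width} -> {spec2.hidden_width} -> "
            f"{spec2.output_width}  ({self.net2.n_parameters:,} parameters)",
            file=buf,
        )
        print(
            f"window {self.encoder.window} "
            f"({self.encoder.per_residue_width} values per slot), "
            f"stage-2 window {self.encoder.stage2_window}",
            file=buf,
        )
        print(
            f"corpus split: {len(self.train_ids)} train / "
            f"{len(self.val_ids)} validation / {len(self.test_ids)} test chains",
            file=buf,
        )
        for name, run in (("stage 1", self.run1), ("stage 2", self.run2)):
            if run.history:
                last = run.history[-1]
                best = max(
                    (h.get("val_q8", np.nan) for h in run.history), default=np.nan
                )
                print(
                    f"{name}: {len(run.history)} epochs, final loss "
                    f"{last['loss']:.4f}, best validation Q8 {best:.2f}%",
                    file=buf,
                )
        return buf.getvalue()

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Persist the fitted predictor (no corpus) to one .npz archive."""
        meta = {
            "window": self.encoder.window,
            "stage2_window": self.encoder.stage2_window,
            "hidden1": self.net1.spec.hidden_width,
            "hidden2": self.net2.spec.hidden_width,
            "loss1": self.net1.spec.loss,
            "loss2": self.net2.spec.loss,
            "rt": self.potentials.rt,
            "alpha": self.potentials.alpha,
            "doublet_offsets": list(self.potentials.offsets.doublet_offsets),
            "triplet_pairs": [list(p) for p in self.potentials.offsets.triplet_offset_pairs],
            "seed": self.seed,
        }
        payload = {
            "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            "scaler_mean": self.scaler.mean,
            "scaler_std": self.scaler.std,
            "u_singlet": self.potentials.u_singlet,
            "net1_W1": self.net1.W1,
            "net1_b1": self.net1.b1,
            "net1_W2": self.net1.W2,
            "net1_b2": self.net1.b2,
            "net2_W1": self.net2.W1,
            "net2_b1": self.net2.b1,
            "net2_W2": self.net2.W2,
            "net2_b2": self.net2.b2,
        }
        for k, arr in self.potentials.u_doublet.items():
            payload[f"u_doublet_{k}"] = arr
        for (k1, k2), arr in self.potentials.u_triplet.items():
            payload[f"u_triplet_{k1}_{k2}"] = arr
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path) -> "SS8Results":
        """Load a predictor saved with :meth:`save` (corpus-free)."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            offsets = OffsetConfig(
                doublet_offsets=tuple(meta["doublet_offsets"]),
                triplet_offset_pairs=tuple(tuple(p) for p in meta["triplet_pairs"]),
            )
            encoder = EncoderConfig(meta["window"], meta["stage2_window"])
            potentials = PotentialTables(
                offsets=offsets,
                u_singlet=data["u_singlet"],
                u_doublet={k: data[f"u_doublet_{k}"] for k in offsets.doublet_offsets},
                u_triplet={
                    p: data[f"u_triplet_{p[0]}_{p[1]}"]
                    for p in offsets.triplet_offset_pairs
                },
                rt=meta["rt"],
                alpha=meta["alpha"],
            )
            scaler = ContextScaler(mean=data["scaler_mean"], std=data["scaler_std"])
            net1 = init_network(
                NetworkSpec(
                    encoder.stage1_row_width, meta["hidden1"], loss=meta["loss1"]
                )
            )
            net1.W1, net1.b1 = data["net1_W1"], data["net1_b1"]
            net1.W2, net1.b2 = data["net1_W2"], data["net1_b2"]
            net2 = init_network(
                NetworkSpec(
                    encoder.stage2_row_width, meta["hidden2"], loss=meta["loss2"]
                )
            )
            net2.W1, net2.b1 = data["net2_W1"], data["net2_b1"]
            net2.W2, net2.b2 = data["net2_W2"], data["net2_b2"]
        return cls(
            encoder=encoder,
            potentials=potentials,
            scaler=scaler,
            net1=net1,
            net2=net2,
            run1=TrainingRun(),
            run2=TrainingRun(),
            seed=int(meta["seed"]),
        )


# --------------------------------------------------------------------------
# Cross-validation
# --------------------------------------------------------------------------


@dataclass
class CVResult:
    """Per-fold reports and their average."""

    fold_reports: list[EvalReport]
    fold_results: list[SS8Results]

    @property
    def mean_q8(self) -> float:
        return float(np.mean([r.overall_q8 for r in self.fold_reports]))

    @property
    def mean_sov8(self) -> float:
        return float(np.mean([r.overall_sov8 for r in self.fold_reports]))

    def table(self) -> pd.DataFrame:
        rows = []
        for i, rep in enumerate(self.fold_reports):
            rows.append(
                {"fold": str(i), "q8": rep.overall_q8, "sov8": rep.overall_sov8}
            )
        rows.append({"fold": "average", "q8": self.mean_q8, "sov8": self.mean_sov8})
        return pd.DataFrame(rows)


def cross_validate(
    model: TemplateSS8Model,
    n_folds: int = 7,
    seed: int = 0,
    run1: TrainingRun | None = None,
    run2: TrainingRun | None = None,
) -> CVResult:
    """Chain-level N-fold cross-validation (5 train / 1 validation / 1 test
    role split per round at the default 7 folds).

    Context tables and networks are re-derived per round from that
    round's training chains, so test chains never contribute counts to
    the statistics used for their own prediction. The headline score is
    the arithmetic mean of the per-round test scores.
    """
    folds = make_cv_folds(model.chain_ids, n_folds=n_folds, seed=seed)
    reports, fits = [], []
    for held in range(n_folds):
        train, val, test = folds.roles(held)
        r1 = dataclasses.replace(run1, history=[]) if run1 is not None else None
        r2 = dataclasses.replace(run2, history=[]) if run2 is not None else None
        res = model.fit(
            train_ids=train, val_ids=val, test_ids=test,
            run1=r1, run2=r2, seed=seed + held,
        )
        reports.append(res.evaluate(test))
        fits.append(res)
    return CVResult(reports, fits)
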