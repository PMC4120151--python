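"""Q8 and SOV8 scoring, cross-validation folds, similarity-binned reports.

Q8 is the percentage of residues whose predicted 8-state label matches
the reference; per-state Q uses the reference-state rows of the 8 x 8
confusion matrix. SOV8 is the 1999-revision segment-overlap score with
each of the eight states as its own segment class: per overlapping
segment pair,

    score += len(s_ref) * (minov + delta) / maxov,
    delta  = min(maxov - minov, minov, len(s_ref)//2, len(s_pred)//2),

normalized over reference segment lengths including segments with no
overlapping partner. SOV is less sensitive than Q8 to single-residue
errors and rewards getting segments roughly right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabets import N_SS8, SS8_INDEX, SS8_ORDER, ss8_to_indices

__all__ = [
    "EvalReport",
    "FoldAssignment",
    "evaluate_predictions",
    "q8_score",
    "sov8_score",
    "make_cv_folds",
    "similarity_binned_eval",
    "plot_similarity_bins",
]

#: Column order used by report tables (helix types first, strand, bridge,
#: bend, turn, coil, then the pooled score).
TABLE_STATE_ORDER = "GHIEBSTC"


@dataclass
class EvalReport:
    """Scores for one prediction set.

    ``per_state_q``/``per_state_sov`` are in canonical state order with
    NaN marking states absent from the reference (undefined scores,
    displayed as 0.00 in tables but excluded from macro averages).
    """

    confusion: np.ndarray = field(default_factory=lambda: np.zeros((N_SS8, N_SS8)))
    per_state_q: np.ndarray = field(default_factory=lambda: np.full(N_SS8, np.nan))
    overall_q8: float = np.nan
    per_state_sov: np.ndarray = field(default_factory=lambda: np.full(N_SS8, np.nan))
    overall_sov8: float = np.nan
    n_residues: int = 0

    def to_table(self) -> pd.DataFrame:
        """Two-row table (Q8, SOV8) over states G,H,I,E,B,S,T,C + Overall."""
        cols = list(TABLE_STATE_ORDER) + ["Overall"]
        rows = {}
        for name, per_state, overall in (
            ("Q8", self.per_state_q, self.overall_q8),
            ("SOV8", self.per_state_sov, self.overall_sov8),
        ):
            vals = [per_state[SS8_INDEX[s]] for s in TABLE_STATE_ORDER] + [overall]
            rows[name] = [0.0 if np.isnan(v) else round(float(v), 2) for v in vals]
        return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def _check_pair(pred: str, truth: str) -> None:
    if len(pred) != len(truth):
        raise ValueError(
            f"prediction length {len(pred)} != reference length {len(truth)}"
        )


def _segments(states: np.ndarray, keep: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs (state, start, stop) over kept positions.

    Excluded (undetermined) positions break segments and belong to none.
    """
    segs = []
    start = None
    cur = -1
    for i, (s, k) in enumerate(zip(states, keep)):
        if not k or s != cur:
            if start is not None:
                segs.append((cur, start, i))
            start = i if k else None
            cur = s if k else -1
    if start is not None:
        segs.append((cur, start, len(states)))
    return segs


def evaluate_predictions(
    preds: list[str],
    truths: list[str],
    masks: list[np.ndarray] | None = None,
) -> EvalReport:
    """Compute the full report (Q8 parts and SOV8 parts) for a chain set.

    ``masks`` optionally flags determined residues per chain; masked-out
    positions are excluded from both scores and break SOV segments.
    """
    if len(preds) != len(truths):
        raise ValueError("different numbers of predicted and reference chains")
    report = EvalReport()
    sov_num = np.zeros(N_SS8)
    sov_den = np.zeros(N_SS8)

    for ci, (pred, truth) in enumerate(zip(preds, truths)):
        _check_pair(pred, truth)
        p = ss8_to_indices(pred)
        t = ss8_to_indices(truth)
        keep = (
            np.asarray(masks[ci], dtype=bool)
            if masks is not None
            else np.ones(len(truth), dtype=bool)
        )
        np.add.at(report.confusion, (t[keep], p[keep]), 1.0)

        tsegs = _segments(t, keep)
        psegs = _segments(p, keep)
        for state in range(N_SS8):
            ts = [s for s in tsegs if s[0] == state]
            ps = [s for s in psegs if s[0] == state]
            for _, t0, t1 in ts:
                len1 = t1 - t0
                overlapped = False
                for _, p0, p1 in ps:
                    minov = min(t1, p1) - max(t0, p0)
                    if minov <= 0:
                        continue
                    overlapped = True
                    len2 = p1 - p0
                    maxov = max(t1, p1) - min(t0, p0)
                    delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                    sov_num[state] += len1 * (minov + delta) / maxov
                    sov_den[state] += len1
                if not overlapped:
                    sov_den[state] += len1

    total = report.confusion.sum()
    report.n_residues = int(total)
    truth_counts = report.confusion.sum(axis=1)
    correct = np.diag(report.confusion)
    with np.errstate(invalid="ignore", divide="ignore"):
        report.per_state_q = np.where(
            truth_counts > 0, 100.0 * correct / truth_counts, np.nan
        )
        report.overall_q8 = float(100.0 * correct.sum() / total) if total else np.nan
        report.per_state_sov = np.where(
            sov_den > 0, 100.0 * sov_num / sov_den, np.nan
        )
    den = sov_den.sum()
    report.overall_sov8 = float(100.0 * sov_num.sum() / den) if den else np.nan
    return report


def q8_score(
    preds: list[str], truths: list[str], masks: list[np.ndarray] | None = None
) -> EvalReport:
    """Report with the Q parts filled (SOV parts computed alongside)."""
    return evaluate_predictions(preds, truths, masks)


def sov8_score(
    preds: list[str], truths: list[str], masks: list[np.ndarray] | None = None
) -> EvalReport:
    """Report with the SOV parts filled (Q parts computed alongside)."""
    return evaluate_predictions(preds, truths, masks)


# --------------------------------------------------------------------------
# Cross-validation bookkeeping
# --------------------------------------------------------------------------


@dataclass
class FoldAssignment:
    """Chain-level random partition into folds of near-equal size.

    Per evaluation round with held fold h: fold h is the test set, fold
    (h+1) mod n the validation set, the remaining n-2 folds train.
    """

    fold_of_chain: dict[str, int]
    n_folds: int

    def chains_in_fold(self, fold: int) -> list[str]:
        return [c for c, f in self.fold_of_chain.items() if f == fold]

    def roles(self, held: int) -> tuple[list[str], list[str], list[str]]:
        """(train_ids, validation_ids, test_ids) for one round."""
        test = self.chains_in_fold(held)
        val = self.chains_in_fold((held + 1) % self.n_folds)
        train = [
            c
            for c, f in self.fold_of_chain.items()
            if f != held and f != (held + 1) % self.n_folds
        ]
        return train, val, test


def make_cv_folds(
    chain_ids: list[str], n_folds: int = 7, seed: int = 0
) -> FoldAssignment:
    """Seeded uniform random chain-level partition into ``n_folds`` folds.

    Fold sizes differ by at most one chain.
    """
    if len(chain_ids) < n_folds:
        raise ValueError(f"need at least {n_folds} chains, got {len(chain_ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(chain_ids))
    assignment = {}
    for pos, idx in enumerate(order):
        assignment[chain_ids[idx]] = pos % n_folds
    return FoldAssignment(assignment, n_folds)


# --------------------------------------------------------------------------
# Similarity-binned reporting
# --------------------------------------------------------------------------


def similarity_binned_eval(
    reports: dict[str, EvalReport],
    similarities: dict[str, float],
    bins: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Mean scores per template-similarity bin.

    ``similarities`` holds each chain's selected-template similarity
    (0 when no template was used). Bins are half-open intervals
    (lo, hi]; chains with similarity exactly 0 form their own
    "none" bin regardless of the interval list. Per-state means skip
    chains where that state is undefined.
    """
    bins = bins or [(0.0, 0.10), (0.10, 0.20), (0.20, 0.40), (0.40, 0.70), (0.70, 0.95)]
    for (lo1, hi1) in bins:
        if hi1 <= lo1:
            raise ValueError(f"empty bin ({lo1}, {hi1}]")
    for i, (lo1, hi1) in enumerate(bins):
        for lo2, hi2 in bins[i + 1 :]:
            if max(lo1, lo2) < min(hi1, hi2):
                raise ValueError("overlapping similarity bins")

    def bin_label(sim: float) -> str | None:
        if sim == 0.0:
            return "none"
        for lo, hi in bins:
            if lo < sim <= hi:
                return f"({lo * 100:g}, {hi * 100:g}]"
        return None

    labels = ["none"] + [f"({lo * 100:g}, {hi * 100:g}]" for lo, hi in bins]
    grouped: dict[str, list[EvalReport]] = {lab: [] for lab in labels}
    for cid, rep in reports.items():
        lab = bin_label(similarities.get(cid, 0.0))
        if lab is not None:
            grouped[lab].append(rep)

    rows = []
    for lab in labels:
        reps = grouped[lab]
        row: dict[str, object] = {"bin": lab, "n_chains": len(reps)}
        if reps:
            q = np.array([r.overall_q8 for r in reps])
            row["q8"] = float(np.nanmean(q))
            per = np.array([r.per_state_q for r in reps])
            counts = (~np.isnan(per)).sum(axis=0)
            sums = np.nansum(per, axis=0)
            means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
            for s in TABLE_STATE_ORDER:
                row[f"q_{s}"] = float(means[SS8_INDEX[s]])
        else:
            row["q8"] = np.nan
            for s in TABLE_STATE_ORDER:
                row[f"q_{s}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def plot_similarity_bins(table: pd.DataFrame, path=None):
    """Bar chart of mean Q8 per similarity bin (first bar: template-less)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(table["bin"], table["q8"], color="steelblue")
    ax.set_xlabel("template sequence similarity (%)")
    ax.set_ylabel("mean Q8 (%)")
    ax.set_ylim(0, 100)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
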