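"""Context-based mean-force potentials.

Secondary-structure formation is strongly locally dependent: hydrogen
bonds between residues at positions i and i+3 / i+4 / i+5 drive 3-10,
alpha and pi helices, and strand residues pair at alternating offsets.
This module extracts PSSM-weighted singlet, doublet and triplet
statistics from a labeled corpus and converts them, via the
inverse-Boltzmann relation, into pseudo-energies

    U(C, ctx) = -RT ln( P_obs(C | ctx) / P_ref(C | ctx') )

where the reference conditions on strictly less of the context
(the conditional-probability reference approach). The resulting scores
quantify how favourable each of the 8 states is for a residue given its
sequence neighbours at fixed offsets, and serve as fallback structure
features where no homology template covers a residue.

Counts are *weighted*: each position contributes its profile frequency
(product of frequencies for doublets/triplets) rather than a hard count,
so the statistics integrate evolutionary information.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alphabets import AA_INDEX, N_AA, N_SS8, SS8_INDEX, seq_to_indices, ss8_to_indices
from .io import ChainRecord, FormatError, ProfileMatrix

__all__ = [
    "OffsetConfig",
    "ContextCountTables",
    "PotentialTables",
    "ContextScaler",
    "accumulate_counts",
    "observed_probability",
    "reference_probability",
    "potential",
    "build_potentials",
    "context_score_profile",
    "save_tables",
    "load_tables",
]


def _default_pairs(offsets: tuple[int, ...]) -> tuple[tuple[int, int], ...]:
    return tuple(
        (k1, k2) for k1, k2 in itertools.combinations(sorted(offsets), 2)
    )


DEFAULT_DOUBLET_OFFSETS: tuple[int, ...] = (-5, -4, -3, -2, -1, 1, 2, 3, 4, 5)


@dataclass(frozen=True)
class OffsetConfig:
    """Which relative positions enter the doublet/triplet statistics.

    Defaults cover k in {-5..-1, 1..5} (spanning the i+3/i+4/i+5
    helix hydrogen-bonding offsets and short-range strand alternation)
    and all 45 ordered pairs thereof. Triplet potentials factor through
    doublet probabilities at both component offsets, so every triplet
    pair's components must appear in ``doublet_offsets``.
    """

    doublet_offsets: tuple[int, ...] = DEFAULT_DOUBLET_OFFSETS
    triplet_offset_pairs: tuple[tuple[int, int], ...] = field(
        default_factory=lambda: _default_pairs(DEFAULT_DOUBLET_OFFSETS)
    )

    def __post_init__(self) -> None:
        if 0 in self.doublet_offsets:
            raise ValueError("offset 0 is not a context offset")
        if len(set(self.doublet_offsets)) != len(self.doublet_offsets):
            raise ValueError("duplicate doublet offsets")
        for k1, k2 in self.triplet_offset_pairs:
            if k1 >= k2 or k1 == 0 or k2 == 0:
                raise ValueError(f"triplet pair ({k1},{k2}) must satisfy k1 < k2, both nonzero")
            if k1 not in self.doublet_offsets or k2 not in self.doublet_offsets:
                raise ValueError(
                    f"triplet pair ({k1},{k2}) needs both offsets in doublet_offsets"
                )


@dataclass
class ContextCountTables:
    """Weighted observed counts, state-conditioned.

    Unconditioned counts are the sums over the state axis, so the
    consistency invariant (state-marginals reproduce context totals)
    holds by construction.
    """

    offsets: OffsetConfig
    singlet_state: np.ndarray  # (8, 20)
    doublet_state: dict[int, np.ndarray]  # k -> (8, 20, 20): [c, center, neighbor]
    triplet_state: dict[tuple[int, int], np.ndarray]  # (8, 20, 20, 20)
    total_weight: float

    @property
    def n_singlet(self) -> np.ndarray:
        return self.singlet_state.sum(axis=0)

    def n_doublet(self, k: int) -> np.ndarray:
        return self.doublet_state[k].sum(axis=0)

    def n_triplet(self, pair: tuple[int, int]) -> np.ndarray:
        return self.triplet_state[pair].sum(axis=0)

    @classmethod
    def zeros(cls, offsets: OffsetConfig) -> "ContextCountTables":
        return cls(
            offsets=offsets,
            singlet_state=np.zeros((N_SS8, N_AA)),
            doublet_state={k: np.zeros((N_SS8, N_AA, N_AA)) for k in offsets.doublet_offsets},
            triplet_state={
                p: np.zeros((N_SS8, N_AA, N_AA, N_AA)) for p in offsets.triplet_offset_pairs
            },
            total_weight=0.0,
        )


def _pair_slices(L: int, k: int) -> tuple[slice, slice]:
    """Index slices (center j, neighbor j+k) covering all valid j."""
    if k > 0:
        return slice(0, L - k), slice(k, L)
    return slice(-k, L), slice(0, L + k)


def _triple_bounds(L: int, k1: int, k2: int) -> tuple[int, int]:
    lo = max(0, -k1, -k2)
    hi = min(L, L - k1, L - k2)
    return lo, max(lo, hi)


def accumulate_counts(
    corpus: list[tuple[ChainRecord, ProfileMatrix]],
    offsets: OffsetConfig | None = None,
) -> ContextCountTables:
    """Accumulate PSSM-weighted context counts over a labeled corpus.

    For every position j with determined structure, the singlet count of
    residue type a receives the profile frequency P_j(a); a doublet at
    offset k receives the product P_j(a) * P_{j+k}(b) provided both
    positions lie inside the chain and are determined, and similarly for
    triplets. State-conditioned tables restrict the sum to positions
    whose label (at the center position j) equals the state.
    """
    offsets = offsets or OffsetConfig()
    tables = ContextCountTables.zeros(offsets)
    for chain, profile in corpus:
        if chain.ss8 is None:
            raise ValueError(f"{chain.chain_id}: corpus chain lacks ss8 labels")
        L = len(chain)
        if len(profile) != L:
            raise ValueError(
                f"{chain.chain_id}: profile length {len(profile)} != chain length {L}"
            )
        P = profile.freqs
        s = ss8_to_indices(chain.ss8)
        det = chain.determined_mask

        for c in range(N_SS8):
            sel = det & (s == c)
            if sel.any():
                tables.singlet_state[c] += P[sel].sum(axis=0)
        tables.total_weight += float(det.sum())

        for k in offsets.doublet_offsets:
            if abs(k) >= L:
                continue
            jc, jn = _pair_slices(L, k)
            mask = det[jc] & det[jn]
            sj = s[jc]
            Pc, Pn = P[jc], P[jn]
            for c in range(N_SS8):
                idx = np.flatnonzero(mask & (sj == c))
                if idx.size:
                    tables.doublet_state[k][c] += np.einsum(
                        "ja,jb->ab", Pc[idx], Pn[idx]
                    )

        for pair in offsets.triplet_offset_pairs:
            k1, k2 = pair
            lo, hi = _triple_bounds(L, k1, k2)
            if hi <= lo:
                continue
            j = np.arange(lo, hi)
            mask = det[j] & det[j + k1] & det[j + k2]
            sj = s[j]
            Pc, P1, P2 = P[j], P[j + k1], P[j + k2]
            for c in range(N_SS8):
                idx = np.flatnonzero(mask & (sj == c))
                if idx.size:
                    tables.triplet_state[pair][c] += np.einsum(
                        "ja,jb,jc->abc", Pc[idx], P1[idx], P2[idx], optimize=True
                    )
    return tables


# --------------------------------------------------------------------------
# Probabilities (scalar API; pseudocount-regularized)
# --------------------------------------------------------------------------


def _ctx_indices(context: tuple) -> tuple:
    """Normalize a context descriptor to (kind, offsets, residue indices)."""
    kind = context[0]
    if kind == "singlet":
        (_, r) = context
        return "singlet", (), (AA_INDEX[r],)
    if kind == "doublet":
        (_, k, r, rn) = context
        return "doublet", (k,), (AA_INDEX[r], AA_INDEX[rn])
    if kind == "triplet":
        (_, pair, r, r1, r2) = context
        return "triplet", tuple(pair), (AA_INDEX[r], AA_INDEX[r1], AA_INDEX[r2])
    raise ValueError(f"unknown context kind {kind!r}")


def observed_probability(
    tables: ContextCountTables, state: str, context: tuple, alpha: float = 1.0
) -> float:
    """P_obs(state | context) with pseudocount ``alpha`` per state cell.

    ``context`` is ("singlet", R), ("doublet", k, R, R_k) or
    ("triplet", (k1, k2), R, R_k1, R_k2), with residues as letters.
    """
    c = SS8_INDEX[state]
    kind, offs, res = _ctx_indices(context)
    if kind == "singlet":
        num = tables.singlet_state[c, res[0]]
        den = tables.n_singlet[res[0]]
    elif kind == "doublet":
        num = tables.doublet_state[offs[0]][c, res[0], res[1]]
        den = tables.n_doublet(offs[0])[res[0], res[1]]
    else:
        num = tables.triplet_state[offs][c, res[0], res[1], res[2]]
        den = tables.n_triplet(offs)[res[0], res[1], res[2]]
    return float((num + alpha) / (den + N_SS8 * alpha))


def reference_probability(
    tables: ContextCountTables, state: str, context: tuple, alpha: float = 1.0
) -> float:
    """P_ref(state | context): the center residue is marginalized out.

    The singlet reference is the corpus-wide state frequency (independent
    of the residue argument); the doublet/triplet references condition on
    the neighbor residue(s) only.
    """
    c = SS8_INDEX[state]
    kind, offs, res = _ctx_indices(context)
    if kind == "singlet":
        num = tables.singlet_state[c].sum()
        den = tables.n_singlet.sum()
    elif kind == "doublet":
        marg = tables.doublet_state[offs[0]].sum(axis=1)  # (8, neighbor)
        num = marg[c, res[1]]
        den = marg.sum(axis=0)[res[1]]
    else:
        marg = tables.triplet_state[offs].sum(axis=1)  # (8, n1, n2)
        num = marg[c, res[1], res[2]]
        den = marg.sum(axis=0)[res[1], res[2]]
    return float((num + alpha) / (den + N_SS8 * alpha))


def potential(
    tables: ContextCountTables,
    state: str,
    context: tuple,
    rt: float = 1.0,
    alpha: float = 1.0,
) -> float:
    """Mean-force potential U(state, context) in units of RT.

    Singlet:  -RT ln( P_obs(C|R) / P_ref(C|R) ).
    Doublet:  -RT ln( P_obs(C|RR+k) P_ref(C|R) / [P_ref(C|RR+k) P_obs(C|R)] ).
    Triplet:  -RT ln of the 8-factor ratio chaining both doublet levels.
    Negative values mean the context favours the state.
    """
    kind, offs, res = _ctx_indices(context)
    po = observed_probability(tables, state, context, alpha)
    pr = reference_probability(tables, state, context, alpha)
    if kind == "singlet":
        return float(-rt * np.log(po / pr))
    r = context[2]
    singlet = ("singlet", r)
    po_s = observed_probability(tables, state, singlet, alpha)
    pr_s = reference_probability(tables, state, singlet, alpha)
    if kind == "doublet":
        return float(-rt * np.log((po * pr_s) / (pr * po_s)))
    (_, (k1, k2), rc, r1, r2) = context
    d1 = ("doublet", k1, rc, r1)
    d2 = ("doublet", k2, rc, r2)
    po_1 = observed_probability(tables, state, d1, alpha)
    pr_1 = reference_probability(tables, state, d1, alpha)
    po_2 = observed_probability(tables, state, d2, alpha)
    pr_2 = reference_probability(tables, state, d2, alpha)
    num = po * pr_2 * pr_1 * po_s
    den = pr * po_2 * po_1 * pr_s
    return float(-rt * np.log(num / den))


# --------------------------------------------------------------------------
# Vectorized potential tables
# --------------------------------------------------------------------------


def _pad_mean(arr: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Append, along each residue axis, an extra slot holding the axis mean.

    Slot index 20 stands for an unknown residue ('X'): its potential is
    the average over the 20 canonical types.
    """
    out = arr
    for ax in axes:
        mean = out.mean(axis=ax, keepdims=True)
        out = np.concatenate([out, mean], axis=ax)
    return out


@dataclass
class PotentialTables:
    """Precomputed mean-force potentials for fast per-chain scoring.

    Residue axes have width 21: index 20 is the unknown-residue ('X')
    slot, holding the mean over canonical types.
    """

    offsets: OffsetConfig
    u_singlet: np.ndarray  # (8, 21)
    u_doublet: dict[int, np.ndarray]  # (8, 21, 21)
    u_triplet: dict[tuple[int, int], np.ndarray]  # (8, 21, 21, 21)
    rt: float = 1.0
    alpha: float = 1.0


def build_potentials(
    tables: ContextCountTables,
    rt: float = 1.0,
    alpha: float = 1.0,
    pseudocount: str = "background",
) -> PotentialTables:
    """Convert count tables into dense potential tables (all contexts at once).

    ``pseudocount`` selects the regularizer, with total strength
    ``8 * alpha`` per context:

    * ``"background"`` (default): shrink each conditional toward the
      corpus-wide state distribution. Under label-sequence independence
      this estimator is unbiased at every context level, so potentials
      vanish as the corpus grows — a uniform pseudocount instead drags
      small-count (doublet/triplet) cells toward 1/8 harder than the
      large-count singlet cells and leaves a spurious residual energy
      for rare states.
    * ``"uniform"``: the plain additive-alpha rule
      (N(C,ctx)+alpha)/(N(ctx)+8*alpha).
    """
    if pseudocount not in ("background", "uniform"):
        raise ValueError(f"unknown pseudocount mode {pseudocount!r}")
    a = alpha
    A8 = N_SS8 * a

    N_cs = tables.singlet_state  # (8,20)
    n_c = N_cs.sum(axis=1)
    if pseudocount == "background":
        q = (n_c + a) / (n_c.sum() + A8)  # corpus state distribution, (8,)
    else:
        q = np.full(N_SS8, 1.0 / N_SS8)
    prior = A8 * q  # per-state additive mass, sums to 8*alpha

    def _lp(counts: np.ndarray) -> np.ndarray:
        """log P(state | context) with shrinkage; state axis first."""
        shape = (N_SS8,) + (1,) * (counts.ndim - 1)
        return np.log(counts + prior.reshape(shape)) - np.log(
            counts.sum(axis=0) + A8
        )

    lp_obs_s = _lp(N_cs)  # (8,20)
    lp_ref_s = _lp(n_c[:, None])[:, 0]  # (8,)
    u_singlet = -rt * (lp_obs_s - lp_ref_s[:, None])

    lp_obs_d: dict[int, np.ndarray] = {}
    lp_ref_d: dict[int, np.ndarray] = {}
    u_doublet: dict[int, np.ndarray] = {}
    for k, D in tables.doublet_state.items():
        lp_obs = _lp(D)  # (8, a, b)
        lp_ref = _lp(D.sum(axis=1))  # (8, b): center marginalized
        lp_obs_d[k], lp_ref_d[k] = lp_obs, lp_ref
        u_doublet[k] = -rt * (
            lp_obs + lp_ref_s[:, None, None] - lp_ref[:, None, :] - lp_obs_s[:, :, None]
        )

    u_triplet: dict[tuple[int, int], np.ndarray] = {}
    for pair, T in tables.triplet_state.items():
        k1, k2 = pair
        lp_obs = _lp(T)  # (8, a, b1, b2)
        lp_ref = _lp(T.sum(axis=1))  # (8, b1, b2)
        u_triplet[pair] = -rt * (
            lp_obs
            + lp_ref_d[k2][:, None, None, :]
            + lp_ref_d[k1][:, None, :, None]
            + lp_obs_s[:, :, None, None]
            - lp_ref[:, None, :, :]
            - lp_obs_d[k2][:, :, None, :]
            - lp_obs_d[k1][:, :, :, None]
            - lp_ref_s[:, None, None, None]
        )

    return PotentialTables(
        offsets=tables.offsets,
        u_singlet=_pad_mean(u_singlet, (1,)),
        u_doublet={k: _pad_mean(u, (1, 2)) for k, u in u_doublet.items()},
        u_triplet={p: _pad_mean(u, (1, 2, 3)) for p, u in u_triplet.items()},
        rt=rt,
        alpha=alpha,
    )


def context_score_profile(
    chain: ChainRecord, potentials: PotentialTables
) -> np.ndarray:
    """Total context pseudo-energy profile, an L x 8 matrix.

    Row i holds U(C, R_i) = U_singlet + sum_k U_doublet + sum_pairs
    U_triplet for the residue at i adopting each of the 8 states
    (canonical order). Offsets that fall outside the chain simply
    contribute nothing. Labels are not needed: scoring uses the actual
    residue identities of the target sequence (unknowns use the averaged
    'X' slot).
    """
    L = len(chain)
    a = seq_to_indices(chain.sequence)
    a = np.where(a < 0, N_AA, a)  # X -> averaged slot
    scores = potentials.u_singlet[:, a].T.copy()  # (L, 8)

    for k, U in potentials.u_doublet.items():
        if abs(k) >= L:
            continue
        jc, jn = _pair_slices(L, k)
        scores[jc] += U[:, a[jc], a[jn]].T

    for (k1, k2), U in potentials.u_triplet.items():
        lo, hi = _triple_bounds(L, k1, k2)
        if hi <= lo:
            continue
        j = np.arange(lo, hi)
        scores[lo:hi] += U[:, a[j], a[j + k1], a[j + k2]].T

    return scores


@dataclass
class ContextScaler:
    """Maps raw pseudo-energies onto the bounded [0, 1] feature range.

    Z-scores per state against training-corpus statistics, clips at
    +/- 3 standard deviations and rescales linearly, so one feature unit
    spans six standard deviations of the training energy distribution.
    """

    mean: np.ndarray | None = None  # (8,)
    std: np.ndarray | None = None  # (8,)
    clip: float = 3.0

    def fit(self, score_rows: np.ndarray) -> "ContextScaler":
        score_rows = np.asarray(score_rows, dtype=float)
        self.mean = score_rows.mean(axis=0)
        std = score_rows.std(axis=0)
        self.std = np.where(std > 0, std, 1.0)
        return self

    def transform(self, scores: np.ndarray) -> np.ndarray:
        if self.mean is None:
            raise RuntimeError("ContextScaler not fitted")
        z = (scores - self.mean) / self.std
        return (np.clip(z, -self.clip, self.clip) + self.clip) / (2 * self.clip)


# --------------------------------------------------------------------------
# Persistence
# --------------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_tables(tables: ContextCountTables, path) -> None:
    """Persist count tables (with their offset config) to an .npz archive."""
    payload = {
        "version": np.array([_FORMAT_VERSION]),
        "total_weight": np.array([tables.total_weight]),
        "doublet_offsets": np.array(tables.offsets.doublet_offsets, dtype=np.int64),
        "triplet_pairs": np.array(
            tables.offsets.triplet_offset_pairs, dtype=np.int64
        ).reshape(-1, 2),
        "singlet_state": tables.singlet_state,
    }
    for k, arr in tables.doublet_state.items():
        payload[f"doublet_{k}"] = arr
    for (k1, k2), arr in tables.triplet_state.items():
        payload[f"triplet_{k1}_{k2}"] = arr
    np.savez_compressed(path, **payload)


def load_tables(path) -> ContextCountTables:
    """Load count tables written by :func:`save_tables`."""
    with np.load(path) as data:
        if int(data["version"][0]) != _FORMAT_VERSION:
            raise FormatError(f"{path}: unsupported table archive version")
        offs = OffsetConfig(
            doublet_offsets=tuple(int(k) for k in data["doublet_offsets"]),
            triplet_offset_pairs=tuple(
                (int(k1), int(k2)) for k1, k2 in data["triplet_pairs"]
            ),
        )
        return ContextCountTables(
            offsets=offs,
            singlet_state=data["singlet_state"],
            doublet_state={k: data[f"doublet_{k}"] for k in offs.doublet_offsets},
            triplet_state={
                p: data[f"triplet_{p[0]}_{p[1]}"] for p in offs.triplet_offset_pairs
            },
            total_weight=float(data["total_weight"][0]),
        )
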