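"""Synthetic labeled corpora for desk-scale training and testing.

Real training corpora (PISCES-culled PDB chain sets with PSI-BLAST
profiles and DSSP labels) require large downloads; this module emulates
their statistical structure so every other module can be exercised
end-to-end:

* 8-state label strings follow a first-order Markov chain whose
  self-loop mass sets per-state mean segment lengths (helices long,
  bridges single-residue), mirroring the strong local dependency of
  secondary structure;
* residues are drawn from state-conditioned emission distributions
  whose sharpness sets how much the sequence alone reveals the state;
* profiles are the true state's emission row perturbed by Dirichlet
  noise, emulating PSI-BLAST frequency profiles;
* template tracks cover a contiguous region and copy the truth with a
  controllable error rate, by default tied to 1 - similarity so that
  better templates are genuinely more informative.

The generator is fully seeded, and the singlet Bayes rate (the best
possible accuracy from a single residue identity) is available in
closed form as a baseline for learnability checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabets import AA_ORDER, N_AA, N_SS8, SS8_ORDER
from .io import (
    ChainRecord,
    ProfileMatrix,
    read_dssp,
    read_fasta,
    read_pssm,
    write_dssp,
    write_fasta,
    write_pssm,
)
from .templates import (
    AlignmentHit,
    TemplateTrack,
    iter_hit_rows,
    map_alignment_to_template,
    select_template,
    write_hit_table,
)

__all__ = [
    "GeneratorConfig",
    "CorpusBundle",
    "default_transition",
    "default_emission",
    "stationary_distribution",
    "singlet_bayes_rate",
    "generate_chain",
    "generate_template",
    "generate_corpus",
    "write_corpus",
    "read_corpus",
]

#: Mean segment length per state (canonical order G,H,I,E,B,T,S,C):
#: helices long, bridges single-residue, turns/bends short.
MEAN_SEGMENT_LENGTHS = {"G": 3, "H": 10, "I": 5, "E": 5, "B": 1, "T": 3, "S": 2, "C": 4}

#: Relative segment-entry weights, chosen so the stationary residue
#: frequencies are qualitatively protein-like (H and C most common, I
#: rarest).
_ENTRY_WEIGHTS = {
    "G": 0.058,
    "H": 0.139,
    "I": 0.009,
    "E": 0.182,
    "B": 0.043,
    "T": 0.159,
    "S": 0.173,
    "C": 0.237,
}


def default_transition() -> np.ndarray:
    """8 x 8 state-transition matrix with protein-like segment statistics."""
    P = np.zeros((N_SS8, N_SS8))
    w = np.array([_ENTRY_WEIGHTS[s] for s in SS8_ORDER])
    for i, s in enumerate(SS8_ORDER):
        stay = 1.0 - 1.0 / MEAN_SEGMENT_LENGTHS[s]
        off = w.copy()
        off[i] = 0.0
        off /= off.sum()
        P[i] = (1.0 - stay) * off
        P[i, i] = stay
    return P


#: Emission preference centers on a ring over the 20 residue types.
#: States within a structural family share a center — the three helix
#: types (G,H,I), the two strand types (E,B), and turn/bend (T,S) — so
#: the sequence identifies the family but not the member, as in real
#: proteins where e.g. 3-10 and alpha helix propensities are nearly
#: identical. Family members are separated only by segment dynamics and
#: by template information. Coil (C) is broad.
_EMISSION_CENTERS = {"G": 2.0, "H": 2.0, "I": 2.0, "E": 8.0, "B": 8.0, "T": 13.0, "S": 13.0, "C": 17.0}
_EMISSION_WIDTHS = {"G": 2.5, "H": 2.5, "I": 2.5, "E": 2.5, "B": 2.5, "T": 2.5, "S": 2.5, "C": 6.0}


def default_emission(sharpness: float = 3.0) -> np.ndarray:
    """8 x 20 state-conditioned residue emission matrix.

    Each state prefers a soft block of residue types; states in the same
    structural family (helices G/H/I, strands E/B, turn/bend T/S) share
    the block, so single-residue information is deliberately ambiguous
    within families, as it is in real proteins, and context or template
    information must disambiguate. ``sharpness`` scales the
    log-preferences.
    """
    centers = np.array([_EMISSION_CENTERS[s] for s in SS8_ORDER])
    widths = np.array([_EMISSION_WIDTHS[s] for s in SS8_ORDER])
    r = np.arange(N_AA)
    d = np.abs(r[None, :] - centers[:, None])
    d = np.minimum(d, N_AA - d)  # circular distance
    bump = np.exp(-(d**2) / (2 * widths[:, None] ** 2))
    logits = sharpness * bump
    e = np.exp(logits - logits.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic corpus generator (fully seeded)."""

    n_chains: int = 50
    length_range: tuple[int, int] = (50, 120)
    state_transition: np.ndarray = field(default_factory=default_transition)
    emission_sharpness: float = 3.0
    emission: np.ndarray | None = None  # default: default_emission(sharpness)
    pssm_noise: float = 10.0  # Dirichlet concentration; larger = cleaner profiles
    #: weight of the query residue's one-hot blended into its profile row,
    #: emulating the substantial frequency PSI-BLAST assigns the query
    #: residue itself; also guarantees the true residue nonzero frequency
    profile_query_blend: float = 0.3
    template_similarity: float = 0.0
    template_coverage: float = 0.0
    template_error_rate: float | None = None  # None -> 1 - similarity
    seed: int = 0

    def __post_init__(self) -> None:
        self.state_transition = np.asarray(self.state_transition, dtype=float)
        if self.state_transition.shape != (N_SS8, N_SS8) or np.any(
            self.state_transition < 0
        ):
            raise ValueError("state_transition must be a nonnegative 8x8 matrix")
        if np.any(np.abs(self.state_transition.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("state_transition rows must sum to 1")
        if self.emission is None:
            self.emission = default_emission(self.emission_sharpness)
        self.emission = np.asarray(self.emission, dtype=float)
        if self.emission.shape != (N_SS8, N_AA) or np.any(self.emission < 0):
            raise ValueError("emission must be a nonnegative 8x20 matrix")
        if np.any(np.abs(self.emission.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("emission rows must sum to 1")
        for name in ("template_similarity", "template_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.template_error_rate is not None and not (
            0.0 <= self.template_error_rate <= 1.0
        ):
            raise ValueError("template_error_rate must be in [0, 1] or None")
        if self.pssm_noise <= 0:
            raise ValueError("pssm_noise must be positive")
        if not 0.0 < self.profile_query_blend <= 1.0:
            raise ValueError("profile_query_blend must be in (0, 1]")

    @property
    def effective_error_rate(self) -> float:
        if self.template_error_rate is not None:
            return self.template_error_rate
        return 1.0 - self.template_similarity


def stationary_distribution(transition: np.ndarray) -> np.ndarray:
    """Stationary distribution of an ergodic chain (left eigenvector)."""
    vals, vecs = np.linalg.eig(transition.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def singlet_bayes_rate(cfg: GeneratorConfig) -> float:
    """Best achievable accuracy from the residue identity alone.

    With stationary state frequencies pi and emissions e, the Bayes
    classifier picks argmax_c pi_c e_c(r), so its accuracy is
    sum_r max_c pi_c e_c(r). Anything above this must exploit context
    (neighbouring residues, profile, or template).
    """
    pi = stationary_distribution(cfg.state_transition)
    joint = pi[:, None] * cfg.emission
    return float(joint.max(axis=0).sum())


def generate_chain(
    cfg: GeneratorConfig, rng: np.random.Generator, chain_id: str = "chain0"
) -> tuple[ChainRecord, ProfileMatrix]:
    """Sample one labeled chain and its noisy profile."""
    lo, hi = cfg.length_range
    L = int(rng.integers(lo, hi + 1))
    pi = stationary_distribution(cfg.state_transition)
    states = np.empty(L, dtype=np.int64)
    states[0] = rng.choice(N_SS8, p=pi)
    for j in range(1, L):
        states[j] = rng.choice(N_SS8, p=cfg.state_transition[states[j - 1]])
    residues = np.array(
        [rng.choice(N_AA, p=cfg.emission[c]) for c in states], dtype=np.int64
    )
    sequence = "".join(AA_ORDER[r] for r in residues)
    ss8 = "".join(SS8_ORDER[c] for c in states)

    alpha = cfg.pssm_noise * cfg.emission[states] + 1e-2
    freqs = np.vstack([rng.dirichlet(a) for a in alpha])
    onehot = np.zeros((L, N_AA))
    onehot[np.arange(L), residues] = 1.0
    blend = cfg.profile_query_blend
    freqs = (1.0 - blend) * freqs + blend * onehot
    freqs /= freqs.sum(axis=1, keepdims=True)

    return ChainRecord(chain_id, sequence, ss8), ProfileMatrix(chain_id, freqs)


def generate_template(
    truth: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> TemplateTrack:
    """Sample a template track for a chain with the given true labels.

    A contiguous region of fractional length ``template_coverage`` copies
    the truth; each covered position is rewritten to a uniformly chosen
    *different* state with probability ``effective_error_rate``. The
    similarity degree is constant over the covered region.
    """
    L = len(truth)
    track = TemplateTrack.empty(L)
    n_cov = int(round(cfg.template_coverage * L))
    if n_cov == 0 or cfg.template_similarity <= 0.0:
        return track
    start = int(rng.integers(0, L - n_cov + 1))
    err = cfg.effective_error_rate
    for pos in range(start, start + n_cov):
        true_state = SS8_ORDER.index(truth[pos])
        if rng.random() < err:
            wrong = int(rng.integers(0, N_SS8 - 1))
            state = wrong if wrong < true_state else wrong + 1
        else:
            state = true_state
        track.states[pos] = state
        track.similarity[pos] = cfg.template_similarity
    return track


@dataclass
class CorpusBundle:
    """An in-memory synthetic corpus, keyed by chain id."""

    config: GeneratorConfig
    chains: list[ChainRecord]
    profiles: dict[str, ProfileMatrix]
    templates: dict[str, TemplateTrack]

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def chain(self, chain_id: str) -> ChainRecord:
        return next(c for c in self.chains if c.chain_id == chain_id)


def generate_corpus(
    cfg: GeneratorConfig,
    similarity_cycle: list[float] | None = None,
) -> CorpusBundle:
    """Generate a fully reproducible corpus of chains/profiles/templates.

    ``similarity_cycle``, when given, overrides ``cfg.template_similarity``
    per chain in round-robin order (similarity 0 means no template),
    which yields exactly balanced similarity groups for binned
    evaluation; the error rate then follows 1 - similarity unless
    ``template_error_rate`` is set.
    """
    rng = np.random.default_rng(cfg.seed)
    chains: list[ChainRecord] = []
    profiles: dict[str, ProfileMatrix] = {}
    templates: dict[str, TemplateTrack] = {}
    for i in range(cfg.n_chains):
        cid = f"synth{i:05d}"
        chain, profile = generate_chain(cfg, rng, cid)
        if similarity_cycle is not None:
            sim = similarity_cycle[i % len(similarity_cycle)]
            sub = GeneratorConfig(
                n_chains=1,
                length_range=cfg.length_range,
                state_transition=cfg.state_transition,
                emission=cfg.emission,
                pssm_noise=cfg.pssm_noise,
                profile_query_blend=cfg.profile_query_blend,
                template_similarity=sim,
                template_coverage=cfg.template_coverage if sim > 0 else 0.0,
                template_error_rate=cfg.template_error_rate,
                seed=cfg.seed,
            )
            track = generate_template(chain.ss8, sub, rng)
        else:
            track = generate_template(chain.ss8, cfg, rng)
        chains.append(chain)
        profiles[cid] = profile
        templates[cid] = track
    return CorpusBundle(cfg, chains, profiles, templates)


# --------------------------------------------------------------------------
# On-disk round trip in the standard formats
# --------------------------------------------------------------------------


def write_corpus(bundle: CorpusBundle, outdir: str | Path) -> None:
    """Write the bundle in the exact formats the parsers read.

    Layout: ``chains.fasta``; ``pssm/<id>.pssm``; ``dssp/<id>.dssp``
    (labels); ``hits.tsv`` plus ``dssp/t_<id>.dssp`` pseudo hit chains
    realizing each template track as an alignment against a chain of
    "known" structure.
    """
    outdir = Path(outdir)
    (outdir / "pssm").mkdir(parents=True, exist_ok=True)
    (outdir / "dssp").mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.chains, outdir / "chains.fasta")
    first = True
    for chain in bundle.chains:
        cid = chain.chain_id
        write_pssm(bundle.profiles[cid], chain.sequence, outdir / "pssm" / f"{cid}.pssm")
        write_dssp([chain], outdir / "dssp" / f"{cid}.dssp")
        track = bundle.templates.get(cid)
        if track is None or not track.present.any():
            continue
        covered = np.flatnonzero(track.present)
        start, stop = int(covered[0]), int(covered[-1]) + 1
        hit_id = f"t_{cid}"
        hit_chain = ChainRecord(
            hit_id,
            chain.sequence[start:stop],
            track.states_string()[start:stop].replace(".", "C"),
        )
        write_dssp([hit_chain], outdir / "dssp" / f"{hit_id}.dssp")
        sim = float(track.similarity[covered[0]])
        hit = AlignmentHit(
            hit_id=hit_id,
            similarity=sim,
            evalue=1e-5,
            rank=1,
            aligned_pairs=[(int(q), int(q) - start) for q in covered],
        )
        write_hit_table(cid, [hit], outdir / "hits.tsv", append=not first)
        first = False
    if first:  # no templated chains at all: still leave a valid empty table
        (outdir / "hits.tsv").write_text("# qid\tsid\trank\tpident\tevalue\tblocks\n")


def read_corpus(indir: str | Path, cfg: GeneratorConfig | None = None) -> CorpusBundle:
    """Read a corpus directory written by :func:`write_corpus`."""
    indir = Path(indir)
    chains = read_fasta(indir / "chains.fasta")
    profiles: dict[str, ProfileMatrix] = {}
    templates: dict[str, TemplateTrack] = {}
    labeled: list[ChainRecord] = []

    hits_by_query: dict[str, list[AlignmentHit]] = {}
    hits_path = indir / "hits.tsv"
    if hits_path.exists():
        for qid, hit in iter_hit_rows(hits_path):
            hits_by_query.setdefault(qid, []).append(hit)

    for chain in chains:
        cid = chain.chain_id
        profiles[cid] = read_pssm(indir / "pssm" / f"{cid}.pssm", cid)
        dssp = read_dssp(indir / "dssp" / f"{cid}.dssp")[0]
        labeled.append(ChainRecord(cid, chain.sequence, dssp.ss8, dssp.determined))
        track = TemplateTrack.empty(len(chain.sequence))
        hit = select_template(hits_by_query.get(cid, []))
        if hit is not None:
            hit_chain = read_dssp(indir / "dssp" / f"{hit.hit_id}.dssp")[0]
            track = map_alignment_to_template(hit, hit_chain, len(chain.sequence))
        templates[cid] = track
    return CorpusBundle(cfg or GeneratorConfig(n_chains=len(labeled)), labeled, profiles, templates)
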