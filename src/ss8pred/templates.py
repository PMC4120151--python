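"""Structural templates from homology search hits.

A profile search of the query against sequences of known structure yields
ranked alignment hits. The top hit below a similarity ceiling (default
95%, which excludes trivial self-matches) is selected, and the DSSP
8-state assignment of the hit chain is transferred to the aligned query
positions, annotated with the hit's sequence similarity. Query positions
without template coverage stay empty and later fall back to context-based
scores in the encoder.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabets import SS8_INDEX, SS8_ORDER
from .io import ChainRecord, FormatError

__all__ = [
    "AlignmentHit",
    "TemplateTrack",
    "parse_hit_table",
    "write_hit_table",
    "select_template",
    "map_alignment_to_template",
]


@dataclass
class AlignmentHit:
    """One profile-search hit against a chain of known structure."""

    hit_id: str
    similarity: float  # identity fraction over the aligned region, in [0,1]
    evalue: float
    rank: int
    aligned_pairs: list[tuple[int, int]] = field(default_factory=list)  # 0-based (query, hit)

    def __post_init__(self) -> None:
        if not 0.0 <= self.similarity <= 1.0:
            raise ValueError(f"hit {self.hit_id}: similarity must be in [0,1]")
        if self.evalue < 0:
            raise ValueError(f"hit {self.hit_id}: negative E-value")
        if self.rank < 1:
            raise ValueError(f"hit {self.hit_id}: rank must be positive")
        q_prev, s_prev = -1, -1
        for q, s in self.aligned_pairs:
            if q <= q_prev or s <= s_prev:
                raise ValueError(
                    f"hit {self.hit_id}: aligned_pairs must be strictly increasing"
                )
            q_prev, s_prev = q, s


@dataclass
class TemplateTrack:
    """Per-residue template annotation for a query of length L.

    ``states[i]`` is the transferred state index (canonical order) or -1
    where no template covers position i; ``similarity[i]`` is the hit
    similarity there and 0 exactly where no state is present.
    """

    states: np.ndarray  # (L,) int8, -1 = absent
    similarity: np.ndarray  # (L,) float
    source_id: str | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.similarity = np.asarray(self.similarity, dtype=float)
        if self.states.shape != self.similarity.shape:
            raise ValueError("states/similarity length mismatch")
        present = self.states >= 0
        if np.any((self.similarity > 0) != present):
            raise ValueError("similarity must be > 0 exactly where a state is present")

    def __len__(self) -> int:
        return self.states.shape[0]

    @property
    def present(self) -> np.ndarray:
        return self.states >= 0

    @property
    def coverage(self) -> float:
        return float(self.present.mean()) if len(self) else 0.0

    @classmethod
    def empty(cls, length: int) -> "TemplateTrack":
        return cls(np.full(length, -1, dtype=np.int8), np.zeros(length))

    def states_string(self, absent_char: str = ".") -> str:
        return "".join(
            SS8_ORDER[s] if s >= 0 else absent_char for s in self.states
        )


# --------------------------------------------------------------------------
# Hit tables
# --------------------------------------------------------------------------
#
# Dialect: tab-separated columns
#   qid  sid  rank  pident  evalue  blocks
# where blocks is a comma-joined list of gapless aligned segments
# "qstart-qend/sstart-send" in 1-based inclusive coordinates.


def _expand_blocks(blocks: str) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    for block in blocks.split(","):
        qpart, spart = block.split("/")
        q0, q1 = (int(x) for x in qpart.split("-"))
        s0, s1 = (int(x) for x in spart.split("-"))
        if q1 - q0 != s1 - s0:
            raise ValueError(f"block {block!r}: unequal segment lengths")
        pairs.extend((q0 - 1 + i, s0 - 1 + i) for i in range(q1 - q0 + 1))
    return pairs


def iter_hit_rows(path: str | Path):
    """Yield (query_id, AlignmentHit) per parseable row, in file order.

    Malformed rows are skipped with a warning.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                qid, sid, rank, pident, evalue, blocks = line.split("\t")
                hit = AlignmentHit(
                    hit_id=sid,
                    similarity=float(pident) / 100.0,
                    evalue=float(evalue),
                    rank=int(rank),
                    aligned_pairs=_expand_blocks(blocks),
                )
            except (ValueError, IndexError) as exc:
                warnings.warn(f"{path}:{lineno}: skipping malformed hit row ({exc})")
                continue
            yield qid, hit


def parse_hit_table(path: str | Path) -> list[AlignmentHit]:
    """Read a hit report; malformed rows are skipped with a warning.

    Hits are returned sorted by rank; percent identity is converted to a
    fraction. An empty file yields an empty list.
    """
    hits = [hit for _, hit in iter_hit_rows(path)]
    hits.sort(key=lambda h: h.rank)
    return hits


def write_hit_table(
    qid: str, hits: list[AlignmentHit], path: str | Path, append: bool = False
) -> None:
    """Write hits in the tab-separated dialect :func:`parse_hit_table` reads."""
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("# qid\tsid\trank\tpident\tevalue\tblocks\n")
        for hit in hits:
            blocks = []
            pairs = hit.aligned_pairs
            i = 0
            while i < len(pairs):
                j = i
                while (
                    j + 1 < len(pairs)
                    and pairs[j + 1][0] == pairs[j][0] + 1
                    and pairs[j + 1][1] == pairs[j][1] + 1
                ):
                    j += 1
                (q0, s0), (q1, s1) = pairs[i], pairs[j]
                blocks.append(f"{q0 + 1}-{q1 + 1}/{s0 + 1}-{s1 + 1}")
                i = j + 1
            fh.write(
                f"{qid}\t{hit.hit_id}\t{hit.rank}\t{hit.similarity * 100:.2f}\t"
                f"{hit.evalue:g}\t{','.join(blocks)}\n"
            )


# --------------------------------------------------------------------------
# Template selection and mapping
# --------------------------------------------------------------------------


def select_template(
    hits: list[AlignmentHit], max_similarity: float = 0.95
) -> AlignmentHit | None:
    """Pick the top-ranked hit strictly below the similarity ceiling.

    The ceiling (default 0.95) rejects near-identical chains so that
    evaluation never amounts to copying the answer from the query's own
    structure. Returns None when no hit qualifies.
    """
    for hit in sorted(hits, key=lambda h: h.rank):
        if hit.similarity < max_similarity:
            return hit
    return None


def map_alignment_to_template(
    hit: AlignmentHit, hit_chain: ChainRecord, query_len: int
) -> TemplateTrack:
    """Transfer the hit chain's 8-state labels onto the query.

    Each aligned pair copies the hit residue's state and the hit's
    similarity onto the query position; hit residues with undetermined
    structure leave the query position empty, as do unaligned positions.
    """
    if hit_chain.ss8 is None:
        raise ValueError(f"hit chain {hit_chain.chain_id} lacks ss8 labels")
    track = TemplateTrack.empty(query_len)
    track.source_id = hit.hit_id
    det = hit_chain.determined_mask
    for q, s in hit.aligned_pairs:
        if not 0 <= q < query_len:
            raise ValueError(f"hit {hit.hit_id}: query position {q} out of range")
        if not 0 <= s < len(hit_chain):
            raise ValueError(f"hit {hit.hit_id}: hit position {s} out of range")
        if not det[s]:
            continue
        track.states[q] = SS8_INDEX[hit_chain.ss8[s]]
        track.similarity[q] = hit.similarity
    return track
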