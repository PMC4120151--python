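"""Readers and writers for the formats the predictor touches.

FASTA (via Biopython), PSI-BLAST ASCII PSSM profiles (the
``-out_ascii_pssm`` dialect), DSSP classic text output, and the package's
tab-separated prediction output. Also the dataset-level chain filters
applied before training.

All coordinates are converted to 0-based half-open at this boundary;
DSSP and PSSM files are 1-based on disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabets import (
    AA_INDEX,
    AA_ORDER,
    N_AA,
    N_SS8,
    PSIBLAST_AA_ORDER,
    PSIBLAST_TO_CANONICAL,
    SS8_ORDER,
)


class FormatError(ValueError):
    """Raised when an input file cannot be parsed in its declared format."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ChainRecord:
    """One protein chain: sequence plus optional 8-state labels.

    Parameters
    ----------
    chain_id : str
        Unique identifier for the chain.
    sequence : str
        Upper-case amino-acid letters; unknown residues as ``'X'``.
    ss8 : str, optional
        Secondary-structure string over ``GHIEBTSC``, same length as the
        sequence.
    determined : ndarray of bool, optional
        Per-residue flag; ``False`` marks residues whose structure is
        undetermined (excluded from training samples and scoring but kept
        in place in the sequence). ``None`` means all determined.
    """

    chain_id: str
    sequence: str
    ss8: str | None = None
    determined: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.ss8 is not None:
            if len(self.ss8) != len(self.sequence):
                raise ValueError(
                    f"{self.chain_id}: ss8 length {len(self.ss8)} != "
                    f"sequence length {len(self.sequence)}"
                )
            bad = set(self.ss8) - set(SS8_ORDER)
            if bad:
                raise ValueError(f"{self.chain_id}: invalid ss8 letters {bad}")
        if self.determined is not None:
            self.determined = np.asarray(self.determined, dtype=bool)
            if self.determined.shape != (len(self.sequence),):
                raise ValueError(f"{self.chain_id}: determined mask length mismatch")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def determined_mask(self) -> np.ndarray:
        """Boolean mask of determined residues (all True when unset)."""
        if self.determined is None:
            return np.ones(len(self.sequence), dtype=bool)
        return self.determined


@dataclass
class ProfileMatrix:
    """Per-position residue-frequency profile (an L x 20 matrix).

    Columns follow :data:`ss8pred.alphabets.AA_ORDER`; each row is a
    probability distribution over the 20 amino-acid types.
    """

    chain_id: str
    freqs: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != N_AA:
            raise ValueError(f"{self.chain_id}: profile must be L x {N_AA}")
        if np.any(self.freqs < -1e-12) or np.any(self.freqs > 1 + 1e-12):
            raise ValueError(f"{self.chain_id}: profile entries outside [0, 1]")
        rowsum = self.freqs.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > 1e-6):
            raise ValueError(f"{self.chain_id}: profile rows must sum to 1")

    def __len__(self) -> int:
        return self.freqs.shape[0]


@dataclass
class DatasetFilterReport:
    """Bookkeeping from :func:`filter_dataset`."""

    kept: int = 0
    dropped_short: int = 0
    dropped_long: int = 0
    residues_dropped_undetermined: int = 0


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------


def _clean_sequence(raw: str, chain_id: str) -> str:
    seq = raw.upper()
    cleaned = []
    n_mapped = 0
    for ch in seq:
        if ch in AA_INDEX:
            cleaned.append(ch)
        else:
            cleaned.append("X")
            if ch != "X":
                n_mapped += 1
    if n_mapped:
        warnings.warn(
            f"{chain_id}: {n_mapped} non-canonical residue letters mapped to 'X'"
        )
    return "".join(cleaned)


def read_fasta(path: str | Path) -> list[ChainRecord]:
    """Read a (multi-record) FASTA file into :class:`ChainRecord` objects.

    Sequences are upper-cased and non-canonical letters mapped to ``'X'``.
    Duplicate identifiers are disambiguated with ``.2``, ``.3``, ... and a
    warning is emitted.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: dict[str, int] = {}
    chains = []
    for rec in records:
        cid = rec.id
        if cid in seen:
            seen[cid] += 1
            warnings.warn(f"duplicate FASTA id {cid!r}; renaming to {cid}.{seen[cid]}")
            cid = f"{cid}.{seen[cid]}"
        else:
            seen[cid] = 1
        chains.append(ChainRecord(cid, _clean_sequence(str(rec.seq), cid)))
    return chains


def write_fasta(chains: list[ChainRecord], path: str | Path) -> None:
    """Write chains to FASTA."""
    recs = [
        SeqRecord(Seq(c.sequence), id=c.chain_id, description="") for c in chains
    ]
    SeqIO.write(recs, str(path), "fasta")


# --------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# --------------------------------------------------------------------------


def read_pssm(path: str | Path, chain_id: str | None = None) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM into a frequency profile.

    The weighted-observed-percentage block (columns 23-42 of each data row)
    is used; log-odds scores are ignored. Percentages are divided by 100
    and each row renormalized to sum 1. Rows PSI-BLAST left all-zero are
    replaced by the query residue's one-hot distribution ('X' queries get
    the uniform distribution). Columns are remapped from PSI-BLAST's
    native order to the canonical alphabetical order.
    """
    path = Path(path)
    rows: list[np.ndarray] = []
    query: list[str] = []
    numbers: list[int] = []
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if len(tok) < 42 or not tok[0].isdigit() or len(tok[1]) != 1:
                continue
            try:
                pct = np.array([float(x) for x in tok[22:42]], dtype=float)
            except ValueError:
                raise FormatError(f"{path}: malformed percentage block: {line!r}")
            numbers.append(int(tok[0]))
            query.append(tok[1].upper())
            rows.append(pct)
    if not rows:
        raise FormatError(f"{path}: no PSSM rows found (truncated or wrong dialect?)")
    if numbers != list(range(1, len(numbers) + 1)):
        raise FormatError(f"{path}: PSSM row numbering is not contiguous from 1")
    freqs = np.vstack(rows)[:, PSIBLAST_TO_CANONICAL] / 100.0
    rowsum = freqs.sum(axis=1)
    for i in np.flatnonzero(rowsum <= 0):
        aa = query[i]
        if aa in AA_INDEX:
            freqs[i] = 0.0
            freqs[i, AA_INDEX[aa]] = 1.0
        else:
            freqs[i] = 1.0 / N_AA
        rowsum[i] = 1.0
    freqs /= freqs.sum(axis=1, keepdims=True)
    return ProfileMatrix(chain_id or path.stem, freqs)


_PSSM_HEADER = (
    "\nLast position-specific scoring matrix computed, weighted observed "
    "percentages rounded down, information per position, and relative weight "
    "of gapless real matches to pseudocounts\n"
)


def write_pssm(profile: ProfileMatrix, sequence: str, path: str | Path) -> None:
    """Write a profile in the PSI-BLAST ASCII PSSM dialect.

    Log-odds columns are written as zeros (the parser ignores them);
    percentages are written with decimals so profiles round-trip to within
    renormalization tolerance.
    """
    canonical_to_psiblast = np.array(
        [AA_ORDER.index(a) for a in PSIBLAST_AA_ORDER], dtype=np.int64
    )
    with open(path, "w") as fh:
        fh.write(_PSSM_HEADER)
        labels = "  ".join(PSIBLAST_AA_ORDER)
        fh.write(f"            {labels}   {labels}\n")
        for i, (aa, row) in enumerate(zip(sequence, profile.freqs), start=1):
            native = row[canonical_to_psiblast] * 100.0
            logodds = "  ".join("0" for _ in range(N_AA))
            pcts = " ".join(f"{v:.6f}" for v in native)
            fh.write(f"{i:5d} {aa}   {logodds}  {pcts}  0.00 0.00\n")
        fh.write("\n                      K         Lambda\n")


# --------------------------------------------------------------------------
# DSSP
# --------------------------------------------------------------------------

_DSSP_COLUMNS_HEADER = "  #  RESIDUE AA STRUCTURE"


def read_dssp(path: str | Path) -> list[ChainRecord]:
    """Parse DSSP classic text output into per-chain records.

    The structure column is mapped onto the 8 letters ``GHIEBTSC`` (blank
    and any unrecognized code become ``'C'``). ``'!'`` rows split chains.
    Gaps in the residue numbering within a chain mark residues whose
    structure was undetermined: they are filled in as ``'X'``/``'C'`` with
    ``determined=False``. Lower-case amino-acid codes (disulfide-bonded
    cysteines) are read as ``'C'`` (cysteine).
    """
    path = Path(path)
    stem = path.stem
    lines = path.read_text().splitlines()
    start = None
    for i, line in enumerate(lines):
        if line.startswith(_DSSP_COLUMNS_HEADER):
            start = i + 1
            break
    if start is None:
        raise FormatError(f"{path}: DSSP column header not found")

    chains: list[tuple[str, list[str], list[str], list[bool]]] = []
    cur_letter: str | None = None
    prev_num: int | None = None

    def new_chain(letter: str) -> None:
        nonlocal cur_letter, prev_num
        chains.append((letter, [], [], []))
        cur_letter = letter
        prev_num = None

    for line in lines[start:]:
        if len(line) < 17:
            continue
        aa = line[13]
        if aa == "!":
            cur_letter = None
            continue
        letter = line[11]
        try:
            resnum = int(line[5:10])
        except ValueError:
            continue
        if cur_letter is None or letter != cur_letter:
            new_chain(letter)
        _, seq, ss, det = chains[-1]
        if prev_num is not None and resnum > prev_num + 1:
            for _ in range(resnum - prev_num - 1):
                seq.append("X")
                ss.append("C")
                det.append(False)
        prev_num = resnum
        if aa.islower():
            aa = "C"
        seq.append(aa if aa in AA_INDEX else "X")
        code = line[16]
        ss.append(code if code in SS8_ORDER and code != "C" else "C")
        det.append(True)

    letters = [c[0] for c in chains]
    records = []
    for letter, seq, ss, det in chains:
        if not seq:
            continue
        if len(chains) == 1:
            cid = stem
        else:
            cid = f"{stem}:{letter}" if letters.count(letter) == 1 else f"{stem}:{letter}{len(records)}"
        records.append(
            ChainRecord(cid, "".join(seq), "".join(ss), np.array(det, dtype=bool))
        )
    if not records:
        raise FormatError(f"{path}: no residue rows found")
    return records


def write_dssp(chains: list[ChainRecord], path: str | Path) -> None:
    """Write chains as a DSSP-classic-format fixture file.

    Chains are separated by ``'!'`` break rows and lettered A, B, ...
    Undetermined residues are omitted, leaving a numbering gap, which is
    how real DSSP output represents residues without coordinates.
    """
    header = [
        "==== Secondary structure fixture in DSSP classic layout ====",
        "REFERENCE  synthetic fixture, not a real DSSP run",
        f"  {sum(len(c) for c in chains):5d}  {len(chains):3d}",
        _DSSP_COLUMNS_HEADER
        + "   BP1 BP2  ACC     N-H-->O    O-->H-N    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
    ]
    serial = 0
    body = []
    for ci, chain in enumerate(chains):
        if ci > 0:
            serial += 1
            body.append(f"{serial:5d}        !              0   0    0")
        letter = chr(ord("A") + (ci % 26))
        mask = chain.determined_mask
        ss8 = chain.ss8 or "C" * len(chain)
        for pos, (aa, code) in enumerate(zip(chain.sequence, ss8)):
            if not mask[pos]:
                continue
            serial += 1
            sscol = " " if code == "C" else code
            body.append(
                f"{serial:5d}{pos + 1:5d} {letter} {aa}  {sscol}"
                + " " * 10
                + "0   0    0"
            )
    Path(path).write_text("\n".join(header + body) + "\n")


# --------------------------------------------------------------------------
# Dataset filtering
# --------------------------------------------------------------------------

MIN_CHAIN_LENGTH = 40
MAX_CHAIN_LENGTH = 1000


def filter_dataset(
    chains: list[ChainRecord],
    min_length: int = MIN_CHAIN_LENGTH,
    max_length: int = MAX_CHAIN_LENGTH,
) -> tuple[list[ChainRecord], DatasetFilterReport]:
    """Apply the training-set chain filters.

    Chains shorter than ``min_length`` residues (profile generation is
    unreliable for very short sequences) or longer than ``max_length`` are
    dropped. Residues with undetermined structure remain in place but are
    counted; downstream sample extraction skips them via the
    ``determined`` mask.
    """
    kept: list[ChainRecord] = []
    report = DatasetFilterReport()
    for chain in chains:
        if len(chain) < min_length:
            report.dropped_short += 1
        elif len(chain) > max_length:
            report.dropped_long += 1
        else:
            kept.append(chain)
            report.residues_dropped_undetermined += int(
                (~chain.determined_mask).sum()
            )
    report.kept = len(kept)
    return kept, report


# --------------------------------------------------------------------------
# Prediction output
# --------------------------------------------------------------------------


def write_prediction(
    chain: ChainRecord,
    states: str,
    probs: np.ndarray,
    path: str | Path,
) -> None:
    """Write a prediction as TSV: index, residue, state, 8 probabilities."""
    probs = np.asarray(probs, dtype=float)
    if probs.shape != (len(chain), N_SS8):
        raise ValueError("probability matrix shape mismatch")
    with open(path, "w") as fh:
        fh.write(f"# chain\t{chain.chain_id}\n")
        cols = "\t".join(f"p{s}" for s in SS8_ORDER)
        fh.write(f"# idx\tresidue\tstate\t{cols}\n")
        for i, (aa, st) in enumerate(zip(chain.sequence, states)):
            row = "\t".join(f"{p:.6f}" for p in probs[i])
            fh.write(f"{i + 1}\t{aa}\t{st}\t{row}\n")


def read_prediction(path: str | Path) -> tuple[str, str, str, np.ndarray]:
    """Read a prediction TSV back: (chain_id, sequence, states, probs)."""
    chain_id = Path(path).stem
    seq: list[str] = []
    states: list[str] = []
    probs: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if line.startswith("# chain\t"):
                    chain_id = line.strip().split("\t")[1]
                continue
            tok = line.split()
            if len(tok) != 3 + N_SS8:
                raise FormatError(f"{path}: malformed prediction row: {line!r}")
            seq.append(tok[1])
            states.append(tok[2])
            probs.append([float(x) for x in tok[3:]])
    return chain_id, "".join(seq), "".join(states), np.array(probs, dtype=float)
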