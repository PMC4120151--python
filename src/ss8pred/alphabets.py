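"""Canonical alphabets and index maps.

Every array in the package that is indexed by amino-acid type or by
secondary-structure state uses the orders defined here. External file
dialects (PSI-BLAST column order, DSSP codes) are remapped at the parser
boundary.
"""

from __future__ import annotations

import numpy as np

#: Amino acids, alphabetical by one-letter code. Column order of every
#: 20-wide profile/count axis.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ORDER)}
N_AA: int = 20

#: The eight DSSP states: 3-10 helix, alpha helix, pi helix, strand,
#: beta bridge, turn, bend, other/coil. Order of every 8-wide state axis.
SS8_ORDER: str = "GHIEBTSC"
SS8_INDEX: dict[str, int] = {s: i for i, s in enumerate(SS8_ORDER)}
N_SS8: int = 8

#: Tie-break priority for argmax state assignment, most to least frequent
#: in globular proteins. When probabilities tie exactly, the earlier
#: letter here wins.
TIEBREAK_PRIORITY: str = "HECTGSB I".replace(" ", "")

#: Rank of each canonical state index under the tie-break priority
#: (lower rank wins).
TIEBREAK_RANK: np.ndarray = np.array(
    [TIEBREAK_PRIORITY.index(s) for s in SS8_ORDER], dtype=np.int64
)

#: PSI-BLAST's native column order in ASCII PSSM files.
PSIBLAST_AA_ORDER: str = "ARNDCQEGHILKMFPSTWVY"
#: Permutation taking a PSI-BLAST-ordered 20-vector to canonical order:
#: canonical[i] = psiblast_row[PSIBLAST_TO_CANONICAL[i]].
PSIBLAST_TO_CANONICAL: np.ndarray = np.array(
    [PSIBLAST_AA_ORDER.index(a) for a in AA_ORDER], dtype=np.int64
)


def seq_to_indices(sequence: str) -> np.ndarray:
    """Map a sequence to amino-acid indices; 'X' (or any unknown) -> -1."""
    return np.array([AA_INDEX.get(a, -1) for a in sequence], dtype=np.int64)


def ss8_to_indices(ss8: str) -> np.ndarray:
    """Map an 8-state string to state indices. Raises on unknown letters."""
    try:
        return np.array([SS8_INDEX[s] for s in ss8], dtype=np.int64)
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown secondary-structure letter {exc}") from exc
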