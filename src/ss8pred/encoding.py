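"""Window encodings feeding the two prediction networks.

Stage 1 (sequence -> structure): each residue is described by a sliding
window (default 15 residues) of 30-value blocks — 20 profile
frequencies, 1 terminal flag (set when the slot falls off either end of
the chain), 1 template-similarity degree, and 8 structure values. The
structure values are the one-hot transferred template state where the
template covers the slot, and the bounded context-based scores (with
similarity 0) otherwise. 15 x 30 = 450 values per residue.

Stage 2 (structure -> structure refinement): a window over the stage-1
output distributions, 9 values per slot (8 probabilities + terminal
flag), 135 per residue at the default window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .alphabets import N_AA, N_SS8
from .io import ChainRecord, ProfileMatrix
from .templates import TemplateTrack

__all__ = ["EncoderConfig", "encode_chain_stage1", "encode_chain_stage2"]

#: profile(20) + terminal flag(1) + similarity(1) + structure(8)
PER_RESIDUE_WIDTH = N_AA + 1 + 1 + N_SS8
#: stage-2 slot: 8 probabilities + terminal flag
STAGE2_SLOT_WIDTH = N_SS8 + 1

_TERMINAL_COL = N_AA  # index of the terminal flag inside a 30-value block
_SIMILARITY_COL = N_AA + 1
_STRUCT_COLS = slice(N_AA + 2, N_AA + 2 + N_SS8)


@dataclass(frozen=True)
class EncoderConfig:
    """Window sizes for both stages; windows must be odd so the predicted
    residue sits at the center slot."""

    window: int = 15
    stage2_window: int = 15

    def __post_init__(self) -> None:
        for name in ("window", "stage2_window"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be an odd positive integer, got {w}")

    @property
    def per_residue_width(self) -> int:
        return PER_RESIDUE_WIDTH

    @property
    def stage1_row_width(self) -> int:
        return self.window * PER_RESIDUE_WIDTH

    @property
    def stage2_row_width(self) -> int:
        return self.stage2_window * STAGE2_SLOT_WIDTH


def _window_stack(blocks: np.ndarray, pad_block: np.ndarray, window: int) -> np.ndarray:
    """Slide an odd-size window over per-position blocks, padding both ends."""
    half = window // 2
    L, width = blocks.shape
    padded = np.vstack([np.tile(pad_block, (half, 1)), blocks, np.tile(pad_block, (half, 1))])
    # (L, window, width) -> (L, window * width)
    view = sliding_window_view(padded, (window, width)).reshape(L, window * width)
    return np.ascontiguousarray(view)


def encode_chain_stage1(
    chain: ChainRecord,
    profile: ProfileMatrix,
    template: TemplateTrack | None,
    ctx_scores: np.ndarray,
    cfg: EncoderConfig | None = None,
) -> np.ndarray:
    """Encode a chain for the sequence->structure network.

    ``ctx_scores`` is the L x 8 matrix of *scaled* context scores
    (already mapped into [0, 1]); ``template`` may be None for the pure
    context-score path. Returns an L x (window * 30) feature matrix.
    Off-chain slots are all-zero except the terminal flag.
    """
    cfg = cfg or EncoderConfig()
    L = len(chain)
    ctx_scores = np.asarray(ctx_scores, dtype=float)
    if len(profile) != L or ctx_scores.shape != (L, N_SS8):
        raise ValueError(f"{chain.chain_id}: encoder input length mismatch")
    if template is not None and len(template) != L:
        raise ValueError(f"{chain.chain_id}: template track length mismatch")

    blocks = np.zeros((L, PER_RESIDUE_WIDTH))
    blocks[:, :N_AA] = profile.freqs
    blocks[:, _STRUCT_COLS] = ctx_scores
    if template is not None:
        present = template.present
        if present.any():
            idx = np.flatnonzero(present)
            blocks[idx, _SIMILARITY_COL] = template.similarity[idx]
            onehot = np.zeros((idx.size, N_SS8))
            onehot[np.arange(idx.size), template.states[idx]] = 1.0
            blocks[idx, _STRUCT_COLS] = onehot

    pad = np.zeros(PER_RESIDUE_WIDTH)
    pad[_TERMINAL_COL] = 1.0
    return _window_stack(blocks, pad, cfg.window)


def encode_chain_stage2(
    stage1_probs: np.ndarray, cfg: EncoderConfig | None = None
) -> np.ndarray:
    """Encode stage-1 output distributions for the refinement network.

    Each window slot carries the 8 stage-1 probabilities plus a terminal
    flag. Rows that do not sum to 1 are renormalized with a warning.
    """
    cfg = cfg or EncoderConfig()
    probs = np.asarray(stage1_probs, dtype=float)
    if probs.ndim != 2 or probs.shape[1] != N_SS8:
        raise ValueError("stage1_probs must be L x 8")
    rowsum = probs.sum(axis=1)
    if np.any(np.abs(rowsum - 1.0) > 1e-6):
        warnings.warn("stage-1 probability rows do not sum to 1; renormalizing")
        probs = probs / rowsum[:, None]

    L = probs.shape[0]
    blocks = np.zeros((L, STAGE2_SLOT_WIDTH))
    blocks[:, :N_SS8] = probs
    pad = np.zeros(STAGE2_SLOT_WIDTH)
    pad[N_SS8] = 1.0
    return _window_stack(blocks, pad, cfg.stage2_window)
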