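"""Independent brute-force oracles used by the test suite.

These are written as position-by-position loops, deliberately separate
from the vectorized implementations they check.
"""

import numpy as np

from ss8pred.alphabets import N_AA, N_SS8, SS8_INDEX


def brute_force_counts(corpus, offsets):
    """Position-loop recomputation of the PSSM-weighted context counts.

    Returns (singlet_state, doublet_state, triplet_state, total_weight)
    with the same array layouts as ContextCountTables.
    """
    singlet = np.zeros((N_SS8, N_AA))
    doublet = {k: np.zeros((N_SS8, N_AA, N_AA)) for k in offsets.doublet_offsets}
    triplet = {
        p: np.zeros((N_SS8, N_AA, N_AA, N_AA)) for p in offsets.triplet_offset_pairs
    }
    total = 0.0
    for chain, profile in corpus:
        P = profile.freqs
        det = chain.determined_mask
        L = len(chain)
        for j in range(L):
            if not det[j]:
                continue
            c = SS8_INDEX[chain.ss8[j]]
            singlet[c] += P[j]
            total += 1.0
            for k in offsets.doublet_offsets:
                jj = j + k
                if 0 <= jj < L and det[jj]:
                    doublet[k][c] += np.outer(P[j], P[jj])
            for (k1, k2) in offsets.triplet_offset_pairs:
                j1, j2 = j + k1, j + k2
                if 0 <= j1 < L and 0 <= j2 < L and det[j1] and det[j2]:
                    triplet[(k1, k2)][c] += (
                        P[j][:, None, None] * P[j1][None, :, None] * P[j2][None, None, :]
                    )
    return singlet, doublet, triplet, total


def sov99_score(pairs, delta_on=True):
    """Segment-overlap score (1999 revision), generalized to 8 states.

    ``pairs`` is a list of (pred_string, truth_string). Returns
    (overall, per_state) on the 0-100 scale with NaN for states absent
    from the truth. Written independently of the package implementation:
    segments are enumerated per chain with itertools.groupby and the
    per-pair formula is applied literally.
    """
    from itertools import groupby

    def segments(s):
        segs = []
        pos = 0
        for state, grp in groupby(s):
            n = len(list(grp))
            segs.append((state, pos, pos + n))
            pos += n
        return segs

    num = dict.fromkeys(range(N_SS8), 0.0)
    den = dict.fromkeys(range(N_SS8), 0.0)
    for pred, truth in pairs:
        tsegs = segments(truth)
        psegs = segments(pred)
        for state_letter in set(truth):
            c = SS8_INDEX[state_letter]
            for (ts, t0, t1) in tsegs:
                if ts != state_letter:
                    continue
                len1 = t1 - t0
                found = False
                for (ps, p0, p1) in psegs:
                    if ps != state_letter:
                        continue
                    minov = min(t1, p1) - max(t0, p0)
                    if minov <= 0:
                        continue
                    found = True
                    maxov = max(t1, p1) - min(t0, p0)
                    len2 = p1 - p0
                    if delta_on:
                        delta = min(maxov - minov, minov, len1 // 2, len2 // 2)
                    else:
                        delta = 0
                    num[c] += len1 * (minov + delta) / maxov
                    den[c] += len1
                if not found:
                    den[c] += len1
    per_state = np.full(N_SS8, np.nan)
    for c in range(N_SS8):
        if den[c] > 0:
            per_state[c] = 100.0 * num[c] / den[c]
    overall = 100.0 * sum(num.values()) / sum(den.values())
    return overall, per_state


def random_micro_corpus(rng, one_hot):
    """A random corpus of <=5 labeled chains of length <=10."""
    from ss8pred.alphabets import AA_ORDER, SS8_ORDER
    from ss8pred.io import ChainRecord, ProfileMatrix

    corpus = []
    for ci in range(rng.integers(1, 6)):
        L = int(rng.integers(1, 11))
        seq = "".join(rng.choice(list(AA_ORDER), size=L))
        ss8 = "".join(rng.choice(list(SS8_ORDER), size=L))
        det = rng.random(L) > 0.1
        chain = ChainRecord(f"m{ci}", seq, ss8, det)
        if one_hot:
            freqs = np.zeros((L, N_AA))
            for i, aa in enumerate(seq):
                freqs[i, AA_ORDER.index(aa)] = 1.0
        else:
            freqs = rng.dirichlet(np.ones(N_AA) * 0.5, size=L)
        corpus.append((chain, ProfileMatrix(f"m{ci}", freqs)))
    return corpus
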