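"""Independent brute-force oracles used to cross-check the implementation."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_kmer_counts(sequences, k: int, trim: int) -> dict[str, int]:
    """Dictionary-based canonical k-mer counting by literal window scan."""
    counts: dict[str, int] = {}
    for seq in sequences:
        core = seq[trim : len(seq) - trim] if trim else seq
        for i in range(len(core) - k + 1):
            w = core[i : i + k]
            if any(b not in "ACGT" for b in w):
                continue
            canon = min(w, rc(w))
            counts[canon] = counts.get(canon, 0) + 1
    return counts


def brute_force_interval_members(positions, intervals, trim: int):
    """Per-position membership scan: which positions fall in a trimmed interval."""
    kept = []
    for p in positions:
        for (s, e) in intervals:
            if s + trim <= p < e - trim:
                kept.append(p)
                break
    return sorted(set(kept))


def step_up_bh(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adjusted = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        adjusted[i] = val
        prev = val
    return adjusted


def brute_force_introns(exons_by_transcript, min_length: int):
    """Exon-gap enumeration: returns set of (start, end) intervals per transcript."""
    out = {}
    for tx, exons in exons_by_transcript.items():
        exons = sorted(exons)
        gaps = [
            (e1, s2)
            for (_, e1), (s2, _) in zip(exons, exons[1:])
            if s2 - e1 >= min_length
        ]
        out[tx] = gaps
    return out
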