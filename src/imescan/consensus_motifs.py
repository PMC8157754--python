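"""Collapse candidate hexamers into IUPAC consensus motifs.

Hexamers that survive validation often differ by a shift or a single base
(e.g. AGATCG vs AAATCG), or are reverse complements of one another. A
shift/orientation-aware alignment distance is computed for every pair,
average-linkage hierarchical clustering groups similar hexamers, and each
cluster is rendered as an IUPAC consensus supported column-wise by at
least ``min_support`` member bases (weakly supported terminal columns are
trimmed). Linkage heights are reported so a manual, dendrogram-guided
grouping can be reproduced with an explicit threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .annotation_io import reverse_complement

_IUPAC_OF_BASES = {
    frozenset("A"): "A", frozenset("C"): "C",
    frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y",
    frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V",
    frozenset("ACGT"): "N",
}

DEFAULT_THRESHOLD = 0.22
DEFAULT_GAP_PENALTY = 0.6


@dataclass
class ConsensusMotif:
    iupac: str
    members: list[str]
    support: list[dict[str, int]]  # per emitted column: base -> member count
    linkage_height: float
    fallback_medoid: bool = False


def _align_cost(a: str, b: str, offset: int, gap_penalty: float) -> float:
    """Mismatches in the overlap plus a per-bp overhang penalty, over len 6."""
    k = len(a)
    if offset >= 0:
        ov_a = a[offset:]
        ov_b = b[: k - offset]
    else:
        ov_a = a[: k + offset]
        ov_b = b[-offset:]
    mism = sum(x != y for x, y in zip(ov_a, ov_b))
    return (mism + gap_penalty * abs(offset)) / k


def best_alignment(
    a: str, b: str, max_offset: int = 2, gap_penalty: float = DEFAULT_GAP_PENALTY
) -> tuple[float, int, bool]:
    """Minimum alignment cost of b (or its reverse complement) against a.

    Returns (cost, offset, is_reverse_complement); offset is the shift of
    b's first base relative to a's first base.
    """
    best = (float("inf"), 0, False)
    for flip, bb in ((False, b), (True, reverse_complement(b))):
        for off in range(-max_offset, max_offset + 1):
            cost = _align_cost(a, bb, off, gap_penalty)
            if cost < best[0]:
                best = (cost, off, flip)
    return best


def kmer_alignment_distance(
    a: str, b: str, max_offset: int = 2, gap_penalty: float = DEFAULT_GAP_PENALTY
) -> float:
    """Orientation-collapsed shift-aware distance between two hexamers in [0, 1]."""
    return min(1.0, best_alignment(a, b, max_offset, gap_penalty)[0])


def distance_matrix(kmers: list[str], **kwargs) -> np.ndarray:
    n = len(kmers)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = kmer_alignment_distance(kmers[i], kmers[j], **kwargs)
    return d


def cluster_kmers(
    distances: np.ndarray, threshold: float = DEFAULT_THRESHOLD
) -> tuple[list[list[int]], np.ndarray]:
    """Average-linkage clustering cut at ``threshold``.

    Returns member-index clusters (deterministic given input order) and the
    linkage matrix (for dendrogram-height reporting).
    """
    n = distances.shape[0]
    if n == 1:
        return [[0]], np.empty((0, 4))
    link = average(squareform(distances, checks=False))
    labels = fcluster(link, t=threshold, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    ordered = sorted(clusters.values(), key=lambda c: c[0])
    return ordered, link


def _cluster_height(members: list[int], distances: np.ndarray) -> float:
    if len(members) < 2:
        return 0.0
    sub = distances[np.ix_(members, members)]
    return float(sub.max())


def build_consensus(
    members: list[str],
    distances: np.ndarray | None = None,
    min_support: int = 2,
    max_offset: int = 2,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
    linkage_height: float = 0.0,
) -> ConsensusMotif:
    """IUPAC consensus of a hexamer cluster.

    Members are oriented and offset-aligned against the cluster medoid
    (minimum summed distance). Per column, the IUPAC code covering all
    observed bases is emitted when the column is supported by at least
    ``min_support`` member bases; weaker columns are trimmed from the ends.
    Single-member clusters return the hexamer itself.
    """
    if not members:
        raise ValueError("cluster must be non-empty")
    if len(members) == 1:
        return ConsensusMotif(
            iupac=members[0],
            members=list(members),
            support=[{b: 1} for b in members[0]],
            linkage_height=linkage_height,
        )
    if distances is None:
        distances = distance_matrix(members, max_offset=max_offset, gap_penalty=gap_penalty)
    medoid_idx = int(np.argmin(distances.sum(axis=1)))
    medoid = members[medoid_idx]
    k = len(medoid)
    aligned: list[tuple[str, int]] = []
    for m in members:
        _, off, flip = best_alignment(medoid, m, max_offset, gap_penalty)
        seq = reverse_complement(m) if flip else m
        aligned.append((seq, off))
    lo = min(off for _, off in aligned)
    hi = max(off + k for _, off in aligned)
    columns: list[dict[str, int]] = []
    for col in range(lo, hi):
        counts: dict[str, int] = {}
        for seq, off in aligned:
            j = col - off
            if 0 <= j < k:
                counts[seq[j]] = counts.get(seq[j], 0) + 1
        columns.append(counts)
    support = [sum(c.values()) for c in columns]
    start, end = 0, len(columns)
    while start < end and support[start] < min_support:
        start += 1
    while end > start and support[end - 1] < min_support:
        end -= 1
    kept = columns[start:end]
    if not kept:
        return ConsensusMotif(
            iupac=medoid,
            members=list(members),
            support=[{b: 1} for b in medoid],
            linkage_height=linkage_height,
            fallback_medoid=True,
        )
    iupac = "".join(_IUPAC_OF_BASES[frozenset(c.keys())] for c in kept)
    return ConsensusMotif(
        iupac=iupac,
        members=list(members),
        support=kept,
        linkage_height=linkage_height,
    )


def collapse_to_consensus(
    kmers: list[str],
    threshold: float = DEFAULT_THRESHOLD,
    min_support: int = 2,
    max_offset: int = 2,
    gap_penalty: float = DEFAULT_GAP_PENALTY,
) -> list[ConsensusMotif]:
    """Distance -> clustering -> per-cluster consensus, end to end."""
    d = distance_matrix(kmers, max_offset=max_offset, gap_penalty=gap_penalty)
    clusters, _ = cluster_kmers(d, threshold=threshold)
    out = []
    for members_idx in clusters:
        members = [kmers[i] for i in members_idx]
        sub = d[np.ix_(members_idx, members_idx)]
        out.append(
            build_consensus(
                members,
                distances=sub,
                min_support=min_support,
                max_offset=max_offset,
                gap_penalty=gap_penalty,
                linkage_height=_cluster_height(members_idx, d),
            )
        )
    return out


def write_meme_like(motifs: list[ConsensusMotif], path: str) -> None:
    """Minimal MEME-like text: alphabet plus per-position base counts."""
    with open(path, "w") as fh:
        fh.write("ALPHABET= ACGT\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.iupac} members={','.join(m.members)}\n")
            fh.write(f"letter-counts: alength= 4 w= {len(m.support)}\n")
            for col in m.support:
                fh.write(
                    " ".join(str(col.get(b, 0)) for b in "ACGT") + "\n"
                )
            fh.write("\n")
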