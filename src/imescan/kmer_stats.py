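"""Hexamer statistics and the four-criterion candidate selection.

A k-mer (default hexamer, k=6) is a candidate IME motif when, comparing
first introns against all other introns, it shows

1. higher sequence conservation (masked/unmasked count ratio) in first
   introns than in other introns,
2. higher relative occurrence in first introns (relative frequency F > 1),
3. a significantly non-uniform positional distribution within first
   introns (positional entropy against a uniform empirical null), and
4. a positional distribution that differs significantly between first and
   other introns (exact contingency test on the binned positions).

Reverse-complementary k-mers are collapsed onto a canonical form (the
lexicographic minimum of the pair), giving (4^k + 4^(k/2)) / 2 classes for
even k — 2080 hexamers. Splice-site-proximal bases (3 bp at each intron
end) are excluded from all counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .annotation_io import IntronRecord, reverse_complement

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_CODE_BASE = np.array(list("ACGT"))


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _rc_code(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of integer-encoded k-mers (vectorized)."""
    out = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        out = out * 4 + (3 - (tmp % 4))
        tmp //= 4
    return out


@lru_cache(maxsize=None)
def canonical_table(k: int) -> tuple[tuple[str, ...], np.ndarray]:
    """All canonical k-mers (sorted) and a 4^k lookup of code -> class index."""
    codes = np.arange(4**k)
    rc = _rc_code(codes, k)
    canon_code = np.minimum(codes, rc)
    uniq = np.unique(canon_code)
    idx_of_code = np.searchsorted(uniq, canon_code)
    kmers = tuple(_decode(c, k) for c in uniq)
    return kmers, idx_of_code


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def n_canonical(k: int) -> int:
    return len(canonical_table(k)[0])


def canonical_kmer(seq: str) -> str | None:
    """Lexicographic minimum of a k-mer and its reverse complement.

    Returns None (uncountable) for sequences containing N or other
    non-ACGT characters.
    """
    if any(b not in "ACGT" for b in seq):
        return None
    rc = reverse_complement(seq)
    return min(seq, rc)


@dataclass
class KmerCountTable:
    """Canonical k-mer counts in first vs other introns, masked and unmasked."""

    k: int
    kmers: tuple[str, ...]
    count_first: np.ndarray
    count_other: np.ndarray
    masked_first: np.ndarray
    masked_other: np.ndarray

    @property
    def total_first(self) -> int:
        return int(self.count_first.sum())

    @property
    def total_other(self) -> int:
        return int(self.count_other.sum())

    def index_of(self, kmer: str) -> int:
        i = np.searchsorted(np.asarray(self.kmers), canonical_kmer(kmer))
        return int(i)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "C_f": self.count_first,
                "C_o": self.count_other,
                "masked_f": self.masked_first,
                "masked_o": self.masked_other,
            },
            index=pd.Index(self.kmers, name="kmer"),
        )


def _window_codes(seq: str, k: int, trim: int) -> np.ndarray:
    """Canonical-classless integer codes of all valid k-windows of the
    trimmed sequence; windows containing non-ACGT characters are dropped.
    Returns (codes, window_start_offsets) with offsets 0-based within the
    untrimmed sequence."""
    core = seq[trim : len(seq) - trim] if trim else seq
    if len(core) < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    codes = _encode(core)
    valid = codes >= 0
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    ok = np.lib.stride_tricks.sliding_window_view(valid, k).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    wcodes = (np.where(win >= 0, win, 0) @ powers)[ok]
    offsets = np.flatnonzero(ok) + trim
    return wcodes, offsets


def count_kmers(
    introns: list[IntronRecord],
    k: int = 6,
    trim: int = 3,
    masked_sequences: dict[str, str] | None = None,
) -> KmerCountTable:
    """Count canonical k-mers over trimmed intron sequences.

    ``introns`` must carry sequences and ``is_first`` flags; masked
    sequences (SNP positions replaced by a non-nucleotide symbol) are
    counted in parallel — a masked window simply fails the ACGT check, so
    masked counts can only be lower.
    """
    kmers, idx_of_code = canonical_table(k)
    n = len(kmers)
    counts = {key: np.zeros(n, dtype=np.int64) for key in ("cf", "co", "mf", "mo")}
    for rec in introns:
        wc, _ = _window_codes(rec.sequence, k, trim)
        key = "cf" if rec.is_first else "co"
        if len(wc):
            counts[key] += np.bincount(idx_of_code[wc], minlength=n)
        if masked_sequences is not None:
            mseq = masked_sequences.get(rec.intron_id, rec.sequence)
            mwc, _ = _window_codes(mseq, k, trim)
            mkey = "mf" if rec.is_first else "mo"
            if len(mwc):
                counts[mkey] += np.bincount(idx_of_code[mwc], minlength=n)
    if masked_sequences is None:
        counts["mf"] = counts["cf"].copy()
        counts["mo"] = counts["co"].copy()
    return KmerCountTable(
        k, kmers, counts["cf"], counts["co"], counts["mf"], counts["mo"]
    )


def relative_frequency(table: KmerCountTable) -> np.ndarray:
    """Relative frequency F per canonical k-mer.

    F = (C_f / sum_j C_f,j) / (C_o / sum_j C_o,j); k-mers absent from other
    introns but present in first introns get +inf.
    """
    tf, to = table.total_first, table.total_other
    if tf == 0 or to == 0:
        raise ValueError("both intron sets must contain at least one k-mer window")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (table.count_first / tf) / (table.count_other / to)
    f[(table.count_other == 0) & (table.count_first > 0)] = np.inf
    f[(table.count_other == 0) & (table.count_first == 0)] = np.nan
    return f


def conservation_rate(table: KmerCountTable, which: str) -> np.ndarray:
    """Masked/unmasked count ratio per k-mer; NaN where the k-mer is absent."""
    if which == "first":
        num, den = table.masked_first, table.count_first
    elif which == "other":
        num, den = table.masked_other, table.count_other
    else:
        raise ValueError("which must be 'first' or 'other'")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = num / den
    return np.where(den > 0, ratio, np.nan)


def positional_profiles(
    introns: list[IntronRecord], k: int = 6, trim: int = 3, bins: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Binned relative start positions per canonical k-mer.

    The relative position of an occurrence is its 1-based first position
    within the untrimmed intron divided by intron length; binned over
    ``bins`` equal bins of (0, 1). Returns (binned_first, binned_other),
    each (n_canonical x bins).
    """
    kmers, idx_of_code = canonical_table(k)
    n = len(kmers)
    out = {True: np.zeros((n, bins), np.int64), False: np.zeros((n, bins), np.int64)}
    for rec in introns:
        wc, offsets = _window_codes(rec.sequence, k, trim)
        if not len(wc):
            continue
        rel = (offsets + 1) / rec.length
        b = np.minimum((rel * bins).astype(np.int64), bins - 1)
        np.add.at(out[rec.is_first], (idx_of_code[wc], b), 1)
    return out[True], out[False]


def positional_entropy(
    positions=None, bins: int = 10, binned: np.ndarray | None = None
) -> tuple[float, np.ndarray]:
    """Shannon entropy (natural log) of binned relative positions.

    Accepts raw relative positions in (0, 1) or pre-binned counts; zero
    bins contribute 0 (0 * log 0 = 0). Undefined (NaN) for zero occurrences.
    """
    if binned is None:
        positions = np.asarray(positions, dtype=float)
        binned, _ = np.histogram(positions, bins=bins, range=(0.0, 1.0))
    binned = np.asarray(binned)
    total = binned.sum()
    if total == 0:
        return float("nan"), binned
    p = binned / total
    s = float(-xlogy(p, p).sum())
    return s, binned


def entropy_empirical_pvalue(
    s_obs: float,
    n_occurrences: int,
    bins: int = 10,
    n_sim: int = 10_000,
    seed=None,
) -> float:
    """Empirical p for low entropy against a uniform positional null.

    Simulates ``n_sim`` multinomial draws of ``n_occurrences`` occurrences
    over ``bins`` uniform bins; p = (1 + #{S_sim <= S_obs}) / (1 + n_sim)
    (add-one estimator, never exactly zero).
    """
    if n_occurrences < 1:
        raise ValueError("entropy p-value needs at least one occurrence")
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n_occurrences, np.full(bins, 1.0 / bins), size=n_sim)
    p = draws / n_occurrences
    s_sim = -xlogy(p, p).sum(axis=1)
    return (1 + int((s_sim <= s_obs + 1e-12).sum())) / (1 + n_sim)


def _log_table_prob(row1: np.ndarray, colsums: np.ndarray) -> np.ndarray:
    """log of the conditional (fixed-margin) probability kernel of 2xC tables:
    sum_c log C(n_c, t_c); the row-margin term is constant and omitted."""
    return (
        gammaln(colsums + 1)
        - gammaln(row1 + 1)
        - gammaln(colsums - row1 + 1)
    ).sum(axis=-1)


def positional_contrast_test(
    binned_first,
    binned_other,
    n_sim: int = 100_000,
    seed=None,
) -> float:
    """Exact conditional homogeneity test of a 2xC binned-position table.

    2x2 tables use the exact hypergeometric (Fisher) test; wider tables use
    a Monte-Carlo exact conditional test: row-1 counts are drawn from the
    multivariate hypergeometric distribution given the margins and tables
    at most as probable as the observed one are counted (add-one estimator).
    """
    r1 = np.asarray(binned_first, dtype=np.int64)
    r2 = np.asarray(binned_other, dtype=np.int64)
    if (r1 < 0).any() or (r2 < 0).any():
        raise ValueError("counts must be non-negative")
    if r1.sum() == 0 and r2.sum() == 0:
        return float("nan")
    keep = (r1 + r2) > 0
    r1, r2 = r1[keep], r2[keep]
    if len(r1) < 2:
        return 1.0
    if len(r1) == 2:
        return float(fisher_exact(np.array([r1, r2]))[1])
    colsums = r1 + r2
    n1 = int(r1.sum())
    rng = np.random.default_rng(seed)
    sim = rng.multivariate_hypergeometric(colsums, n1, size=n_sim, method="marginals")
    logp_obs = _log_table_prob(r1, colsums)
    logp_sim = _log_table_prob(sim, colsums)
    hits = int((logp_sim <= logp_obs + 1e-9).sum())
    return (1 + hits) / (1 + n_sim)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def compute_kmer_statistics(
    introns: list[IntronRecord],
    masked_sequences: dict[str, str] | None = None,
    k: int = 6,
    trim: int = 3,
    bins: int = 10,
    n_sim_entropy: int = 10_000,
    n_sim_contrast: int = 10_000,
    refine_nsim: int = 200_000,
    refine_p: float = 0.02,
    seed=None,
) -> pd.DataFrame:
    """Full per-k-mer statistics table over a first/other intron corpus.

    Columns: C_f, C_o, masked_f, masked_o, F, cons_f, cons_o, S_H,
    p_entropy, q_entropy, p_contrast, q_contrast, c1..c4, candidate.
    k-mers with no occurrence in first introns have undefined positional
    statistics and can never be candidates.

    Both simulation-based tests are adaptive two-stage Monte Carlo: every
    k-mer is screened at the stated simulation count and those with
    p <= ``refine_p`` are re-simulated at ``refine_nsim`` draws. The exact
    tests being approximated have unbounded p-value resolution; without
    refinement the add-one Monte-Carlo floor (1 / (n_sim + 1)) cannot
    survive FDR adjustment across thousands of k-mers.
    """
    rng = np.random.default_rng(seed)
    table = count_kmers(introns, k=k, trim=trim, masked_sequences=masked_sequences)
    bin_f, bin_o = positional_profiles(introns, k=k, trim=trim, bins=bins)
    df = table.as_frame()
    df["F"] = relative_frequency(table)
    df["cons_f"] = conservation_rate(table, "first")
    df["cons_o"] = conservation_rate(table, "other")

    n = len(df)
    s_h = np.full(n, np.nan)
    p_ent = np.full(n, np.nan)
    p_con = np.full(n, np.nan)
    for i in range(n):
        nf = int(bin_f[i].sum())
        if nf == 0:
            continue
        s_h[i], _ = positional_entropy(binned=bin_f[i])
        p_ent[i] = entropy_empirical_pvalue(
            s_h[i], nf, bins=bins, n_sim=n_sim_entropy, seed=rng
        )
        if p_ent[i] <= refine_p and refine_nsim > n_sim_entropy:
            p_ent[i] = entropy_empirical_pvalue(
                s_h[i], nf, bins=bins, n_sim=refine_nsim, seed=rng
            )
        p_con[i] = positional_contrast_test(
            bin_f[i], bin_o[i], n_sim=n_sim_contrast, seed=rng
        )
        if p_con[i] <= refine_p and refine_nsim > n_sim_contrast:
            p_con[i] = positional_contrast_test(
                bin_f[i], bin_o[i], n_sim=refine_nsim, seed=rng
            )
    df["S_H"] = s_h
    df["p_entropy"] = p_ent
    df["q_entropy"] = bh_fdr(p_ent)
    df["p_contrast"] = p_con
    df["q_contrast"] = bh_fdr(p_con)
    return df


def select_candidates(rows: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Apply the four candidate criteria (strict inequalities; ties fail).

    Adds boolean c1..c4 and candidate columns; k-mers with any missing
    statistic are excluded (logged)."""
    df = rows.copy()
    needed = ["cons_f", "cons_o", "F", "q_entropy", "q_contrast"]
    missing = df[needed].isna().any(axis=1)
    if missing.any():
        logger.info(
            "%d k-mers lack complete statistics and are excluded", int(missing.sum())
        )
    df["c1"] = (df["cons_f"] > df["cons_o"]) & ~missing
    df["c2"] = (df["F"] > 1.0) & ~missing
    df["c3"] = (df["q_entropy"] < alpha) & ~missing
    df["c4"] = (df["q_contrast"] < alpha) & ~missing
    df["candidate"] = df[["c1", "c2", "c3", "c4"]].all(axis=1)
    return df


def write_kmer_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="kmer")
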