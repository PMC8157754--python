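"""Co-expression and expression-level validation of candidate motifs.

The functional argument runs through effect sizes: if a first-intron motif
mediates expression enhancement, the genes that carry it should (i) be
co-expressed — their pairwise Pearson correlations across conditions sit
higher than those of gene sets defined by occurrence-matched control
hexamers — and (ii) sit at a higher expression level than the background.
Both comparisons are summarised as Cohen's d with the pooled-SD formula.

The module also carries a pentamer log-odds scorer in the spirit of
IMEter: pentamer frequencies of TSS-proximal introns are contrasted with
TSS-distal introns, and a sequence scores the sum of its pentamer weights.
The scorer is trained on the corpus at hand rather than on an external
training set, which keeps it self-contained; reports state this.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation_io import IntronRecord, reverse_complement
from .kmer_stats import KmerCountTable, canonical_kmer

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_tsv(path: str, provenance: str = "condition") -> pd.DataFrame:
    """Gene x sample matrix from TSV (header = sample ids, first column = gene)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    df.attrs["provenance"] = provenance
    return df


def upper_quartile_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Upper-quartile normalization followed by ln(x + 1).

    Each sample is scaled so that its 75th percentile over expressed genes
    (value > 0) equals the across-sample mean of those percentiles.
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("counts must be non-negative")
    uq = np.empty(values.shape[1])
    for j in range(values.shape[1]):
        col = values[:, j]
        expressed = col[col > 0]
        if expressed.size == 0:
            raise ValueError(f"sample {counts.columns[j]!r} has all-zero counts")
        uq[j] = np.percentile(expressed, 75)
    target = uq.mean()
    scaled = values * (target / uq)
    out = pd.DataFrame(np.log1p(scaled), index=counts.index, columns=counts.columns)
    out.attrs["provenance"] = counts.attrs.get("provenance", "accession")
    return out


def filter_expressed_genes(
    expr: pd.DataFrame,
    introns: list[IntronRecord],
    mode: str = "condition",
    condition_threshold: float = 0.1,
    accession_threshold: float = 1.0,
) -> list[str]:
    """Genes usable for expression analysis.

    Both modes require the gene to possess a first intron. Condition mode
    additionally requires an annotated 5'UTR-overlapping context is checked
    by the caller via ``utr5_genes``; here the median log expression must
    exceed ``condition_threshold``. Accession mode requires median
    expression > ``accession_threshold``.
    """
    first_genes = {r.gene_id for r in introns if r.is_first}
    med = expr.median(axis=1)
    if mode == "condition":
        ok = med > condition_threshold
    elif mode == "accession":
        ok = med > accession_threshold
    else:
        raise ValueError("mode must be 'condition' or 'accession'")
    genes = [g for g in expr.index[ok] if g in first_genes]
    if not genes:
        logger.warning("expressed-gene filter produced an empty gene list")
    return genes


def utr5_genes(introns: list[IntronRecord]) -> set[str]:
    """Genes whose first intron analysis context includes a 5'UTR flag source."""
    return {r.gene_id for r in introns if r.is_first and r.in_utr5}


# ---------------------------------------------------------------------------
# effect sizes

@dataclass
class EffectSizeResult:
    """Cohen's d (pooled SD) with group sizes and a context-dependent p."""

    cohens_d: float
    n1: int
    n2: int
    p: float = float("nan")


def cohens_d(x, y) -> EffectSizeResult:
    """Pooled-SD Cohen's d; positive when the first group's mean is larger."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d requires at least two values per group")
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    pooled = math.sqrt(((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2))
    if pooled == 0:
        return EffectSizeResult(float("nan"), n1, n2)
    return EffectSizeResult((x.mean() - y.mean()) / pooled, n1, n2)


def pairwise_correlations(
    expr: pd.DataFrame,
    gene_set,
    max_pairs: int = 200_000,
    seed=None,
) -> np.ndarray:
    """Pearson r across samples for every unordered gene pair of the set.

    Zero-variance genes are dropped (their correlations are undefined).
    If the number of pairs exceeds ``max_pairs`` a seeded uniform subsample
    of pairs is returned instead.
    """
    genes = [g for g in gene_set if g in expr.index]
    if len(genes) < 2:
        raise ValueError("need at least two genes with expression")
    mat = expr.loc[genes].to_numpy(dtype=float)
    sd = mat.std(axis=1)
    keep = sd > 0
    if not keep.all():
        logger.warning("%d zero-variance genes skipped", int((~keep).sum()))
        mat = mat[keep]
    m = mat.shape[0]
    if m < 2:
        raise ValueError("fewer than two genes with expression variance")
    corr = np.corrcoef(mat)
    iu = np.triu_indices(m, k=1)
    r = corr[iu]
    if len(r) > max_pairs:
        rng = np.random.default_rng(seed)
        r = rng.choice(r, size=max_pairs, replace=False)
    return r


def expression_level_effect(
    gene_set, expr: pd.DataFrame, background=None
) -> EffectSizeResult:
    """Cohen's d (+ Welch t p) of per-gene median expression: set vs background."""
    if background is None:
        background = list(expr.index)
    med = expr.median(axis=1)
    x = med.loc[[g for g in gene_set if g in med.index]].to_numpy()
    y = med.loc[[g for g in background if g in med.index]].to_numpy()
    if len(x) < 2:
        logger.warning("gene set too small for an expression-level effect")
        return EffectSizeResult(float("nan"), len(x), len(y))
    res = cohens_d(x, y)
    res.p = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
    return res


# ---------------------------------------------------------------------------
# motif gene sets and matched controls

def motif_gene_set(motif: str, first_introns: list[IntronRecord]) -> list[str]:
    """Genes whose first intron contains the k-mer or its reverse complement."""
    rc = reverse_complement(motif)
    genes = {
        r.gene_id
        for r in first_introns
        if r.is_first and (motif in r.sequence or rc in r.sequence)
    }
    return sorted(genes)


def matched_control_hexamers(
    target: str, table: KmerCountTable, tol: float = 0.10
) -> list[str]:
    """Canonical k-mers with first-intron counts within +/- tol of the target's."""
    idx = table.index_of(target)
    c = int(table.count_first[idx])
    lo = math.ceil((1 - tol) * c)
    hi = math.floor((1 + tol) * c)
    out = [
        km
        for j, km in enumerate(table.kmers)
        if j != idx and lo <= table.count_first[j] <= hi
    ]
    if not out:
        logger.warning("no occurrence-matched controls for %s (count %d)", target, c)
    return out


@dataclass
class CoexpressionEffect:
    motif: str
    mean_d: float
    per_control: pd.DataFrame
    n_motif_genes: int


def coexpression_effect(
    motif: str,
    expr: pd.DataFrame,
    first_introns: list[IntronRecord],
    table: KmerCountTable,
    gene_filter=None,
    tol: float = 0.10,
    max_controls: int | None = None,
    max_pairs: int = 200_000,
    seed=None,
) -> CoexpressionEffect | None:
    """Mean Cohen's d of the motif set's pair correlations vs matched controls.

    For each occurrence-matched control hexamer, Cohen's d is computed
    between the motif gene set's pairwise-correlation vector and the
    control gene set's; the mean over controls is the motif's co-expression
    effect. Returns None when no control yields a comparable gene set.
    """
    rng = np.random.default_rng(seed)
    allowed = set(gene_filter) if gene_filter is not None else None

    def _genes(kmer: str) -> list[str]:
        genes = motif_gene_set(kmer, first_introns)
        if allowed is not None:
            genes = [g for g in genes if g in allowed]
        return [g for g in genes if g in expr.index]

    motif_genes = _genes(motif)
    if len(motif_genes) < 2:
        logger.warning("motif %s has <2 expressed genes", motif)
        return None
    r_motif = pairwise_correlations(expr, motif_genes, max_pairs, rng)
    controls = matched_control_hexamers(motif, table, tol=tol)
    if max_controls is not None and len(controls) > max_controls:
        controls = list(rng.choice(controls, size=max_controls, replace=False))
    rows = []
    for ctrl in controls:
        ctrl_genes = _genes(ctrl)
        if len(ctrl_genes) < 2:
            continue
        r_ctrl = pairwise_correlations(expr, ctrl_genes, max_pairs, rng)
        d = cohens_d(r_motif, r_ctrl)
        rows.append((ctrl, d.cohens_d, len(ctrl_genes), d.n1, d.n2))
    if not rows:
        return None
    per_control = pd.DataFrame(
        rows, columns=["control", "cohens_d", "n_genes", "n_pairs_motif", "n_pairs_control"]
    )
    return CoexpressionEffect(
        motif=motif,
        mean_d=float(per_control["cohens_d"].mean()),
        per_control=per_control,
        n_motif_genes=len(motif_genes),
    )


def refine_candidates(
    effects: dict[str, CoexpressionEffect | None], threshold: float = 0.05
) -> list[str]:
    """Pure threshold on the mean co-expression effect (order-preserving)."""
    return [
        m
        for m, eff in effects.items()
        if eff is not None and eff.mean_d > threshold
    ]


# ---------------------------------------------------------------------------
# pentamer log-odds scorer (IMEter-style)

@dataclass
class PentamerLogOdds:
    """Canonical pentamer log2-odds weights (TSS-proximal vs distal corpora)."""

    weights: dict[str, float]
    pseudocount: float
    n_proximal_windows: int
    n_distal_windows: int
    k: int = 5

    def weight(self, kmer: str) -> float:
        canon = canonical_kmer(kmer)
        if canon is None:
            return 0.0
        return self.weights.get(canon, 0.0)


def _pentamer_counts(introns: list[IntronRecord], k: int, trim: int) -> dict[str, int]:
    from .kmer_stats import _window_codes, canonical_table

    kmers, idx_of_code = canonical_table(k)
    acc = np.zeros(len(kmers), np.int64)
    for rec in introns:
        wc, _ = _window_codes(rec.sequence, k, trim)
        if len(wc):
            acc += np.bincount(idx_of_code[wc], minlength=len(kmers))
    return dict(zip(kmers, acc.tolist()))


def train_pentamer_logodds(
    proximal: list[IntronRecord],
    distal: list[IntronRecord],
    pseudocount: float = 1.0,
    k: int = 5,
    trim: int = 3,
) -> PentamerLogOdds:
    """log2 of proximal vs distal canonical pentamer relative frequencies."""
    if not proximal or not distal:
        raise ValueError("both corpora must be non-empty")
    cp = _pentamer_counts(proximal, k, trim)
    cd = _pentamer_counts(distal, k, trim)
    tp = sum(cp.values()) + pseudocount * len(cp)
    td = sum(cd.values()) + pseudocount * len(cd)
    weights = {
        km: math.log2(((cp[km] + pseudocount) / tp) / ((cd[km] + pseudocount) / td))
        for km in cp
    }
    return PentamerLogOdds(
        weights=weights,
        pseudocount=pseudocount,
        n_proximal_windows=sum(cp.values()),
        n_distal_windows=sum(cd.values()),
        k=k,
    )


def imeter_like_score(sequence: str, weights: PentamerLogOdds) -> float:
    """Sum of canonical pentamer weights over all step-1 windows."""
    k = weights.k
    if len(sequence) < k:
        logger.warning("sequence shorter than %d bp scores 0", k)
        return 0.0
    return float(
        sum(weights.weight(sequence[i : i + k]) for i in range(len(sequence) - k + 1))
    )


def rank_by_imeter(
    first_introns: list[IntronRecord], weights: PentamerLogOdds
) -> pd.Series:
    """Per-gene IMEter-style score of the first intron, descending."""
    scores = {
        r.gene_id: imeter_like_score(r.sequence, weights)
        for r in first_introns
        if r.is_first
    }
    return pd.Series(scores).sort_values(ascending=False)


def compare_to_imeter_set(
    gene_set,
    imeter_ranking: pd.Series,
    expr: pd.DataFrame,
    remove_overlap: bool = False,
    max_pairs: int = 200_000,
    seed=None,
) -> EffectSizeResult:
    """Cohen's d of pair correlations: motif gene set vs size-matched top-IMEter set.

    With ``remove_overlap`` genes shared between the two sets are removed
    from the IMEter set before the size match."""
    rng = np.random.default_rng(seed)
    genes = [g for g in gene_set if g in expr.index]
    ranking = imeter_ranking[imeter_ranking.index.isin(expr.index)]
    if remove_overlap:
        ranking = ranking[~ranking.index.isin(genes)]
    top = list(ranking.index[: len(genes)])
    r_set = pairwise_correlations(expr, genes, max_pairs, rng)
    r_top = pairwise_correlations(expr, top, max_pairs, rng)
    return cohens_d(r_set, r_top)


def compare_to_random_sets(
    gene_set,
    expr: pd.DataFrame,
    n_draws: int = 10,
    max_pairs: int = 200_000,
    seed=None,
) -> EffectSizeResult:
    """Mean Cohen's d of pair correlations vs seeded random equal-size gene sets."""
    rng = np.random.default_rng(seed)
    genes = [g for g in gene_set if g in expr.index]
    r_set = pairwise_correlations(expr, genes, max_pairs, rng)
    pool = np.asarray([g for g in expr.index if g not in set(genes)])
    ds = []
    for _ in range(n_draws):
        draw = rng.choice(pool, size=len(genes), replace=False)
        r_rand = pairwise_correlations(expr, list(draw), max_pairs, rng)
        ds.append(cohens_d(r_set, r_rand).cohens_d)
    mean_d = float(np.mean(ds))
    return EffectSizeResult(mean_d, len(r_set), len(r_set))
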