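"""First-intron feature table and the expression-level classifier.

Casts IME as a prediction problem: can features of a gene's first intron
alone separate highly from lowly expressed genes? The 25 features cover
geometry (length, distances to TSS and translation start), sequence
content (base and canonical-dimer composition, splice sites excluded), the
pentamer log-odds score, population variation (SNPs per bp), methylation
(differentially methylated positions per context), conserved non-coding
positions, transposable elements, intron retention in alternative
isoforms, and a normalized minimum folding energy consumed from a
pluggable per-intron table. A random forest with fixed hyperparameters
(6000 trees, depth 10, min split 5, min leaf 2, sqrt features) is
evaluated by 10-fold cross-validated ROC and a held-out 80/20 accuracy;
feature relevance via permutation mean-decrease-in-accuracy (5 repeats)
and exact interventional Shapley attribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from ._treeshap import interventional_shap
from .annotation_io import GenomeAnnotation, IntronRecord
from .coexpression import PentamerLogOdds, imeter_like_score
from .variants_io import SnpTable

logger = logging.getLogger(__name__)

DIMER_CLASSES = ("AA", "AC", "AG", "AT", "CA", "CC", "CG", "GA", "GC", "TA")
_DIMER_CANON = {
    d: min(d, d.translate(str.maketrans("ACGT", "TGCA"))[::-1])
    for d in ("".join((a, b)) for a in "ACGT" for b in "ACGT")
}

FEATURE_COLUMNS = (
    "length",
    "distance_CDS",
    "distance_TSS",
    "imeter",
    "SNP_per_bp",
    "DMR_C",
    "DMR_CG",
    "n_transposons",
    "IR",
    "CNS",
    "min_fold_energy",
    "A",
    "T",
    "C",
    "G",
) + DIMER_CLASSES


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def _interval_trees(intervals) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in intervals or ():
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def _covered_positions(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> int:
    tree = trees.get(chrom)
    if tree is None:
        return 0
    covered = 0
    for iv in tree.overlap(start, end):
        covered += min(end, iv.end) - max(start, iv.begin)
    return covered


def _count_overlapping(trees: dict[str, IntervalTree], chrom: str, start: int, end: int) -> int:
    tree = trees.get(chrom)
    return len(tree.overlap(start, end)) if tree is not None else 0


def _retained(rec: IntronRecord, annotation: GenomeAnnotation) -> int:
    gene = annotation.gene(rec.gene_id)
    for tx in gene.transcripts:
        if tx.id == rec.transcript_id:
            continue
        for s, e in tx.exons:
            if s < rec.end and rec.start < e:
                return 1
    return 0


def build_feature_table(
    introns: list[IntronRecord],
    annotation: GenomeAnnotation,
    imeter_weights: PentamerLogOdds | None = None,
    snps: SnpTable | None = None,
    dmr_c=None,
    dmr_cg=None,
    cns=None,
    te=None,
    fold_energy: dict[str, float] | None = None,
    trim: int = 3,
) -> pd.DataFrame:
    """Per-gene 25-feature table over first introns (one row per gene).

    BED-derived inputs are optional; absent ones contribute zeros (logged).
    Composition is computed on the splice-site-trimmed sequence; dimer and
    interval features are normalized by intron length; the folding energy
    is divided by (intron length + 40) to account for the 20 bp exon
    overhang on each side used when it was computed.
    """
    for name, data in (("dmr_c", dmr_c), ("dmr_cg", dmr_cg), ("cns", cns), ("te", te)):
        if data is None:
            logger.info("feature input %s absent: feature set to 0", name)
    dmr_c_t = _interval_trees(dmr_c)
    dmr_cg_t = _interval_trees(dmr_cg)
    cns_t = _interval_trees(cns)
    te_t = _interval_trees(te)
    fold_energy = fold_energy or {}
    snp_pos: dict[str, np.ndarray] = {}
    if snps is not None:
        for chrom, sub in snps.sites.groupby("chrom"):
            snp_pos[chrom] = np.sort(sub["pos"].to_numpy())

    rows = {}
    for rec in introns:
        if not rec.is_first or not rec.sequence:
            continue
        length = rec.length
        core = rec.sequence[trim : len(rec.sequence) - trim]
        n_valid = sum(core.count(b) for b in "ACGT")
        comp = {
            b: (core.count(b) / n_valid if n_valid else 0.0) for b in "ATCG"
        }
        dimers = dict.fromkeys(DIMER_CLASSES, 0.0)
        for i in range(len(core) - 1):
            canon = _DIMER_CANON.get(core[i : i + 2])
            if canon is not None:
                dimers[canon] += 1
        for d in dimers:
            dimers[d] /= length
        if rec.chrom in snp_pos:
            pos = snp_pos[rec.chrom]
            n_snp = int(np.searchsorted(pos, rec.end) - np.searchsorted(pos, rec.start))
        else:
            n_snp = 0
        energy = fold_energy.get(rec.intron_id, 0.0)
        row = {
            "length": float(length),
            "distance_CDS": float(rec.dist_cds),
            "distance_TSS": float(rec.dist_tss),
            "imeter": (
                imeter_like_score(rec.sequence, imeter_weights)
                if imeter_weights is not None
                else 0.0
            ),
            "SNP_per_bp": n_snp / length,
            "DMR_C": float(_covered_positions(dmr_c_t, rec.chrom, rec.start, rec.end)),
            "DMR_CG": float(_covered_positions(dmr_cg_t, rec.chrom, rec.start, rec.end)),
            "n_transposons": _count_overlapping(te_t, rec.chrom, rec.start, rec.end) / length,
            "IR": float(_retained(rec, annotation)),
            "CNS": _covered_positions(cns_t, rec.chrom, rec.start, rec.end) / length,
            "min_fold_energy": energy / (length + 40),
            "A": comp["A"],
            "T": comp["T"],
            "C": comp["C"],
            "G": comp["G"],
        }
        row.update(dimers)
        rows[rec.gene_id] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.reindex(columns=FEATURE_COLUMNS)


def label_expression_classes(expr: pd.DataFrame, mode: str = "median") -> pd.Series:
    """High/low labels from per-gene median expression.

    Median mode labels every gene (ties at the median go low); quartile
    mode labels only the top (high) and bottom (low) quartiles, the middle
    half stays NaN and is excluded from training.
    """
    med = expr.median(axis=1)
    if len(med) < 8:
        raise ValueError("need at least 8 genes to define expression classes")
    if mode == "median":
        thr = med.median()
        return (med > thr).astype(int)
    if mode == "quartile":
        lo, hi = med.quantile([0.25, 0.75])
        labels = pd.Series(np.nan, index=med.index)
        labels[med <= lo] = 0
        labels[med >= hi] = 1
        return labels
    raise ValueError("mode must be 'median' or 'quartile'")


RF_PARAMS = dict(
    n_estimators=6000,
    max_depth=10,
    min_samples_split=5,
    min_samples_leaf=2,
    max_features="sqrt",
)


@dataclass
class ModelReport:
    model: RandomForestClassifier
    feature_names: list[str]
    cv_aucs: list[float]
    mean_auc: float
    roc_curves: list[tuple[np.ndarray, np.ndarray]]
    holdout_accuracy: float
    X_test: pd.DataFrame
    y_test: np.ndarray
    seeds: dict[str, int] = field(default_factory=dict)


def train_and_evaluate(
    features: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    n_estimators: int = RF_PARAMS["n_estimators"],
    n_folds: int = 10,
    test_size: float = 0.2,
) -> ModelReport:
    """Fit the random forest; report 10-fold CV ROC/AUC and held-out accuracy.

    One master seed fans out to the split, the CV shuffling and the forest
    bootstrap; all sub-seeds are recorded in the report.
    """
    mask = labels.notna()
    X = features.loc[labels.index[mask]]
    y = labels[mask].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    ss = np.random.SeedSequence(seed)
    seed_split, seed_cv, seed_rf = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    params = dict(RF_PARAMS, n_estimators=n_estimators)

    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed_split
    )
    model = RandomForestClassifier(random_state=seed_rf, **params)
    model.fit(X_train, y_train)
    holdout_accuracy = accuracy_score(y_test, model.predict(X_test))

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed_cv)
    aucs, curves = [], []
    for tr, te in skf.split(X, y):
        m = RandomForestClassifier(random_state=seed_rf, **params)
        m.fit(X.iloc[tr], y[tr])
        prob = m.predict_proba(X.iloc[te])[:, 1]
        aucs.append(float(roc_auc_score(y[te], prob)))
        fpr, tpr, _ = roc_curve(y[te], prob)
        curves.append((fpr, tpr))
    return ModelReport(
        model=model,
        feature_names=list(X.columns),
        cv_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        roc_curves=curves,
        holdout_accuracy=float(holdout_accuracy),
        X_test=X_test,
        y_test=y_test,
        seeds={"split": seed_split, "cv": seed_cv, "forest": seed_rf},
    )


def permutation_importance(
    model,
    X_test: pd.DataFrame,
    y_test,
    repeats: int = 5,
    seed: int = 0,
) -> pd.Series:
    """Mean decrease in held-out accuracy over seeded column permutations."""
    res = _sk_permutation_importance(
        model,
        X_test,
        y_test,
        scoring="accuracy",
        n_repeats=repeats,
        random_state=seed,
    )
    return pd.Series(res.importances_mean, index=X_test.columns, name="MDA")


def shapley_attribution(
    model,
    features: pd.DataFrame,
    background: pd.DataFrame | None = None,
    max_samples: int = 50,
    max_background: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Per-sample, per-feature exact interventional Shapley attributions.

    Attributions are additive: per sample they sum (with the base value) to
    the model's class-1 probability. Foreground/background are seeded
    subsamples when the inputs exceed the caps.
    """
    rng = np.random.default_rng(seed)
    if background is None:
        background = features
    fore = features
    if len(fore) > max_samples:
        fore = fore.iloc[rng.choice(len(fore), max_samples, replace=False)]
    back = background
    if len(back) > max_background:
        back = back.iloc[rng.choice(len(back), max_background, replace=False)]
    phi, _ = interventional_shap(model, fore.to_numpy(), back.to_numpy())
    base = float(model.predict_proba(back)[:, 1].mean())
    return pd.DataFrame(phi, index=fore.index, columns=fore.columns), base


def mean_abs_shap(attributions: pd.DataFrame) -> pd.Series:
    return attributions.abs().mean(axis=0).sort_values(ascending=False)
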