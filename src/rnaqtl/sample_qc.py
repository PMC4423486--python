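"""Sample-level quality control.

Three independent checks: expression-PCA outliers (robust z on a chosen
component), heterozygosity-rate bounds on non-imputed hard calls, and a sex
consistency check from XIST / chromosome-Y expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .dataio import (
    HET,
    MISSING,
    SEX_FEMALE,
    SEX_MALE,
    SEX_UNKNOWN,
    ExpressionMatrix,
    GenotypeTable,
    SampleSheet,
)

log = logging.getLogger(__name__)

FLAG_EXPRESSION_OUTLIER = "expression_outlier"
FLAG_LOW_HET = "low_het"
FLAG_HIGH_HET = "high_het"
FLAG_SEX_MISMATCH = "sex_mismatch"


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # genes x components
    explained_variance: np.ndarray


@dataclass
class QCReport:
    """Per-sample QC summary: PC scores, het rate, predicted sex, flags."""

    pc_scores: pd.DataFrame
    het_rate: pd.Series
    n_snps_used: pd.Series
    sex_predicted: pd.Series
    flags: dict = field(default_factory=dict)  # sample -> set of flags

    def flagged(self) -> set:
        return {s for s, f in self.flags.items() if f}

    def to_frame(self) -> pd.DataFrame:
        samples = self.pc_scores.index
        return pd.DataFrame(
            {
                "pc1": self.pc_scores.iloc[:, 0],
                "het_rate": self.het_rate.reindex(samples),
                "n_snps_used": self.n_snps_used.reindex(samples),
                "sex_predicted": self.sex_predicted.reindex(samples),
                "flags": [",".join(sorted(self.flags.get(s, set()))) for s in samples],
            },
            index=samples,
        )


def expression_pca(expr: ExpressionMatrix, n_components: int | None = None) -> PCAResult:
    """PCA over the sample covariance of a normalized expression matrix.

    Expects quantile-normalized, log2-scale values.  Components are ordered
    by explained variance (descending); score signs are arbitrary.  Constant
    gene rows are dropped.
    """
    X = expr.values.to_numpy(float)
    if X.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    keep = X.std(axis=1) > 0
    if (~keep).any():
        log.info("dropping %d constant genes before PCA", int((~keep).sum()))
    X = X[keep]
    Xc = X - X.mean(axis=1, keepdims=True)
    k = min(X.shape[0], X.shape[1] - 1)
    if n_components is not None:
        k = min(k, n_components)
    # SVD of the gene-centered matrix: right singular vectors are the sample PCs
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (X.shape[1] - 1)
    comp = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        (Vt[:k].T * s[:k]), index=expr.values.columns, columns=comp
    )
    loadings = pd.DataFrame(U[:, :k], index=expr.values.index[keep], columns=comp)
    return PCAResult(scores=scores, loadings=loadings, explained_variance=var[:k])


def flag_expression_outliers(
    scores: pd.DataFrame,
    component: int = 0,
    method: str = "zscore",
    cutoff: float = 4.0,
) -> set:
    """Samples whose chosen-component score is extreme.

    ``zscore``: |robust z| > cutoff, with z = (x - median) / (1.4826 MAD);
    when the MAD is zero any deviation from the median counts as infinite.
    ``threshold``: |score| > cutoff on the raw scale.
    """
    if scores.shape[0] == 0:
        raise ValueError("empty score matrix")
    x = scores.iloc[:, component].to_numpy(float)
    if method == "threshold":
        mask = np.abs(x) > cutoff
    elif method == "zscore":
        med = np.median(x)
        mad = np.median(np.abs(x - med)) * 1.4826
        dev = np.abs(x - med)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(dev == 0, 0.0, np.where(mad == 0, np.inf, dev / max(mad, 1e-300)))
        mask = z > cutoff
    else:
        raise ValueError(f"unknown method {method!r}")
    return set(scores.index[mask])


def heterozygosity_rate(
    gt: GenotypeTable,
    min_maf: float = 0.05,
    min_depth_reads: int = 10,
    min_sites: int = 50,
) -> tuple[pd.Series, pd.Series]:
    """Per-sample heterozygosity rate over qualifying sites.

    A site qualifies for a sample when the variant MAF >= ``min_maf`` and
    that sample's read depth >= ``min_depth_reads``.  The rate is
    (#het calls) / (#non-missing calls) over qualifying sites; samples with
    fewer than ``min_sites`` qualifying non-missing calls get NaN.
    Returns (het_rate, n_snps_used).
    """
    calls = gt.calls.to_numpy()
    maf_ok = (gt.variants["maf"].to_numpy(float) >= min_maf)[:, None]
    if gt.depth is not None:
        depth_ok = gt.depth.to_numpy() >= min_depth_reads
    else:
        depth_ok = np.ones_like(calls, dtype=bool)
    qual = maf_ok & depth_ok & (calls != MISSING)
    n_used = qual.sum(axis=0)
    if n_used.max() == 0:
        raise ValueError("no qualifying sites for any sample")
    n_het = ((calls == HET) & qual).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(n_used >= min_sites, n_het / np.maximum(n_used, 1), np.nan)
    samples = gt.calls.columns
    return (
        pd.Series(rate, index=samples, name="het_rate"),
        pd.Series(n_used, index=samples, name="n_snps_used"),
    )


def filter_heterozygosity(
    rates: pd.Series, low: float = 0.2, high: float = 0.4
) -> dict:
    """Flag samples with rate strictly below ``low`` or strictly above ``high``.

    Bounds are exclusive: a rate of exactly 0.2 or 0.4 is not flagged.
    NaN rates (too few sites) are never flagged here.
    """
    flags: dict = {}
    for s, r in rates.items():
        if np.isnan(r):
            continue
        if r < low:
            flags[s] = FLAG_LOW_HET
        elif r > high:
            flags[s] = FLAG_HIGH_HET
    return flags


def sex_check(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    xist_gene: str,
    chry_genes: tuple | list,
    random_state: int = 0,
) -> tuple[pd.Series, set]:
    """Predict sex from (XIST, mean chrY) expression and flag mismatches.

    A 2-means split in the (XIST, mean-chrY) plane; the cluster with higher
    XIST and lower chrY is called female.  Samples whose prediction differs
    from a non-unknown ``annotated_sex`` are flagged.
    """
    samples = expr.values.columns
    chry_present = [g for g in chry_genes if g in expr.values.index]
    if xist_gene not in expr.values.index or not chry_present:
        warnings.warn("XIST or chrY genes absent; sex predictions unknown")
        return pd.Series(SEX_UNKNOWN, index=samples), set()
    xist = expr.values.loc[xist_gene].to_numpy(float)
    chry = expr.values.loc[chry_present].mean(axis=0).to_numpy(float)
    pts = np.column_stack([xist, chry])
    # standardize so neither axis dominates
    pts = (pts - pts.mean(axis=0)) / np.maximum(pts.std(axis=0), 1e-12)
    km = KMeans(n_clusters=2, n_init=10, random_state=random_state).fit(pts)
    lab = km.labels_
    # female cluster: higher XIST, lower chrY
    score = km.cluster_centers_[:, 0] - km.cluster_centers_[:, 1]
    female_label = int(np.argmax(score))
    pred = pd.Series(
        np.where(lab == female_label, SEX_FEMALE, SEX_MALE), index=samples
    )
    annotated = sheet.data["annotated_sex"].reindex(samples)
    mismatched = set(
        samples[(annotated != SEX_UNKNOWN) & annotated.notna() & (annotated != pred)]
    )
    return pred, mismatched


def run_qc(
    expr_norm: ExpressionMatrix,
    gt: GenotypeTable,
    sheet: SampleSheet,
    xist_gene: str = "XIST",
    chry_genes: tuple = ("RPS4Y1", "EIF1AY", "DDX3Y"),
    outlier_component: int = 0,
    outlier_cutoff: float = 4.0,
    het_low: float = 0.2,
    het_high: float = 0.4,
    min_maf: float = 0.05,
    min_depth_reads: int = 10,
) -> QCReport:
    """Run all three QC checks and assemble a :class:`QCReport`."""
    pca = expression_pca(expr_norm)
    outliers = flag_expression_outliers(
        pca.scores, component=outlier_component, cutoff=outlier_cutoff
    )
    het, n_used = heterozygosity_rate(
        gt, min_maf=min_maf, min_depth_reads=min_depth_reads
    )
    het_flags = filter_heterozygosity(het, low=het_low, high=het_high)
    sex_pred, sex_mism = sex_check(expr_norm, sheet, xist_gene, chry_genes)
    flags: dict = {s: set() for s in expr_norm.values.columns}
    for s in outliers:
        flags.setdefault(s, set()).add(FLAG_EXPRESSION_OUTLIER)
    for s, f in het_flags.items():
        flags.setdefault(s, set()).add(f)
    for s in sex_mism:
        flags.setdefault(s, set()).add(FLAG_SEX_MISMATCH)
    return QCReport(
        pc_scores=pca.scores,
        het_rate=het,
        n_snps_used=n_used,
        sex_predicted=sex_pred,
        flags=flags,
    )
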