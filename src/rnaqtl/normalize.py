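"""Expression normalization and covariate correction.

The eQTL stage consumes a residual expression matrix produced here:
raw counts -> TMM scaling -> log2, per-gene centering and scaling ->
OLS removal of sample covariates -> removal of leading expression PCs.
Quantile normalization (used by the expression-outlier QC) also lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import ExpressionMatrix

log = logging.getLogger(__name__)


def quantile_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample to share the cross-sample mean quantile profile.

    After the transform, each sample's sorted value vector equals the mean of
    the per-sample sorted vectors; ties within a sample receive the mean of
    the quantile values their ranks span.  Idempotent on tie-free input.
    """
    X = expr.values.to_numpy(float)
    G, S = X.shape
    if S < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if (X.sum(axis=0) == 0).any():
        bad = [c for c, z in zip(expr.values.columns, X.sum(axis=0) == 0) if z]
        raise ValueError(f"all-zero sample(s): {bad}")
    mean_sorted = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(S):
        order = np.argsort(X[:, j], kind="stable")
        ranks = np.empty(G, dtype=int)
        ranks[order] = np.arange(G)
        col = mean_sorted[ranks]
        # ties get the mean of the quantile values they span
        vals = X[:, j]
        s = pd.Series(col)
        out[:, j] = s.groupby(vals, sort=False).transform("mean").to_numpy()
    return expr.copy_with(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns)
    )


def _choose_tmm_reference(X: np.ndarray) -> int:
    """Sample whose upper quartile of scaled counts is closest to the mean."""
    lib = X.sum(axis=0)
    f75 = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(X.shape[1])])
    return int(np.argmin(np.abs(f75 - f75.mean())))


def tmm_factors(
    expr: ExpressionMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors.

    For each sample vs the reference (the sample whose upper-quartile is
    closest to the mean upper-quartile), gene-wise log2 ratios M and average
    log2 abundances A are computed over genes nonzero in both; the stated
    fraction is trimmed from *each* tail of M (``trim_m``) and of A
    (``trim_a``), and the factor is the exponentiated precision-weighted mean
    of the surviving M values.  Factors are normalized to geometric mean 1.
    """
    X = expr.values.to_numpy(float)
    S = X.shape[1]
    lib = X.sum(axis=0)
    ref = _choose_tmm_reference(X)
    logf = np.zeros(S)
    xr, nr = X[:, ref], lib[ref]
    for j in range(S):
        if j == ref:
            continue
        xj, nj = X[:, j], lib[j]
        keep = (xj > 0) & (xr > 0)
        if not keep.any():
            name = expr.values.columns[j]
            raise ValueError(f"sample {name} shares no expressed genes with the reference")
        o, r = xj[keep] / nj, xr[keep] / nr
        M = np.log2(o / r)
        A = 0.5 * np.log2(o * r)
        # asymptotic variance of M (delta method); weights are 1/variance
        v = (nj - xj[keep]) / (nj * xj[keep]) + (nr - xr[keep]) / (nr * xr[keep])
        n = len(M)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        rm = pd.Series(M).rank().to_numpy()
        ra = pd.Series(A).rank().to_numpy()
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        if sel.sum() == 0:
            logf[j] = 0.0
        else:
            logf[j] = np.sum(M[sel] / v[sel]) / np.sum(1.0 / v[sel])
    factors = 2.0 ** logf
    factors /= np.exp(np.mean(np.log(factors)))  # geometric mean 1
    return pd.Series(factors, index=expr.values.columns, name="tmm_factor")


def log_center_scale(
    expr: ExpressionMatrix,
    factors: pd.Series | None = None,
    offset: float = 1.0,
) -> ExpressionMatrix:
    """log2(x / scale + offset), then per-gene mean 0 and SD 1.

    ``scale`` combines library size and the TMM factor, normalized to mean 1
    across samples so values stay on the count scale before the log.
    Zero-variance genes are dropped (logged).
    """
    X = expr.values.to_numpy(float)
    lib = expr.total_mapped_reads.reindex(expr.values.columns).to_numpy(float)
    f = np.ones(X.shape[1]) if factors is None else factors.reindex(
        expr.values.columns).to_numpy(float)
    scale = lib * f
    scale = scale / scale.mean()
    Y = np.log2(X / scale[None, :] + offset)
    mu = Y.mean(axis=1)
    sd = Y.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        log.info("dropping %d zero-variance genes", int((~keep).sum()))
    Y = (Y[keep] - mu[keep, None]) / sd[keep, None]
    return expr.copy_with(
        pd.DataFrame(Y, index=expr.values.index[keep], columns=expr.values.columns)
    )


def regress_covariates(
    expr: ExpressionMatrix, covariates: pd.DataFrame
) -> ExpressionMatrix:
    """Per-gene OLS residuals after projecting out intercept + covariates.

    ``covariates`` is samples x covariates and must cover every expression
    sample.  Collinear covariates raise an error naming the offending pair.
    """
    cols = expr.values.columns
    missing = set(cols) - set(covariates.index)
    if missing:
        raise ValueError(f"covariates missing for samples: {sorted(missing)[:5]}")
    C = covariates.reindex(cols).to_numpy(float)
    D = np.column_stack([np.ones(len(cols)), C])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        # name a collinear pair for the error message
        names = list(covariates.columns)
        sd = C.std(axis=0)
        for i, name in enumerate(names):
            if sd[i] == 0:
                raise ValueError(f"collinear covariates: intercept ~ {name}")
        corr = np.corrcoef(C.T) if C.shape[1] > 1 else np.ones((1, 1))
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if abs(corr[i, j]) > 1 - 1e-10:
                    raise ValueError(f"collinear covariates: {names[i]} ~ {names[j]}")
        raise ValueError("collinear covariates")
    X = expr.values.to_numpy(float)
    beta, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    resid = X.T - D @ beta
    return expr.copy_with(
        pd.DataFrame(resid.T, index=expr.values.index, columns=cols)
    )


def remove_expression_pcs(expr: ExpressionMatrix, n_pcs: int) -> ExpressionMatrix:
    """Project out the leading principal components of the sample space.

    PCs are computed on the (already covariate-corrected) matrix with genes
    centered; each gene is residualized on the top ``n_pcs`` sample score
    vectors.  The count is capped at min(samples, genes) - 1.
    """
    X = expr.values.to_numpy(float)
    G, S = X.shape
    n_pcs = int(min(n_pcs, min(G, S) - 1))
    if n_pcs <= 0:
        return expr
    Xc = X - X.mean(axis=1, keepdims=True)
    # sample-space eigenvectors of the G x S matrix
    _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    P = Vt[:n_pcs].T  # S x n_pcs, orthonormal
    resid = Xc - (Xc @ P) @ P.T
    return expr.copy_with(
        pd.DataFrame(resid, index=expr.values.index, columns=expr.values.columns)
    )


@dataclass
class NormalizationRecipe:
    """Ordered normalization steps, serialized alongside outputs.

    The default recipe is the eQTL preprocessing chain: TMM factors,
    log2 + center/scale, covariate regression, expression-PC removal.
    ``n_expression_pcs`` defaults to min(100, n_samples // 10), matching
    the full-cohort ratio of the 100-component correction; the full-cohort
    count is available by configuration.
    """

    use_tmm: bool = True
    log_offset: float = 1.0
    covariates: list = field(default_factory=list)  # column names to use
    n_expression_pcs: int | None = None  # None -> min(100, n_samples // 10)
    applied: list = field(default_factory=list)

    def resolve_n_pcs(self, n_samples: int) -> int:
        if self.n_expression_pcs is None:
            return min(100, n_samples // 10)
        return self.n_expression_pcs

    def run(
        self,
        expr: ExpressionMatrix,
        covariates: pd.DataFrame | None = None,
    ) -> tuple[ExpressionMatrix, pd.Series | None]:
        """Apply the recipe; returns (residual matrix, TMM factors)."""
        self.applied = []
        factors = None
        if self.use_tmm:
            factors = tmm_factors(expr)
            self.applied.append("tmm")
        out = log_center_scale(expr, factors=factors, offset=self.log_offset)
        self.applied.append(f"log2(offset={self.log_offset})+center_scale")
        if covariates is not None and covariates.shape[1] > 0:
            out = regress_covariates(out, covariates)
            self.applied.append(f"regress_covariates({list(covariates.columns)})")
        n_pcs = self.resolve_n_pcs(len(out.values.columns))
        if n_pcs > 0:
            out = remove_expression_pcs(out, n_pcs)
            self.applied.append(f"remove_pcs({n_pcs})")
        return out, factors

    def to_dict(self) -> dict:
        return {
            "use_tmm": self.use_tmm,
            "log_offset": self.log_offset,
            "covariates": list(self.covariates),
            "n_expression_pcs": self.n_expression_pcs,
            "applied": list(self.applied),
        }
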