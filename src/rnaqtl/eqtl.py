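"""Population-stratified cis-eQTL mapping with permutation-based FDR.

Associations are Spearman rank correlations between imputed alt-allele
dosage and residual (covariate-corrected) expression, computed separately
per population, converted to signed z-scores and combined by sample-size
weighting: meta_z = sum_k z_k sqrt(n_k) / sqrt(sum_k n_k).  Gene-level
significance uses each gene's best cis p-value against a null built by
permuting the expression-to-genotype sample linkage within each study,
which preserves study (and hence tissue) composition under the null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .dataio import ExpressionMatrix, GenotypeTable, SampleSheet

_Z_CAP = 38.0  # |z| cap where p underflows


@dataclass
class EqtlResult:
    """Pair-level associations and gene-level permutation FDR."""

    associations: pd.DataFrame  # variant_id, gene_id, distance, per-pop stats, meta_z, p_value, direction
    genes: pd.DataFrame         # gene_id, best_variant, best_p, distance, fdr, significant
    n_permutations: int = 0


def build_cis_pairs(
    gt: GenotypeTable,
    expr: ExpressionMatrix,
    window_bp: int = 250_000,
    min_dr2: float = 0.8,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """All (variant, gene) pairs within ``window_bp`` of the gene center.

    Variants must pass dr2 >= min_dr2 (inclusive) and maf >= min_maf.
    Distance is |pos - floor((start+end)/2)|; the window bound is inclusive.
    """
    v = gt.variants
    pass_v = v[(v["dr2"] >= min_dr2) & (v["maf"] >= min_maf)]
    centers = expr.gene_centers()
    rows = []
    for chrom, vc in pass_v.groupby("chrom", sort=False):
        pos = vc["pos"].to_numpy()
        order = np.argsort(pos)
        pos_s = pos[order]
        ids_s = vc.index.to_numpy()[order]
        genes_c = expr.genes[expr.genes["chrom"] == chrom]
        for gid in genes_c.index:
            c = int(centers.loc[gid])
            lo = np.searchsorted(pos_s, c - window_bp, side="left")
            hi = np.searchsorted(pos_s, c + window_bp, side="right")
            for k in range(lo, hi):
                rows.append((ids_s[k], gid, abs(int(pos_s[k]) - c)))
    if not rows:
        raise ValueError("no cis pairs within the window after filtering")
    return pd.DataFrame(rows, columns=["variant_id", "gene_id", "distance"])


def _rank_standardize(X: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, standardized to mean 0 / SD 1 (NaN if constant)."""
    R = stats.rankdata(X, axis=1)
    R = R - R.mean(axis=1, keepdims=True)
    sd = R.std(axis=1, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = R / sd[:, None]
    Z[sd == 0] = np.nan
    return Z


def _z_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Signed z via the t-approximation of the Spearman null."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - rho**2))
    logp = stats.t.logsf(np.abs(t), df=n - 2)  # one-sided tail
    z = -special.ndtri(np.minimum(np.exp(logp), 0.5))
    z = np.clip(np.nan_to_num(z, posinf=_Z_CAP), 0, _Z_CAP)
    return np.sign(rho) * z


def associate_population(
    pairs: pd.DataFrame,
    gt: GenotypeTable,
    resid: ExpressionMatrix,
    sample_ids: list,
    min_n: int = 30,
    _Ze: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-pair Spearman rho / z / n within one population.

    Pairs are skipped (NaN) when the dosage is constant or fewer than
    ``min_n`` samples have non-missing dosage.
    """
    v_ids = pairs["variant_id"].unique()
    g_ids = pairs["gene_id"].unique()
    D = gt.dosage.loc[v_ids, sample_ids].to_numpy(float)
    E = resid.values.loc[g_ids, sample_ids].to_numpy(float)
    n = len(sample_ids)
    out = pairs.copy()
    if n < min_n:
        out["rho"], out["z"], out["n"] = np.nan, np.nan, 0
        return out
    Zd = _rank_standardize(D)
    Ze = _rank_standardize(E) if _Ze is None else _Ze
    vi = pd.Index(v_ids).get_indexer(pairs["variant_id"])
    gi = pd.Index(g_ids).get_indexer(pairs["gene_id"])
    has_missing = np.isnan(D).any(axis=1)
    rho = np.einsum("ij,ij->i", Zd[vi], Ze[gi]) / n
    # pairwise-complete fallback for variants with missing dosage
    for k in np.where(has_missing[vi])[0]:
        d = D[vi[k]]
        e = resid.values.loc[pairs["gene_id"].iloc[k], sample_ids].to_numpy(float)
        ok = ~np.isnan(d)
        if ok.sum() < min_n or d[ok].std() == 0:
            rho[k] = np.nan
        else:
            rho[k] = stats.spearmanr(d[ok], e[ok]).statistic
    out["rho"] = rho
    out["z"] = _z_from_rho(rho, n)
    out["n"] = np.where(np.isnan(rho), 0, n)
    return out


def meta_analyze(z: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample-size-weighted z combination.

    meta_z = sum_k z_k sqrt(n_k) / sqrt(sum_k n_k); two-sided p from the
    standard normal.  Rows (pairs) where every population is missing give
    NaN.  ``z`` and ``n`` are pairs x populations.
    """
    z = np.atleast_2d(np.asarray(z, float))
    n = np.atleast_2d(np.asarray(n, float))
    ok = ~np.isnan(z) & (n > 0)
    w = np.sqrt(np.where(ok, n, 0.0))
    denom = np.sqrt((w**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        meta_z = np.where(
            denom > 0, np.nansum(np.where(ok, z, 0.0) * w, axis=1) / denom, np.nan
        )
    p = 2.0 * stats.norm.sf(np.abs(meta_z))
    p = np.maximum(p, np.nextafter(0, 1))  # keep p in (0, 1]
    return meta_z, p


def _populations(sheet: SampleSheet, samples: list) -> dict:
    pops: dict = {}
    for s in samples:
        pops.setdefault(sheet.data.loc[s, "population"], []).append(s)
    return pops


def map_cis_eqtl(
    pairs: pd.DataFrame,
    gt: GenotypeTable,
    resid: ExpressionMatrix,
    sheet: SampleSheet,
    min_n: int = 30,
    _Ze_by_pop: dict | None = None,
) -> pd.DataFrame:
    """Per-pair population associations plus the meta-analysis columns."""
    samples = [s for s in resid.values.columns if s in set(gt.samples)]
    pops = _populations(sheet, samples)
    out = pairs.copy()
    zs, ns = [], []
    for pop in sorted(pops):
        res = associate_population(
            pairs, gt, resid, pops[pop], min_n=min_n,
            _Ze=None if _Ze_by_pop is None else _Ze_by_pop.get(pop),
        )
        out[f"rho_{pop}"] = res["rho"].to_numpy()
        out[f"z_{pop}"] = res["z"].to_numpy()
        out[f"n_{pop}"] = res["n"].to_numpy()
        zs.append(res["z"].to_numpy())
        ns.append(res["n"].to_numpy())
    meta_z, p = meta_analyze(np.column_stack(zs), np.column_stack(ns))
    out["meta_z"] = meta_z
    out["p_value"] = p
    out["direction"] = np.sign(meta_z)
    return out


def _best_per_gene(assoc: pd.DataFrame) -> pd.DataFrame:
    """Top variant per gene: smallest p, then distance, then variant id."""
    a = assoc.dropna(subset=["p_value"])
    a = a.sort_values(
        ["gene_id", "p_value", "distance", "variant_id"], kind="mergesort"
    )
    best = a.groupby("gene_id", sort=True).first().reset_index()
    return best[["gene_id", "variant_id", "p_value", "distance", "meta_z"]].rename(
        columns={"variant_id": "best_variant", "p_value": "best_p"}
    )


def permute_within_study(
    samples: list, sheet: SampleSheet, rng: np.random.Generator
) -> list:
    """A permutation of ``samples`` that only moves labels within a study."""
    samples = list(samples)
    perm = list(samples)
    by_study: dict = {}
    for i, s in enumerate(samples):
        by_study.setdefault(sheet.data.loc[s, "study_id"], []).append(i)
    for study, idx in by_study.items():
        if len(idx) == 1:
            warnings.warn(f"study {study} has a single sample; fixed in permutation")
            continue
        shuffled = rng.permutation(idx)
        for i, j in zip(idx, shuffled):
            perm[i] = samples[j]
    assert sorted(perm) == sorted(samples)
    return perm


def permutation_fdr(
    pairs: pd.DataFrame,
    gt: GenotypeTable,
    resid: ExpressionMatrix,
    sheet: SampleSheet,
    n_perm: int = 10,
    seed: int = 0,
    min_n: int = 30,
    significance_fdr: float = 0.05,
) -> EqtlResult:
    """Gene-level FDR from within-study permutations.

    Per permutation the expression-to-genotype linkage is shuffled within
    each study and the full association + meta-analysis is rerun; each
    gene's best p is recorded.  FDR at threshold t is
    (mean over permutations of #null genes with best-p <= t) /
    (#real genes with best-p <= t), clipped to [0, 1] and monotonized to be
    non-decreasing in t.  A gene is significant when FDR at its own best p
    is <= ``significance_fdr``.
    """
    rng = np.random.default_rng(seed)
    samples = [s for s in resid.values.columns if s in set(gt.samples)]
    assoc = map_cis_eqtl(pairs, gt, resid, sheet, min_n=min_n)
    best = _best_per_gene(assoc)
    real_p = best["best_p"].to_numpy()

    null_ps = []
    values = resid.values[samples]
    for _ in range(n_perm):
        perm = permute_within_study(samples, sheet, rng)
        perm_values = values[perm]
        perm_values.columns = samples
        perm_resid = resid.copy_with(perm_values)
        passoc = map_cis_eqtl(pairs, gt, perm_resid, sheet, min_n=min_n)
        null_ps.append(_best_per_gene(passoc)["best_p"].to_numpy())
    null_all = np.sort(np.concatenate(null_ps)) if null_ps else np.array([])

    order = np.argsort(real_p, kind="mergesort")
    fdr_sorted = np.empty(len(real_p))
    sorted_p = real_p[order]
    n_real_le = np.arange(1, len(sorted_p) + 1)
    if n_perm > 0:
        n_null_le = np.searchsorted(null_all, sorted_p, side="right") / n_perm
        fdr_sorted = np.clip(n_null_le / n_real_le, 0.0, 1.0)
        fdr_sorted = np.maximum.accumulate(fdr_sorted)  # monotone in t
    else:
        fdr_sorted = np.full(len(sorted_p), np.nan)
    fdr = np.empty(len(real_p))
    fdr[order] = fdr_sorted
    best["fdr"] = fdr
    best["significant"] = best["fdr"] <= significance_fdr
    return EqtlResult(associations=assoc, genes=best, n_permutations=n_perm)


def replicate(
    result_a: EqtlResult, result_b: EqtlResult, fdr_cutoff: float = 0.05
) -> dict:
    """Replication of A's top variants in B, with direction concordance.

    For every gene significant in A (FDR <= cutoff) the gene's top variant
    is looked up among B's tested pairs; it replicates when its p-value in B
    is within B's significance region (the largest best-p among B's
    significant genes).  Direction concordance is the fraction of
    replicated pairs whose meta_z sign matches between A and B.
    """
    sig_a = result_a.genes[result_a.genes["fdr"] <= fdr_cutoff]
    b_assoc = result_b.associations.set_index(["gene_id", "variant_id"])
    if len(result_a.genes) == 0 or len(result_b.associations) == 0:
        raise ValueError("empty result sets")
    sig_b = result_b.genes[result_b.genes["fdr"] <= fdr_cutoff]
    p_star = sig_b["best_p"].max() if len(sig_b) else -np.inf

    n_sig, n_tested, n_repl, n_dir = len(sig_a), 0, 0, 0
    for _, row in sig_a.iterrows():
        key = (row["gene_id"], row["best_variant"])
        if key not in b_assoc.index:
            continue
        n_tested += 1
        hit = b_assoc.loc[key]
        if float(hit["p_value"]) <= p_star:
            n_repl += 1
            if np.sign(hit["meta_z"]) == np.sign(row["meta_z"]):
                n_dir += 1
    if n_tested == 0:
        raise ValueError("no overlap between A's top variants and B's tested pairs")
    return {
        "n_significant_a": n_sig,
        "n_tested_in_b": n_tested,
        "n_replicated": n_repl,
        "replication_rate": n_repl / n_tested,
        "n_direction_match": n_dir,
        "direction_concordance": (n_dir / n_repl) if n_repl else np.nan,
    }
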