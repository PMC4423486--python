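"""Allele-specific expression: pooled binomial MLE and likelihood-ratio test.

Per SNP, allelic read counts of all qualifying heterozygous samples are
pooled; the alt-allele proportion MLE is p_hat = alt / total, the LRT
statistic is 2(l(p_hat) - l(0.5)) with l the binomial log-likelihood
(combinatorial terms cancel), and the p-value is the upper chi-square tail
with one degree of freedom.  FDR is Benjamini-Hochberg.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import HET, AllelicCountTable, GenotypeTable

DIR_ALT, DIR_REF, DIR_BALANCED = "alt_higher", "ref_higher", "balanced"


@dataclass
class ASEResult:
    """Per-site ASE statistics: pooled counts, MLE, LRT, FDR, direction."""

    sites: pd.DataFrame  # variant_id, n_het_samples, pooled_ref, pooled_alt,
    #                      p_hat, lrt, p_value, fdr, direction


def filter_sites(
    counts: AllelicCountTable,
    gt: GenotypeTable,
    min_het_samples: int = 5,
    min_reads_per_allele: int = 10,
    min_allele_frac: float = 0.02,
    min_gq: float = 30.0,
    min_mappability: float = 1.0,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Eligible sites with their qualifying per-sample rows pooled.

    A sample row qualifies when the sample is called heterozygous with GQ
    strictly above ``min_gq``.  A site is kept when it has at least
    ``min_het_samples`` qualifying samples, its pooled counts carry at least
    ``min_reads_per_allele`` reads and ``min_allele_frac`` of all reads on
    each allele, its mappability is >= ``min_mappability`` and it is not in
    an excluded region.  With ``per_sample=True`` the read-count and
    fraction filters are applied within each sample instead of on the pool.

    Returns a frame with one row per kept site and the pooled counts, plus a
    ``rows`` column holding the per-sample (ref, alt) pairs.
    """
    df = counts.data
    # attach the genotype call and GQ of each (variant, sample) row
    vids = gt.variants.index
    vpos = pd.Index(vids).get_indexer(df["variant_id"])
    spos = pd.Index(gt.calls.columns).get_indexer(df["sample_id"])
    known = (vpos >= 0) & (spos >= 0)
    call = np.full(len(df), -2, dtype=int)
    gq = np.zeros(len(df))
    call[known] = gt.calls.to_numpy()[vpos[known], spos[known]]
    gq[known] = gt.gq.to_numpy()[vpos[known], spos[known]]
    qual = (call == HET) & (gq > min_gq)
    if per_sample:
        tot = (df["ref_count"] + df["alt_count"]).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            fr = df["ref_count"].to_numpy() / np.maximum(tot, 1)
        qual &= (
            (df["ref_count"].to_numpy() >= min_reads_per_allele)
            & (df["alt_count"].to_numpy() >= min_reads_per_allele)
            & (fr >= min_allele_frac)
            & (1 - fr >= min_allele_frac)
        )
    sub = df[qual]
    agg = sub.groupby("variant_id", sort=True).agg(
        n_het_samples=("sample_id", "size"),
        pooled_ref=("ref_count", "sum"),
        pooled_alt=("alt_count", "sum"),
        in_excluded_region=("in_excluded_region", "any"),
        mappability=("mappability", "min"),
    )
    total = agg["pooled_ref"] + agg["pooled_alt"]
    keep = (
        (agg["n_het_samples"] >= min_het_samples)
        & (agg["mappability"] >= min_mappability)
        & ~agg["in_excluded_region"]
    )
    if not per_sample:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_ref = agg["pooled_ref"] / total
        keep &= (
            (agg["pooled_ref"] >= min_reads_per_allele)
            & (agg["pooled_alt"] >= min_reads_per_allele)
            & (frac_ref >= min_allele_frac)
            & (1 - frac_ref >= min_allele_frac)
        )
    else:
        keep &= total > 0
    out = agg[keep].reset_index()
    if len(out) == 0:
        warnings.warn("no sites pass the ASE filters")
        out["rows"] = pd.Series(dtype=object)
        return out
    rows = (
        sub.groupby("variant_id")[["ref_count", "alt_count"]]
        .apply(lambda g: list(map(tuple, g.to_numpy())))
        .rename("rows")
    )
    return out.merge(rows, on="variant_id", how="left")


def binomial_lrt(
    pooled_ref: np.ndarray, pooled_alt: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pooled binomial MLE and LRT against p = 0.5.

    Returns (p_hat, lrt, p_value).  The shared-p likelihood over het samples
    depends only on the pooled counts, so any partition of the same pooled
    counts yields the same statistic.  0 * ln 0 is taken as 0.
    """
    ref = np.asarray(pooled_ref, dtype=float)
    alt = np.asarray(pooled_alt, dtype=float)
    total = ref + alt
    if np.any(total <= 0):
        raise ValueError("pooled total must be positive (filter sites first)")
    p_hat = alt / total
    with np.errstate(divide="ignore", invalid="ignore"):
        ll_hat = np.where(alt > 0, alt * np.log(p_hat), 0.0) + np.where(
            ref > 0, ref * np.log(1.0 - p_hat), 0.0
        )
    ll_null = total * np.log(0.5)
    lrt = np.maximum(2.0 * (ll_hat - ll_null), 0.0)
    p_value = stats.chi2.sf(lrt, df=1)
    p_value = np.maximum(p_value, np.nextafter(0, 1))
    return p_hat, lrt, p_value


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def run_ase(
    sites: pd.DataFrame,
    balanced_tol: float = 0.0,
) -> ASEResult:
    """Run the pooled binomial LRT on filtered sites and attach BH FDR.

    Direction is ``alt_higher``/``ref_higher`` by the sign of p_hat - 0.5
    (``balanced`` when |p_hat - 0.5| <= balanced_tol).
    """
    out = sites.copy()
    p_hat, lrt, p = binomial_lrt(
        out["pooled_ref"].to_numpy(), out["pooled_alt"].to_numpy()
    )
    out["p_hat"], out["lrt"], out["p_value"] = p_hat, lrt, p
    out["fdr"] = bh_fdr(p)
    out["direction"] = np.where(
        np.abs(p_hat - 0.5) <= balanced_tol,
        DIR_BALANCED,
        np.where(p_hat > 0.5, DIR_ALT, DIR_REF),
    )
    return ASEResult(sites=out)


def direction_concordance(
    ase_result: ASEResult,
    eqtl_associations: pd.DataFrame,
    eqtl_genes: pd.DataFrame,
    fdr_cutoff: float = 0.05,
) -> dict:
    """Allelic-direction agreement between significant ASE and eQTL effects.

    Shared (variant, gene) pairs are those where the variant has significant
    ASE (FDR <= cutoff) and the gene is eQTL-significant with that variant
    tested; positive meta_z means the alt allele increases expression, which
    matches ``alt_higher`` ASE.
    """
    sig_ase = ase_result.sites[ase_result.sites["fdr"] <= fdr_cutoff]
    sig = eqtl_genes[eqtl_genes["fdr"] <= fdr_cutoff]
    sig_genes = set(sig["gene_id"])
    # the SNP itself must show a significant eQTL effect on the gene: its
    # pair p-value must fall inside the gene-level significance region
    p_star = sig["best_p"].max() if "best_p" in sig.columns and len(sig) else np.inf
    pairs = eqtl_associations[
        eqtl_associations["gene_id"].isin(sig_genes)
        & eqtl_associations["variant_id"].isin(set(sig_ase["variant_id"]))
        & (eqtl_associations["p_value"] <= p_star)
    ]
    if len(pairs) == 0:
        raise ValueError("no shared (variant, gene) pairs between ASE and eQTL results")
    ase_dir = sig_ase.set_index("variant_id")["direction"]
    n_match = 0
    for _, row in pairs.iterrows():
        a = ase_dir.loc[row["variant_id"]]
        e = DIR_ALT if row["meta_z"] > 0 else DIR_REF
        if a == e:
            n_match += 1
    return {
        "n_shared_pairs": len(pairs),
        "n_concordant": n_match,
        "concordance": n_match / len(pairs),
    }


def class_direction_summary(
    ase_result: ASEResult, class_labels: pd.Series
) -> pd.DataFrame:
    """Per-category distribution of alt-allele fractions.

    ``class_labels`` maps variant_id -> category (e.g. a functional class).
    Each category with >= 2 sites gets a rank-sum (Mann-Whitney) comparison
    of its p_hat values against all other sites.
    """
    df = ase_result.sites.copy()
    df["category"] = class_labels.reindex(df["variant_id"]).to_numpy()
    df = df.dropna(subset=["category"])
    rows = []
    for cat, grp in df.groupby("category", sort=True):
        rest = df[df["category"] != cat]
        row = dict(
            category=cat,
            n=len(grp),
            mean_p_hat=grp["p_hat"].mean(),
            median_p_hat=grp["p_hat"].median(),
        )
        if len(grp) >= 2 and len(rest) >= 2:
            u = stats.mannwhitneyu(grp["p_hat"], rest["p_hat"], alternative="two-sided")
            row["rank_sum_p"] = u.pvalue
        else:
            row["rank_sum_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
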