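"""Duplicate-sample detection by pairwise genotype concordance.

High-quality imputed variants are selected (dr2 strictly above 0.95,
MAF >= 0.05, call rate >= 0.95), LD-pruned with a plink-style sliding
window, and pairwise hard-call concordance is computed on the survivors.
Samples joined by concordance >= 78% form identity groups (connected
components); one representative per group is kept, preferring reference-set
members, then the most common tissue, then the most expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeTable, SampleSheet


@dataclass
class ConcordanceMatrix:
    """Symmetric pairwise concordance with comparison counts.

    ``concordance`` is NaN for pairs with fewer than the minimum number of
    jointly non-missing sites (such pairs are unknown, never duplicates).
    """

    concordance: pd.DataFrame
    n_compared: pd.DataFrame
    n_identical: pd.DataFrame


@dataclass
class IdentityGroups:
    groups: list          # list of sorted sample-id lists
    representative: dict  # group index -> sample_id

    def kept_samples(self) -> list:
        return sorted(self.representative.values())

    def dropped_samples(self) -> list:
        kept = set(self.representative.values())
        return sorted(s for g in self.groups for s in g if s not in kept)


def select_dedup_variants(
    gt: GenotypeTable,
    min_dr2: float = 0.95,
    min_maf: float = 0.05,
    min_call_rate: float = 0.95,
) -> list:
    """Variants passing dr2 > min_dr2 (strict), maf >= min_maf, call_rate >= min_call_rate."""
    v = gt.variants
    mask = (
        (v["dr2"].to_numpy(float) > min_dr2)
        & (v["maf"].to_numpy(float) >= min_maf)
        & (v["call_rate"].to_numpy(float) >= min_call_rate)
    )
    ids = list(v.index[mask])
    if not ids:
        raise ValueError(
            "no variants pass the dedup filters; relax min_dr2/min_maf/min_call_rate"
        )
    return ids


def ld_prune(
    gt: GenotypeTable,
    variant_ids: list | None = None,
    window_variants: int = 1000,
    step: int = 5,
    r2_threshold: float = 0.2,
) -> list:
    """Plink-style --indep-pairwise pruning on dosage correlations.

    Within each sliding window of ``window_variants`` variants (advanced by
    ``step``), while any retained pair has squared dosage correlation above
    the threshold, the pair member with the lower MAF is removed (ties break
    toward the later position).  Input must be position-sorted.
    """
    ids = list(gt.variants.index) if variant_ids is None else list(variant_ids)
    var = gt.variants.loc[ids]
    pos = var["pos"].to_numpy()
    if not (np.diff(pos) >= 0).all():
        raise ValueError("variants must be position-sorted for pruning")
    D = gt.dosage.loc[ids].to_numpy(float)
    maf = var["maf"].to_numpy(float)
    n = len(ids)
    keep = np.ones(n, dtype=bool)
    start = 0
    while True:
        stop = min(start + window_variants, n)
        idx = np.where(keep[start:stop])[0] + start
        if len(idx) > 1:
            W = D[idx]
            sd = W.std(axis=1)
            ok = sd > 0
            with np.errstate(invalid="ignore"):
                C = np.corrcoef(W) ** 2
            C[~ok, :] = 0.0
            C[:, ~ok] = 0.0
            np.fill_diagonal(C, 0.0)
            active = np.ones(len(idx), dtype=bool)
            while True:
                M = C * np.outer(active, active)
                i, j = np.unravel_index(np.argmax(M), M.shape)
                if M[i, j] <= r2_threshold:
                    break
                a, b = idx[i], idx[j]
                # drop the lower-MAF member; tie -> later position
                if maf[a] < maf[b] or (maf[a] == maf[b] and pos[a] > pos[b]):
                    drop = i
                else:
                    drop = j
                active[drop] = False
                keep[idx[drop]] = False
        if stop >= n:
            break
        start += step
    return [ids[i] for i in range(n) if keep[i]]


def pairwise_concordance(
    gt: GenotypeTable,
    variant_ids: list | None = None,
    min_overlap: int = 100,
) -> ConcordanceMatrix:
    """Fraction of identical hard calls over jointly non-missing sites.

    Pairs with fewer than ``min_overlap`` comparable sites get NaN
    concordance (unknown).  Self-concordance is 1 wherever defined.
    """
    calls = gt.calls if variant_ids is None else gt.calls.loc[variant_ids]
    C = calls.to_numpy()
    samples = calls.columns
    present = (C != MISSING).astype(np.float64)
    n_compared = present.T @ present
    matches = np.zeros_like(n_compared)
    for g in (0, 1, 2):
        M = (C == g).astype(np.float64)
        matches += M.T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = matches / n_compared
    conc[n_compared < min_overlap] = np.nan
    return ConcordanceMatrix(
        concordance=pd.DataFrame(conc, index=samples, columns=samples),
        n_compared=pd.DataFrame(n_compared.astype(int), index=samples, columns=samples),
        n_identical=pd.DataFrame(matches.astype(int), index=samples, columns=samples),
    )


def group_and_select(
    conc: ConcordanceMatrix,
    sheet: SampleSheet,
    cutoff: float = 0.78,
) -> IdentityGroups:
    """Identity groups and one representative per group.

    Groups are connected components of the graph with an edge wherever
    concordance >= cutoff.  The representative is chosen by: reference-set
    flag, then cohort-wide tissue frequency, then number of expressed genes,
    ties broken by lexicographic sample id.
    """
    M = conc.concordance
    samples = list(M.index)
    sheet.require_samples(samples)
    g = nx.Graph()
    g.add_nodes_from(samples)
    arr = M.to_numpy()
    iu, ju = np.where(np.triu(np.nan_to_num(arr, nan=-1.0), k=1) >= cutoff)
    g.add_edges_from((samples[i], samples[j]) for i, j in zip(iu, ju))
    tissue_freq = sheet.data["tissue"].value_counts()
    meta = sheet.data

    def priority(s: str):
        row = meta.loc[s]
        return (
            -int(bool(row["is_reference_set"])),
            -int(tissue_freq.get(row["tissue"], 0)),
            -int(row["n_expressed_genes"]),
            s,
        )

    groups, reps = [], {}
    for comp in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0]):
        members = sorted(comp)
        groups.append(members)
        reps[len(groups) - 1] = min(members, key=priority)
    return IdentityGroups(groups=groups, representative=reps)


def genotype_pca(
    gt: GenotypeTable,
    variant_ids: list | None = None,
    n_components: int = 4,
) -> pd.DataFrame:
    """Sample principal components of the (pruned) dosage matrix.

    Uses the same variant set as duplicate removal in the pipeline; missing
    dosages are mean-imputed per variant.  Returns samples x components.
    """
    D = (gt.dosage if variant_ids is None else gt.dosage.loc[variant_ids]).to_numpy(float)
    mu = np.nanmean(D, axis=1, keepdims=True)
    D = np.where(np.isnan(D), mu, D) - mu
    sd = D.std(axis=1)
    D = D[sd > 0]
    k = min(n_components, min(D.shape) - 1, len(gt.samples) - 1)
    _, s, Vt = np.linalg.svd(D, full_matrices=False)
    return pd.DataFrame(
        Vt[:k].T * s[:k],
        index=gt.calls.columns,
        columns=[f"gPC{i + 1}" for i in range(k)],
    )


def dosage_concordance(
    gt_rna: GenotypeTable,
    gt_truth: GenotypeTable,
    maf_bins: tuple = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> pd.DataFrame:
    """Per-variant squared correlation between RNA dosage and truth genotype.

    Computed across shared samples; variants with zero-variance truth are
    skipped (counted in the output attrs).  Returns per-MAF-bin median and
    mean r2 plus an overall row.
    """
    shared_v = gt_rna.variants.index.intersection(gt_truth.variants.index)
    shared_s = [s for s in gt_rna.samples if s in set(gt_truth.samples)]
    if len(shared_v) == 0 or len(shared_s) == 0:
        raise ValueError("no shared variants/samples between tables")
    D = gt_rna.dosage.loc[shared_v, shared_s].to_numpy(float)
    T = gt_truth.calls.loc[shared_v, shared_s].to_numpy(float)
    T[T == MISSING] = np.nan
    r2 = np.full(len(shared_v), np.nan)
    n_skipped = 0
    for i in range(len(shared_v)):
        ok = ~np.isnan(D[i]) & ~np.isnan(T[i])
        if ok.sum() < 3 or T[i, ok].std() == 0 or D[i, ok].std() == 0:
            n_skipped += 1
            continue
        r2[i] = np.corrcoef(D[i, ok], T[i, ok])[0, 1] ** 2
    maf = gt_truth.variants.loc[shared_v, "maf"].to_numpy(float)
    df = pd.DataFrame({"r2": r2, "maf": maf}).dropna()
    rows = []
    for lo, hi in zip(maf_bins[:-1], maf_bins[1:]):
        sel = df[(df["maf"] >= lo) & (df["maf"] < hi if hi < 0.5 else df["maf"] <= hi)]
        rows.append(
            dict(maf_lo=lo, maf_hi=hi, n=len(sel),
                 median_r2=sel["r2"].median(), mean_r2=sel["r2"].mean())
        )
    rows.append(
        dict(maf_lo=0.0, maf_hi=0.5, n=len(df),
             median_r2=df["r2"].median(), mean_r2=df["r2"].mean())
    )
    out = pd.DataFrame(rows)
    out.attrs["n_skipped"] = n_skipped
    return out
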