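"""Synthetic pipeline inputs with the statistical structure the analyses assume.

The generator emulates the *outputs* of the upstream alignment / calling /
imputation stack rather than reads: Hardy-Weinberg genotypes in three
populations with Balding-Nichols differentiated allele frequencies (so
populations separate in genotype PCA), imputation dosages whose squared correlation with the truth is
calibrated to a target dosage-r2, depth-driven genotype qualities,
negative-binomial-like gene counts with planted cis effects and study/GC
covariate structure, and binomial allelic read counts with planted imbalance
and optional reference bias.  Planted duplicate pairs, 1:1 contaminated
mixtures and sex-linked marker genes exercise the QC stages.

Everything is a deterministic function of ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    SEX_FEMALE,
    SEX_MALE,
    SEX_UNKNOWN,
    AllelicCountTable,
    ExpressionMatrix,
    GenotypeTable,
    SampleSheet,
    write_allelic_counts,
    write_expression,
    write_genotypes,
    write_sample_sheet,
)

# marker genes used by the sex check
XIST_GENE = "XIST"
CHRY_GENES = ("RPS4Y1", "EIF1AY", "DDX3Y")

_TISSUES = ("LCL", "blood", "brain", "liver", "fibroblast")

# fraction of non-planted allelic sites placed in exclusion / low-mappability
# regions, so the site filters have something to remove
_EXCLUDED_FRAC = 0.02
_LOW_MAPP_FRAC = 0.02

_ANNOTATED_SEX_FRAC = 0.4  # fraction of samples with a sex annotation

_FST = 0.1  # Balding-Nichols differentiation between populations


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    Defaults are a desk-scale cohort with the population proportions of the
    real study (EUR:AFR:ASN roughly 8:1.7:1), a handful of single-tissue
    studies of which the first is the reference ("Geuvadis-like") set, and
    genotyping/ASE noise levels typical of imputed RNA-seq genotypes.
    """

    n_samples: dict = field(default_factory=lambda: {"EUR": 95, "AFR": 20, "ASN": 12})
    n_studies: int = 4
    n_genes: int = 500
    n_variants: int = 1500
    chrom_length: int = 10_000_000
    depth: float = 30.0          # mean read depth per site
    eqtl_frac: float = 0.1       # fraction of genes with a planted cis effect
    eqtl_beta: float = 1.0       # per-allele effect, in units of the noise SD
    ase_frac: float = 0.05       # fraction of sites with planted imbalance
    ase_ratio: float = 0.7       # true alt-allele proportion at planted sites
    ref_bias: float = 0.0        # multiplicative sampling bias toward ref
    dup_pairs: int = 2           # planted duplicate sample pairs
    contaminated: int = 1        # planted 1:1 mixture samples
    imputation_dr2: float = 0.96  # target corr^2(dosage, true genotype)
    seed: int = 0

    def validate(self) -> None:
        for name in ("eqtl_frac", "ase_frac", "ref_bias"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.ase_ratio < 1.0:
            raise ValueError("ase_ratio must be in (0, 1)")
        if not 0.0 < self.imputation_dr2 <= 1.0:
            raise ValueError("imputation_dr2 must be in (0, 1]")
        if any(n < 2 for n in self.n_samples.values()):
            raise ValueError("need at least 2 samples per population")
        if self.n_studies < 1 or self.n_genes < 1 or self.n_variants < 1:
            raise ValueError("n_studies, n_genes and n_variants must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        n_base = sum(self.n_samples.values())
        if 2 * self.dup_pairs > n_base or 2 * self.contaminated > n_base:
            raise ValueError("not enough base samples for planted duplicates/mixtures")


@dataclass
class GenotypeSim:
    genotypes: GenotypeTable      # observed: noisy dosage, called GT, GQ, depth
    truth: GenotypeTable          # error-free calls and dosages
    sheet: SampleSheet
    dup_pairs: list               # [(original_id, copy_id), ...]
    contaminated_ids: list
    true_sex: pd.Series           # per sample, {male, female}


@dataclass
class ExpressionSim:
    expression: ExpressionMatrix
    eqtl_effects: pd.DataFrame    # gene_id, variant_id, beta (SD units)
    noise_sd: float


@dataclass
class AllelicSim:
    counts: AllelicCountTable
    ase_sites: pd.DataFrame       # variant_id, true_alt_ratio
    excluded_variants: list
    low_mappability_variants: list


def _stage_rng(cfg: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), stage]))


def _rowwise_corr(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    num = (Ac * Bc).sum(axis=1)
    den = np.sqrt((Ac**2).sum(axis=1) * (Bc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, 0.0)


def _draw_maf(rng: np.random.Generator, size) -> np.ndarray:
    """MAF spectrum with density proportional to 1/f on [0.05, 0.5]."""
    lo, hi = 0.05, 0.5
    return lo * (hi / lo) ** rng.uniform(size=size)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(cfg: SimConfig) -> GenotypeSim:
    """Generate the genotype table, truth table and sample sheet.

    Alternative-allele frequencies follow a Balding-Nichols model: a 1/f
    ancestral minor-allele spectrum with per-population Beta drift at Fst
    0.1.  Observed dosages are the true
    genotype plus truncated Gaussian noise scaled so that the per-variant
    squared correlation with the truth matches ``imputation_dr2``.  Hard
    calls are direct (non-imputed) calls: correct with probability
    1 - 10^(-GQ/10), where GQ = min(99, 3 x depth); sites with zero depth
    are missing.  In the noise-free limit (``imputation_dr2 == 1``) both
    mechanisms are disabled.  Duplicate pairs copy the true genotype vector;
    contaminated samples pool two donors' alleles and are called
    heterozygous wherever the pool carries both alleles.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 0)
    pops = list(cfg.n_samples)
    V = cfg.n_variants

    # variant positions and ids
    pos = np.sort(rng.choice(cfg.chrom_length, size=V, replace=False)) + 1
    vids = pd.Index([f"v{i:06d}" for i in range(V)], name="variant_id")

    # Balding-Nichols population frequencies: an ancestral frequency from a
    # 1/f minor-allele spectrum, then per-population Beta drift at Fst 0.1 —
    # populations separate in genotype PCA while common variants stay
    # common across ancestries
    maf0 = _draw_maf(rng, V)
    flip = rng.random(V) < 0.5
    f0 = np.where(flip, 1.0 - maf0, maf0)
    k = (1.0 - _FST) / _FST
    freq = {}
    for p in pops:
        fp = rng.beta(f0 * k, (1.0 - f0) * k)
        freq[p] = np.clip(fp, 0.005, 0.995)

    # base samples
    sample_ids, pop_of, cols = [], {}, []
    for p in pops:
        for i in range(cfg.n_samples[p]):
            sid = f"{p}{i:03d}"
            sample_ids.append(sid)
            pop_of[sid] = p
    G = np.empty((V, len(sample_ids)), dtype=np.int8)
    for j, sid in enumerate(sample_ids):
        G[:, j] = rng.binomial(2, freq[pop_of[sid]])

    # planted duplicates: exact copies of the true genotype vector
    base_ids = list(sample_ids)
    donors = rng.choice(len(base_ids), size=2 * cfg.dup_pairs + 2 * cfg.contaminated,
                        replace=False)
    dup_pairs = []
    extra_cols = []
    for k in range(cfg.dup_pairs):
        src = base_ids[donors[k]]
        copy_id = f"{src}rep"
        dup_pairs.append((src, copy_id))
        sample_ids.append(copy_id)
        pop_of[copy_id] = pop_of[src]
        extra_cols.append(G[:, donors[k]].copy())

    # contaminated samples: 1:1 pool of two donors from one population
    contaminated_ids = []
    mix_truth_dosage = []
    mix_sources = donors[2 * cfg.dup_pairs:].reshape(-1, 2)
    for k, (a, b) in enumerate(mix_sources):
        # re-draw b from the same population as a for a realistic mixture
        same_pop = [j for j, s in enumerate(base_ids)
                    if pop_of[s] == pop_of[base_ids[a]] and j != a]
        b = same_pop[int(rng.integers(len(same_pop)))]
        mid = f"{pop_of[base_ids[a]]}mix{k:02d}"
        contaminated_ids.append(mid)
        sample_ids.append(mid)
        pop_of[mid] = pop_of[base_ids[a]]
        ga, gb = G[:, a], G[:, b]
        # called het wherever the pooled alleles are mixed
        call = np.where((ga + gb == 0), HOM_REF,
                        np.where((ga == 2) & (gb == 2), HOM_ALT, HET)).astype(np.int8)
        extra_cols.append(call)
        mix_truth_dosage.append((ga + gb) / 2.0)

    S = len(sample_ids)
    truth_calls = np.column_stack([G] + extra_cols) if extra_cols else G
    truth_dosage = truth_calls.astype(float)
    for k, mid in enumerate(contaminated_ids):
        truth_dosage[:, sample_ids.index(mid)] = mix_truth_dosage[k]

    # depth: per-variant mean from a Gamma (some sites sparse), Poisson per sample
    lam = rng.gamma(shape=2.0, scale=cfg.depth / 2.0, size=V)
    depth = rng.poisson(lam[:, None], size=(V, S))
    gq = np.minimum(99.0, 3.0 * depth).astype(float)

    noise_free = cfg.imputation_dr2 >= 1.0
    # imputed dosage: truth + Gaussian noise calibrated to the target r2
    if noise_free:
        dosage = truth_dosage.astype(float)
    else:
        # Imputation accuracy is a within-population property (panels and LD
        # differ by ancestry), so noise is calibrated per (variant,
        # population): truncation to [0, 2] removes noise variance, and a few
        # fixed-point iterations rescale sigma so the realized per-variant
        # corr^2 with the truth matches the target within each population.
        dosage = truth_dosage.astype(float).copy()
        z = rng.standard_normal((V, S))
        target_ratio = (1 - cfg.imputation_dr2) / cfg.imputation_dr2
        pop_arr = np.array([pop_of[s] for s in sample_ids])
        for p in pops:
            cols = np.where(pop_arr == p)[0]
            sub_truth = truth_dosage[:, cols]
            var = sub_truth.var(axis=1)
            sigma = np.sqrt(np.maximum(var, 1e-12) * target_ratio)
            sub_z = z[:, cols]
            # the empirical-r2 rescaling is only meaningful with enough
            # samples and a polymorphic variant
            adjustable = (var > 1e-8) if len(cols) >= 10 else np.zeros(V, bool)
            for _ in range(4):
                sub = np.clip(sub_truth + sigma[:, None] * sub_z, 0.0, 2.0)
                r = _rowwise_corr(sub, sub_truth)
                r2 = np.clip(r**2, 1e-6, 1 - 1e-6)
                adj = np.sqrt(target_ratio * r2 / (1 - r2))
                sigma = sigma * np.where(adjustable, np.clip(adj, 0.5, 2.0), 1.0)
            dosage[:, cols] = np.clip(sub_truth + sigma[:, None] * sub_z, 0.0, 2.0)

    # direct hard calls: flip with probability 10^(-GQ/10)
    calls = truth_calls.copy()
    if not noise_free:
        flip = rng.random((V, S)) < np.power(10.0, -gq / 10.0)
        if flip.any():
            shift = rng.integers(1, 3, size=int(flip.sum()))
            calls[flip] = (calls[flip].astype(int) + shift) % 3
    calls = np.where(depth == 0, MISSING, calls).astype(np.int8)
    gq = np.where(depth == 0, 0.0, gq)

    nonmiss = calls != MISSING
    with np.errstate(invalid="ignore"):
        af = np.where(nonmiss, calls, 0).sum(axis=1) / np.maximum(
            2 * nonmiss.sum(axis=1), 1)
    maf = np.minimum(af, 1 - af)
    call_rate = nonmiss.mean(axis=1)

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "ref_allele": rng.choice(list("ACGT"), size=V),
            "alt_allele": "",
            "dr2": cfg.imputation_dr2,
            "maf": maf,
            "call_rate": call_rate,
        },
        index=vids,
    )
    # alt allele distinct from ref
    repl = {"A": "G", "C": "T", "G": "A", "T": "C"}
    variants["alt_allele"] = variants["ref_allele"].map(repl)

    scols = pd.Index(sample_ids)
    gt = GenotypeTable(
        variants=variants,
        calls=pd.DataFrame(calls, index=vids, columns=scols),
        gq=pd.DataFrame(gq, index=vids, columns=scols),
        dosage=pd.DataFrame(dosage, index=vids, columns=scols),
        depth=pd.DataFrame(depth, index=vids, columns=scols),
    )
    tvar = variants.copy()
    tvar["dr2"] = 1.0
    truth = GenotypeTable(
        variants=tvar,
        calls=pd.DataFrame(truth_calls, index=vids, columns=scols),
        gq=pd.DataFrame(np.full((V, S), 99.0), index=vids, columns=scols),
        dosage=pd.DataFrame(truth_dosage, index=vids, columns=scols),
    )

    # sample sheet: single-tissue studies, study 0 is the reference set
    study = rng.integers(0, cfg.n_studies, size=S)
    tissue_of_study = {k: _TISSUES[k % len(_TISSUES)] for k in range(cfg.n_studies)}
    true_sex = pd.Series(
        np.where(rng.random(S) < 0.5, SEX_MALE, SEX_FEMALE), index=scols
    )
    annotated = np.where(
        rng.random(S) < _ANNOTATED_SEX_FRAC, true_sex.to_numpy(), SEX_UNKNOWN
    )
    sheet = SampleSheet(
        data=pd.DataFrame(
            {
                "study_id": [f"study{k}" for k in study],
                "population": [pop_of[s] for s in sample_ids],
                "tissue": [tissue_of_study[k] for k in study],
                "is_reference_set": study == 0,
                "annotated_sex": annotated,
                "n_expressed_genes": 0,
            },
            index=scols.rename("sample_id"),
        )
    )
    return GenotypeSim(gt, truth, sheet, dup_pairs, contaminated_ids, true_sex)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def simulate_expression(cfg: SimConfig, gsim: GenotypeSim) -> ExpressionSim:
    """Generate gene counts with planted cis effects and covariate structure.

    Log-scale expression = gene baseline + per-(study, gene) offset +
    library-size term + GC x library-size technical term + beta x true dosage
    for planted genes + Gaussian noise, exponentiated and Poisson-sampled.
    Genes are anchored at variants so every planted gene has a cis variant
    within the 250 kb window.  Sex marker genes (XIST, chrY) are appended
    with expression determined by the sample's true sex.
    """
    cfg.validate()
    rng = _stage_rng(cfg, 1)
    gt = gsim.truth
    samples = gt.samples
    S = len(samples)
    noise_sd = 0.5

    # anchor each gene at a variant; the planted effect acts through the anchor
    replace = gt.n_variants < cfg.n_genes
    anchors = rng.choice(gt.n_variants, size=cfg.n_genes, replace=replace)
    centers = gt.variants["pos"].to_numpy()[anchors] + rng.integers(
        -50_000, 50_001, size=cfg.n_genes
    )
    centers = np.clip(centers, 50_001, cfg.chrom_length - 50_001)
    lengths = rng.integers(1_000, 100_000, size=cfg.n_genes)
    start = np.maximum(1, centers - lengths // 2)
    end = start + lengths

    order = np.argsort(centers, kind="stable")
    anchors, centers, start, end = anchors[order], centers[order], start[order], end[order]
    gids = pd.Index([f"G{i:04d}" for i in range(cfg.n_genes)], name="gene_id")
    genes = pd.DataFrame(
        {
            "chrom": "1",
            "start": start,
            "end": end,
            "gc_fraction": rng.uniform(0.35, 0.65, size=cfg.n_genes),
        },
        index=gids,
    )

    n_eqtl = int(round(cfg.eqtl_frac * cfg.n_genes))
    # plant effects at common anchors (cohort MAF >= 0.2): a per-allele
    # effect in SD units is only a comparable effect size at comparable
    # allele frequency, and cis-eQTL power studies plant at common variants
    truth_calls = gt.calls.to_numpy()
    af = truth_calls.mean(axis=1) / 2.0
    anchor_maf = np.minimum(af, 1 - af)[anchors]
    common = np.where(anchor_maf >= 0.2)[0]
    if len(common) >= n_eqtl:
        planted = rng.choice(common, size=n_eqtl, replace=False)
    else:
        rest = rng.choice(
            np.setdiff1d(np.arange(cfg.n_genes), common),
            size=n_eqtl - len(common), replace=False,
        )
        planted = np.concatenate([common, rest])
    eff = pd.DataFrame(
        {
            "gene_id": gids[planted],
            "variant_id": gt.variants.index.to_numpy()[anchors[planted]],
            "beta": cfg.eqtl_beta,
        }
    ).reset_index(drop=True)

    study = gsim.sheet.data["study_id"]
    study_codes = pd.Categorical(study.loc[samples]).codes
    n_studies = study_codes.max() + 1

    mu = rng.normal(4.5, 1.0, size=cfg.n_genes)
    study_fx = rng.normal(0.0, 0.5, size=(n_studies, cfg.n_genes))
    libsize = rng.normal(0.0, 0.25, size=S)
    gc = genes["gc_fraction"].to_numpy()

    logmu = (
        mu[:, None]
        + study_fx[study_codes, :].T
        + libsize[None, :]
        + (gc[:, None] - 0.5) * libsize[None, :]
    )
    dos = gt.dosage.to_numpy()
    for gi in planted:
        d = dos[anchors[gi]]
        logmu[gi] += cfg.eqtl_beta * noise_sd * (d - d.mean())
    logmu += rng.normal(0.0, noise_sd, size=logmu.shape)

    counts = rng.poisson(np.exp(np.clip(logmu, None, 12.0)))

    # sex marker genes
    sex = gsim.true_sex.loc[samples].to_numpy()
    female = sex == SEX_FEMALE
    extra_rows, extra_ann = [], []
    xist_mu = np.where(female, 5.0, 0.5)
    extra_rows.append(rng.poisson(np.exp(xist_mu + rng.normal(0, noise_sd, S))))
    extra_ann.append((XIST_GENE, "X", 1_000_000, 1_030_000, 0.5))
    for k, g in enumerate(CHRY_GENES):
        y_mu = np.where(female, 0.3, 4.5)
        extra_rows.append(rng.poisson(np.exp(y_mu + rng.normal(0, noise_sd, S))))
        extra_ann.append((g, "Y", 1_000_000 + 200_000 * k, 1_050_000 + 200_000 * k, 0.5))

    all_genes = pd.concat(
        [
            genes,
            pd.DataFrame(
                [dict(zip(["gene_id", "chrom", "start", "end", "gc_fraction"], r))
                 for r in extra_ann]
            ).set_index("gene_id"),
        ]
    )
    values = pd.DataFrame(
        np.vstack([counts] + [r[None, :] for r in extra_rows]),
        index=all_genes.index,
        columns=samples,
    )
    expr = ExpressionMatrix(genes=all_genes, values=values, is_raw_counts=True)
    gsim.sheet.data["n_expressed_genes"] = (values > 0).sum(axis=0).reindex(
        gsim.sheet.data.index
    )
    return ExpressionSim(expression=expr, eqtl_effects=eff, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# allelic counts
# ---------------------------------------------------------------------------


def simulate_allelic_counts(cfg: SimConfig, gsim: GenotypeSim) -> AllelicSim:
    """Generate per-het-sample allelic read counts.

    For every (variant, sample) called heterozygous, the read total is the
    site/sample depth and the alt count is Binomial(total, p') where p is
    0.5 at null sites and ``ase_ratio`` at planted sites, shifted toward the
    reference by ``ref_bias``:  p' = (1-b)p / ((1-b)p + (1-p)).
    """
    cfg.validate()
    rng = _stage_rng(cfg, 2)
    gt = gsim.genotypes
    V = gt.n_variants
    vindex = gt.variants.index

    n_ase = int(round(cfg.ase_frac * V))
    planted = rng.choice(V, size=n_ase, replace=False)
    is_planted = np.zeros(V, dtype=bool)
    is_planted[planted] = True

    # exclusion / low-mappability flags on non-planted sites
    free = np.where(~is_planted)[0]
    n_excl = int(round(_EXCLUDED_FRAC * V))
    n_lowm = int(round(_LOW_MAPP_FRAC * V))
    flagged = rng.choice(free, size=min(n_excl + n_lowm, len(free)), replace=False)
    excl_idx, lowm_idx = flagged[:n_excl], flagged[n_excl:]
    excluded = set(vindex[excl_idx])
    low_mapp = set(vindex[lowm_idx])

    p_true = np.where(is_planted, cfg.ase_ratio, 0.5)
    b = cfg.ref_bias
    p_obs = ((1 - b) * p_true) / ((1 - b) * p_true + (1 - p_true))

    calls = gt.calls.to_numpy()
    depth = gt.depth.to_numpy()
    vi, si = np.where((calls == HET) & (depth > 0))
    totals = depth[vi, si]
    alts = rng.binomial(totals, p_obs[vi])
    samples = np.asarray(gt.samples)

    df = pd.DataFrame(
        {
            "variant_id": vindex.to_numpy()[vi],
            "sample_id": samples[si],
            "chrom": gt.variants["chrom"].to_numpy()[vi],
            "pos": gt.variants["pos"].to_numpy()[vi],
            "ref_count": totals - alts,
            "alt_count": alts,
        }
    )
    df["in_excluded_region"] = df["variant_id"].isin(excluded)
    df["mappability"] = np.where(df["variant_id"].isin(low_mapp), 0.5, 1.0)
    ase_sites = pd.DataFrame(
        {"variant_id": vindex[planted], "true_alt_ratio": cfg.ase_ratio}
    ).reset_index(drop=True)
    return AllelicSim(
        counts=AllelicCountTable(data=df),
        ase_sites=ase_sites,
        excluded_variants=sorted(excluded),
        low_mappability_variants=sorted(low_mapp),
    )


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def simulate_all(cfg: SimConfig) -> tuple[GenotypeSim, ExpressionSim, AllelicSim]:
    gsim = simulate_genotypes(cfg)
    esim = simulate_expression(cfg, gsim)
    asim = simulate_allelic_counts(cfg, gsim)
    return gsim, esim, asim


def write_bundle(cfg: SimConfig, outdir: str | Path) -> dict:
    """Simulate everything and write the full input bundle to ``outdir``.

    Writes: genotypes.vcf, truth_genotypes.vcf, expression.tsv,
    allelic_counts.tsv, exclusions.bed, mappability.bed, samples.tsv and
    ground_truth.json (planted effects for evaluation).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gsim, esim, asim = simulate_all(cfg)

    write_genotypes(gsim.genotypes, outdir / "genotypes.vcf")
    write_genotypes(gsim.truth, outdir / "truth_genotypes.vcf")
    write_expression(esim.expression, outdir / "expression.tsv")
    write_allelic_counts(asim.counts, outdir / "allelic_counts.tsv")
    write_sample_sheet(gsim.sheet, outdir / "samples.tsv")

    var = gsim.genotypes.variants
    with open(outdir / "exclusions.bed", "w") as fh:
        for v in asim.excluded_variants:
            row = var.loc[v]
            fh.write(f"{row['chrom']}\t{row['pos'] - 1}\t{row['pos']}\n")
    with open(outdir / "mappability.bed", "w") as fh:
        for v in var.index:
            row = var.loc[v]
            score = 0.5 if v in set(asim.low_mappability_variants) else 1.0
            fh.write(f"{row['chrom']}\t{row['pos'] - 1}\t{row['pos']}\tm\t{score}\n")

    truth = {
        "dup_pairs": gsim.dup_pairs,
        "contaminated": gsim.contaminated_ids,
        "true_sex": gsim.true_sex.to_dict(),
        "eqtl_effects": esim.eqtl_effects.to_dict(orient="records"),
        "ase_sites": asim.ase_sites.to_dict(orient="records"),
        "config": asdict(cfg),
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return truth
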