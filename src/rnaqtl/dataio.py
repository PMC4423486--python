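"""Input/output and in-memory containers for the pipeline.

All downstream stages consume the four containers defined here:
:class:`GenotypeTable`, :class:`ExpressionMatrix`, :class:`AllelicCountTable`
and :class:`SampleSheet`.  Genomic positions are 1-based inclusive everywhere
inside the package; BED inputs (0-based half-open) are converted at the
boundary when files are read.

Genotype interchange is VCF 4.x in the Beagle dialect: hard calls in GT,
Phred genotype quality in GQ, expected alt-allele dosage in FORMAT/DS and
estimated imputation dosage-r2 in INFO/DR2.  Multi-allelic records are
dropped (all analyses are biallelic).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

# hard-call codes used throughout
HOM_REF, HET, HOM_ALT, MISSING = 0, 1, 2, -1

SEX_MALE, SEX_FEMALE, SEX_UNKNOWN = "male", "female", "unknown"


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Per-sample, per-variant genotype data.

    Parameters
    ----------
    variants : DataFrame indexed by variant_id with columns
        ``chrom, pos, ref_allele, alt_allele, dr2, maf, call_rate``.
        ``pos`` is 1-based; ``dr2`` is the estimated imputation dosage-r2
        (NaN when unknown — a NaN fails every dr2 threshold); ``maf`` is the
        minor allele frequency in [0, 0.5].
    calls : DataFrame (variants x samples) of hard-call codes
        0=hom_ref, 1=het, 2=hom_alt, -1=missing.
    gq : DataFrame (variants x samples) of Phred-scaled genotype qualities.
    dosage : DataFrame (variants x samples) of expected alt-allele counts
        in [0, 2] (NaN for missing).
    depth : optional DataFrame (variants x samples) of read depths, used by
        the heterozygosity-rate QC.
    """

    variants: pd.DataFrame
    calls: pd.DataFrame
    gq: pd.DataFrame
    dosage: pd.DataFrame
    depth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.variants.index.is_unique:
            raise ValueError("variant ids must be unique")
        if (self.variants["pos"] <= 0).any():
            raise ValueError("positions must be strictly positive (1-based)")
        maf = self.variants["maf"].to_numpy(float)
        ok = np.isnan(maf) | ((maf >= 0) & (maf <= 0.5))
        if not ok.all():
            raise ValueError("maf must lie in [0, 0.5]")
        d = self.dosage.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(d, initial=0.0) < -1e-9 or np.nanmax(d, initial=0.0) > 2 + 1e-9:
                raise ValueError("dosage must lie in [0, 2]")
        for m in (self.calls, self.gq, self.dosage):
            if not m.index.equals(self.variants.index):
                raise ValueError("matrix rows must match the variant index")
            if not m.columns.equals(self.calls.columns):
                raise ValueError("matrices must share one sample order")

    @property
    def samples(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(
        self,
        variant_ids: Sequence[str] | None = None,
        sample_ids: Sequence[str] | None = None,
    ) -> "GenotypeTable":
        v = self.variants.index if variant_ids is None else pd.Index(variant_ids)
        s = self.calls.columns if sample_ids is None else list(sample_ids)
        return GenotypeTable(
            variants=self.variants.loc[v],
            calls=self.calls.loc[v, s],
            gq=self.gq.loc[v, s],
            dosage=self.dosage.loc[v, s],
            depth=None if self.depth is None else self.depth.loc[v, s],
        )


@dataclass
class ExpressionMatrix:
    """Gene-level expression: raw counts or normalized values.

    ``genes`` is indexed by gene_id with columns ``chrom, start, end,
    gc_fraction`` (1-based inclusive coordinates); ``values`` is genes x
    samples; ``total_mapped_reads`` is the per-sample library size.
    The gene center is defined as floor((start + end) / 2).
    """

    genes: pd.DataFrame
    values: pd.DataFrame
    total_mapped_reads: pd.Series | None = None
    is_raw_counts: bool = True

    def __post_init__(self) -> None:
        if not self.genes.index.is_unique:
            raise ValueError("gene ids must be unique")
        if not self.values.index.equals(self.genes.index):
            raise ValueError("values rows must match gene annotation")
        if self.is_raw_counts:
            v = self.values.to_numpy()
            if (v < 0).any():
                raise ValueError("raw counts must be non-negative")
        if self.total_mapped_reads is None:
            self.total_mapped_reads = self.values.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_centers(self) -> pd.Series:
        g = self.genes
        return ((g["start"] + g["end"]) // 2).astype(int)

    def copy_with(self, values: pd.DataFrame, raw: bool = False) -> "ExpressionMatrix":
        return ExpressionMatrix(
            genes=self.genes.loc[values.index],
            values=values,
            total_mapped_reads=self.total_mapped_reads,
            is_raw_counts=raw,
        )


@dataclass
class AllelicCountTable:
    """Per-sample, per-heterozygous-site allelic read counts.

    One row per (variant, sample); columns ``variant_id, sample_id, chrom,
    pos, ref_count, alt_count, in_excluded_region, mappability``.
    """

    data: pd.DataFrame

    REQUIRED = (
        "variant_id",
        "sample_id",
        "chrom",
        "pos",
        "ref_count",
        "alt_count",
        "in_excluded_region",
        "mappability",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"allelic count table missing columns: {missing}")
        dup = self.data.duplicated(subset=["variant_id", "sample_id"])
        if dup.any():
            bad = self.data.loc[dup, ["variant_id", "sample_id"]].iloc[0]
            raise ValueError(
                f"duplicate (variant, sample) rows, first at "
                f"({bad['variant_id']}, {bad['sample_id']})"
            )
        if (self.data[["ref_count", "alt_count"]].to_numpy() < 0).any():
            raise ValueError("allelic counts must be non-negative")


@dataclass
class SampleSheet:
    """Sample metadata: study, population, tissue and QC-relevant flags."""

    data: pd.DataFrame  # indexed by sample_id

    REQUIRED = (
        "study_id",
        "population",
        "tissue",
        "is_reference_set",
        "annotated_sex",
        "n_expressed_genes",
    )

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("sample ids must be unique")
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        absent = set(sample_ids) - set(self.data.index)
        if absent:
            raise ValueError(f"samples absent from sample sheet: {sorted(absent)[:5]}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT_TYPE_MAP = {0: HOM_REF, 1: HET, 2: MISSING, 3: HOM_ALT}  # cyvcf2 gt_types


def read_genotypes(path: str | Path) -> GenotypeTable:
    """Read a VCF into a :class:`GenotypeTable`.

    GT is required; GQ, DS and DP FORMAT fields and the INFO/DR2 field are
    used when present.  Missing GQ becomes 0; missing DS is derived from the
    hard call; MAF and call rate are computed from the calls when the file
    does not carry them.  Multi-allelic records are skipped (count logged).
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    rows, calls, gqs, dss, dps = [], [], [], [], []
    n_multi = 0
    has_depth = False
    for i, v in enumerate(vcf):
        try:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            call = np.array([_GT_TYPE_MAP[t] for t in v.gt_types], dtype=np.int8)
            gq = np.asarray(v.gt_quals, dtype=float)
            gq[~np.isfinite(gq) | (gq < 0)] = 0.0
            gq[call == MISSING] = 0.0
            try:
                ds = v.format("DS")
            except KeyError:
                ds = None
            if ds is None:
                ds = call.astype(float)
                ds[call == MISSING] = np.nan
            else:
                ds = np.asarray(ds, dtype=float).reshape(-1)
                ds[(ds < 0) | (ds > 2)] = np.nan
            try:
                dp = v.format("DP")
            except KeyError:
                dp = None
            if dp is not None:
                has_depth = True
                dp = np.asarray(dp, dtype=float).reshape(-1)
                dp[dp < 0] = 0
            dr2 = v.INFO.get("DR2")
            nonmiss = call != MISSING
            call_rate = float(nonmiss.mean()) if len(call) else 0.0
            if nonmiss.any():
                af = float(call[nonmiss].sum()) / (2 * nonmiss.sum())
                maf = min(af, 1.0 - af)
            else:
                maf = np.nan
            vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
            rows.append(
                dict(
                    variant_id=vid,
                    chrom=v.CHROM,
                    pos=v.POS,
                    ref_allele=v.REF,
                    alt_allele=v.ALT[0],
                    dr2=np.nan if dr2 is None else float(dr2),
                    maf=maf,
                    call_rate=call_rate,
                )
            )
            calls.append(call)
            gqs.append(gq)
            dss.append(ds)
            dps.append(dp if dp is not None else np.zeros(len(samples)))
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    if n_multi:
        log.info("skipped %d multi-allelic records in %s", n_multi, path)
    if not rows:
        raise ParseError(f"no biallelic records in {path}")
    var = pd.DataFrame(rows).set_index("variant_id")
    idx, cols = var.index, pd.Index(samples)
    return GenotypeTable(
        variants=var,
        calls=pd.DataFrame(np.vstack(calls), index=idx, columns=cols),
        gq=pd.DataFrame(np.vstack(gqs), index=idx, columns=cols),
        dosage=pd.DataFrame(np.vstack(dss), index=idx, columns=cols),
        depth=pd.DataFrame(np.vstack(dps), index=idx, columns=cols) if has_depth else None,
    )


def write_genotypes(gt: GenotypeTable, path: str | Path) -> None:
    """Write a :class:`GenotypeTable` as an uncompressed VCF 4.2 file."""
    path = Path(path)
    var = gt.variants.sort_values(["chrom", "pos"], kind="mergesort")
    calls = gt.calls.loc[var.index].to_numpy()
    gq = gt.gq.loc[var.index].to_numpy()
    ds = gt.dosage.loc[var.index].to_numpy()
    dp = None if gt.depth is None else gt.depth.loc[var.index].to_numpy()
    gt_str = {HOM_REF: "0/0", HET: "0/1", HOM_ALT: "1/1", MISSING: "./."}
    fmt = "GT:GQ:DS" + (":DP" if dp is not None else "")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DR2,Number=1,Type=Float,Description="Estimated imputation dosage r-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Phred-scaled genotype quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alt allele dosage">\n')
        if dp is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in var["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gt.samples) + "\n")
        for i, (vid, row) in enumerate(var.iterrows()):
            info = "." if np.isnan(row["dr2"]) else f"DR2={row['dr2']:.4f}"
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(vid),
                str(row["ref_allele"]), str(row["alt_allele"]), ".", "PASS", info, fmt,
            ]
            for j in range(calls.shape[1]):
                d = ds[i, j]
                cell = f"{gt_str[int(calls[i, j])]}:{int(round(gq[i, j]))}:" + (
                    "." if np.isnan(d) else f"{d:.3f}"
                )
                if dp is not None:
                    cell += f":{int(dp[i, j])}"
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# expression / allelic counts / sample sheet TSVs
# ---------------------------------------------------------------------------

_GENE_COLS = ["gene_id", "chrom", "start", "end", "gc_fraction"]


def read_expression(path: str | Path, raw_counts: bool = True) -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    The first five columns are the gene annotation (``gene_id, chrom, start,
    end, gc_fraction``); the remaining header entries are sample ids.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _GENE_COLS if c not in df.columns]
    if missing:
        raise ParseError(f"expression file missing annotation columns: {missing}")
    genes = df[_GENE_COLS].set_index("gene_id")
    genes["chrom"] = genes["chrom"].astype(str)
    values = df.drop(columns=_GENE_COLS[1:]).set_index("gene_id")
    if raw_counts:
        arr = values.to_numpy()
        if not np.allclose(arr, np.round(arr)):
            raise ParseError("raw counts requested but file contains non-integer values")
        values = values.round().astype(np.int64)
    return ExpressionMatrix(genes=genes, values=values, is_raw_counts=raw_counts)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    out = expr.genes.copy()
    out = out.join(expr.values)
    out.index.name = "gene_id"
    fmt = "%d" if expr.is_raw_counts else None
    out.reset_index().to_csv(path, sep="\t", index=False, float_format="%.10g" if fmt is None else None)


def _read_bed_trees(paths: Iterable[str | Path], scored: bool = False) -> dict[str, IntervalTree]:
    """Load BED files (0-based half-open) into per-chromosome interval trees."""
    trees: dict[str, IntervalTree] = {}
    for p in paths:
        with open(p) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ParseError(f"{p}:{ln}: BED line has < 3 fields")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if end <= start:
                    continue
                score = float(parts[4]) if scored and len(parts) > 4 else 1.0
                trees.setdefault(chrom, IntervalTree()).addi(start, end, score)
    return trees


def read_allelic_counts(
    path: str | Path,
    exclusion_beds: Sequence[str | Path] = (),
    mappability_bed: str | Path | None = None,
) -> AllelicCountTable:
    """Read per-sample allelic counts and attach site flags from BED tracks.

    A variant at 1-based position ``pos`` is flagged ``in_excluded_region``
    when the 0-based position ``pos - 1`` falls inside any exclusion
    interval.  Mappability is taken from the (scored) mappability BED by the
    same overlap rule and defaults to 1.0 when no track is given.
    """
    df = pd.read_csv(path, sep="\t")
    need = ["variant_id", "sample_id", "chrom", "pos", "ref_count", "alt_count"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ParseError(f"allelic count file missing columns: {missing}")
    df["chrom"] = df["chrom"].astype(str)
    excl = _read_bed_trees(exclusion_beds)
    mapp = _read_bed_trees([mappability_bed], scored=True) if mappability_bed else {}

    def flag_excluded(chrom: str, pos: int) -> bool:
        t = excl.get(chrom)
        return bool(t and t.overlaps_point(pos - 1))

    def get_mapp(chrom: str, pos: int) -> float:
        t = mapp.get(chrom)
        if not t:
            return 1.0
        hits = t[pos - 1]
        return min(iv.data for iv in hits) if hits else 1.0

    sites = df[["chrom", "pos"]].drop_duplicates()
    sites["in_excluded_region"] = [
        flag_excluded(c, p) for c, p in zip(sites["chrom"], sites["pos"])
    ]
    sites["mappability"] = [get_mapp(c, p) for c, p in zip(sites["chrom"], sites["pos"])]
    df = df.merge(sites, on=["chrom", "pos"], how="left")
    return AllelicCountTable(data=df)


def write_allelic_counts(table: AllelicCountTable, path: str | Path) -> None:
    cols = ["variant_id", "sample_id", "chrom", "pos", "ref_count", "alt_count"]
    table.data[cols].to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t").set_index("sample_id")
    if "is_reference_set" in df.columns:
        df["is_reference_set"] = df["is_reference_set"].astype(bool)
    return SampleSheet(data=df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    out = sheet.data.copy()
    out.index.name = "sample_id"
    out.reset_index().to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as a TSV with deterministic order.

    Rows are stably sorted by whichever of ``chrom, pos, gene_id`` are
    present; two runs on the same input produce byte-identical files.
    """
    df = results.copy()
    sort_cols = [c for c in ("chrom", "pos", "gene_id") if c in df.columns]
    if sort_cols:
        df = df.sort_values(sort_cols, kind="mergesort")
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
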