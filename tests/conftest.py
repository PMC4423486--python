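import numpy as np
import pandas as pd
import pytest

from rnaqtl.dataio import GenotypeTable, SampleSheet
from rnaqtl.synthetic_data import SimConfig, simulate_all


@pytest.fixture(scope="session")
def small_sim():
    """A small default-structure cohort shared by read-only tests."""
    cfg = SimConfig(
        n_samples={"EUR": 40, "AFR": 15, "ASN": 10},
        n_genes=120,
        n_variants=400,
        seed=101,
    )
    return cfg, simulate_all(cfg)


def make_genotype_table(
    calls: np.ndarray,
    pos: np.ndarray | None = None,
    dr2: float | np.ndarray = 1.0,
    maf: np.ndarray | None = None,
    call_rate: np.ndarray | None = None,
    dosage: np.ndarray | None = None,
    gq: float = 99.0,
    depth: np.ndarray | None = None,
    samples: list | None = None,
) -> GenotypeTable:
    """Build a toy GenotypeTable from a calls matrix (variants x samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    V, S = calls.shape
    vids = pd.Index([f"v{i}" for i in range(V)], name="variant_id")
    cols = pd.Index(samples if samples is not None else [f"s{j}" for j in range(S)])
    nonmiss = calls != -1
    af = np.where(nonmiss, calls, 0).sum(axis=1) / np.maximum(2 * nonmiss.sum(axis=1), 1)
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos if pos is not None else np.arange(1, V + 1) * 100,
            "ref_allele": "A",
            "alt_allele": "G",
            "dr2": dr2,
            "maf": maf if maf is not None else np.minimum(af, 1 - af),
            "call_rate": call_rate if call_rate is not None else nonmiss.mean(axis=1),
        },
        index=vids,
    )
    if dosage is None:
        dosage = np.where(calls == -1, np.nan, calls).astype(float)
    return GenotypeTable(
        variants=variants,
        calls=pd.DataFrame(calls, index=vids, columns=cols),
        gq=pd.DataFrame(np.full((V, S), float(gq)), index=vids, columns=cols),
        dosage=pd.DataFrame(np.asarray(dosage, float), index=vids, columns=cols),
        depth=None if depth is None else pd.DataFrame(depth, index=vids, columns=cols),
    )


def make_sheet(samples, **overrides) -> SampleSheet:
    n = len(samples)
    data = pd.DataFrame(
        {
            "study_id": overrides.get("study_id", ["study0"] * n),
            "population": overrides.get("population", ["EUR"] * n),
            "tissue": overrides.get("tissue", ["LCL"] * n),
            "is_reference_set": overrides.get("is_reference_set", [False] * n),
            "annotated_sex": overrides.get("annotated_sex", ["unknown"] * n),
            "n_expressed_genes": overrides.get("n_expressed_genes", [0] * n),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return SampleSheet(data=data)
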