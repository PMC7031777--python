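import numpy as np
import pandas as pd
import pytest

from subreg.pipeline import run_full
from subreg.synthetic_data import PlantedModel, generate_annotation

SMALL_CONFIG = {
    "model": {"n_genes": 2000, "n_tfs": 200},
    "expression": {"n_datasets": 5, "samples_per_dataset": 30},
    "chipseq": {"n_random": 500},
    "knockdown": {"n_random": 300},
}


@pytest.fixture(scope="session")
def tiny_model():
    return PlantedModel.random(
        n_genes=300,
        n_tfs=60,
        n_regulators_per_subtype=2,
        n_targets_per_regulator=8,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_annotation(tiny_model):
    return generate_annotation(tiny_model, n_chromosomes=2)


@pytest.fixture(scope="session")
def small_bundle():
    """One full pipeline run on a small planted cohort, shared read-only."""
    return run_full(SMALL_CONFIG, seed=1)


def toy_annotation(tss_list, chrom="chr1", window_genes=None):
    """Hand-built annotation with one gene per TSS position."""
    rows = []
    for i, tss in enumerate(tss_list):
        rows.append(
            {
                "gene_id": f"g{i}",
                "chrom": chrom,
                "start": tss,
                "end": tss + 1000,
                "strand": "+",
                "tss": tss,
                "is_tf": False,
            }
        )
    df = pd.DataFrame(rows)
    return df.set_index("gene_id", drop=False)


def toy_peaks(rows):
    """Peak table from (chrom, start, end, signal) tuples."""
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "signalValue"])
    df["name"] = [f"p{i}" for i in range(len(df))]
    df["score"] = 0
    df["strand"] = "."
    df["pValue"] = -1.0
    df["qValue"] = -1.0
    df["peak"] = -1
    return df
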