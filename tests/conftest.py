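import numpy as np
import pandas as pd
import pytest

import pbscreen as pb


def make_sites(rows, columns=("sample_id", "chrom", "pos", "orientation",
                              "transposon_end", "read_count")):
    """Build an insertion table from plain tuples, filling metadata columns."""
    df = pd.DataFrame(list(rows), columns=list(columns))
    for c in ("tumor_id", "region_id", "tissue"):
        if c not in df.columns:
            df[c] = ""
    if "read_count" not in df.columns:
        df["read_count"] = 1
    return df


@pytest.fixture(scope="session")
def small_screen():
    """A compact two-chromosome screen with two strong drivers, shared by
    several end-to-end tests."""
    conf = pb.SimConfig(chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
                        n_genes=30, cohort_sizes={"brain": 6, "spinal": 6},
                        lambda_bg=20)
    ttaa, genes, _ = pb.simulate_genome(conf, seed=11)
    conf.drivers = pb.choose_drivers(genes, n=2, pi=1.0, min_separation=400_000)
    screen = pb.simulate_cohort(ttaa, genes, conf, seed=12)
    return conf, ttaa, genes, screen


@pytest.fixture()
def toy_gene():
    return {"gene_id": "g1", "name": "GeneA", "chrom": "chr1",
            "start": 100_000, "end": 150_000, "strand": "+"}


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
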