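import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from sdrkit.io import DepthTable, GenotypeMatrix
from sdrkit.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A compact cohort that keeps the full planted structure but runs fast."""
    return SimulationConfig(
        seed=11,
        chrom_lengths={"chrA": 3_000_000, "chrB": 1_500_000},
        sdr_chrom="chrA",
        sdr_interval=(800_000, 2_200_000),
        y_specific_interval=(1_300_000, 1_600_000),
        snp_rate=1e-4,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default study design (30M/30F, 6.39-8.73 Mb SDR)."""
    return simulate_cohort(SimulationConfig(seed=7))


def make_matrix(codes, sexes, chrom="chr1", start_pos=100, quals=None,
                spacing=10):
    """Build a GenotypeMatrix from a codes array and a sex string like 'MMFF'."""
    codes = np.asarray(codes, dtype=np.int8)
    n_sites, n_ind = codes.shape
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos": [start_pos + spacing * i for i in range(n_sites)],
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
            "qual": quals if quals is not None else [50.0] * n_sites,
        }
    )
    samples = pd.DataFrame(
        {"id": [f"i{j}" for j in range(n_ind)], "sex": list(sexes)}
    )
    return GenotypeMatrix(sites=sites, samples=samples, codes=codes)


def make_depth(gm, mean=30.0, chrom_len=10_000):
    """A single full-coverage window of constant depth for a toy matrix."""
    chroms = list(dict.fromkeys(gm.sites["chrom"]))
    windows = pd.DataFrame(
        {"chrom": chroms, "start": [0] * len(chroms),
         "end": [chrom_len] * len(chroms)}
    )
    values = np.full((len(chroms), gm.n_samples), mean)
    return DepthTable(windows=windows, values=values,
                      sample_ids=list(gm.samples["id"]))


def interval_jaccard(a, b):
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0
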