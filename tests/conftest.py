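import numpy as np
import pytest

from sexlinkscan.core_io import Specimen, VariantTable
from sexlinkscan.simpop import SimConfig, simulate_population


@pytest.fixture(scope="session")
def y_insertion_sim():
    """Small read-bearing population carrying a 2-kb male-limited insertion."""
    cfg = SimConfig(seed=3, n_chromosomes=1, chromosome_length_bp=60_000,
                    architecture="y_insertion")
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def null_small_sim():
    """Small read-bearing population with no sex linkage."""
    cfg = SimConfig(seed=11, n_chromosomes=1, chromosome_length_bp=60_000)
    return simulate_population(cfg)


def make_panel(n_males, n_females, population="pop"):
    return (
        [Specimen(f"m{i + 1}", "male", population) for i in range(n_males)]
        + [Specimen(f"f{i + 1}", "female", population) for i in range(n_females)]
    )


def single_site_table(genotypes, specimens, chrom="LG01", pos=100):
    g = np.asarray(genotypes, dtype=np.int8)[None, :, :]
    return VariantTable(
        np.array([chrom], dtype=object), np.array([pos]),
        np.array(["A"], dtype=object), [("C",)], g, specimens,
    )
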