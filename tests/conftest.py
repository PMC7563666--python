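import numpy as np
import pandas as pd
import pytest

from sexscan.records import GenotypeMatrix


@pytest.fixture(scope="session")
def clean_xy_family():
    """Error-free, fully called XY family (15 sons + 14 daughters)."""
    from sexscan.simdata import FamilyDesign, simulate_family

    design = FamilyDesign(genotyping_error=0.0, missing_rate=0.0, n_sites=600)
    return design, simulate_family(design, seed=11)


def make_matrix(genotypes, sexes, roles, pos=None, chrom="LG23"):
    """Hand-build a GenotypeMatrix from a (sites, individuals, 2) list."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = g.shape[0], g.shape[1]
    if pos is None:
        pos = list(range(1000, 1000 + 100 * n_sites, 100))
    sites = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "ref": ["A"] * n_sites, "alt": ["G"] * n_sites,
    })
    individuals = pd.DataFrame({
        "id": [f"i{k}" for k in range(n_ind)],
        "sex": sexes, "role": roles,
    })
    return GenotypeMatrix(sites=sites, genotypes=g, individuals=individuals)
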