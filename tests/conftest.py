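import numpy as np
import pandas as pd
import pytest

from bloodeqtl import GenotypeMatrix, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-animal cohort with known cis/trans architecture."""
    config = SimulationConfig(
        n_sires=4, progeny_per_sire=10, n_snps=80, n_probes=15,
        n_chromosomes=3, n_cis_effects=3, n_trans_effects=1,
        h2_polygenic=0.3, seed=11,
    )
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def midsize_cohort():
    """A 250-animal cohort large enough for association power."""
    config = SimulationConfig(
        n_sires=10, progeny_per_sire=25, n_snps=200, n_probes=20,
        n_chromosomes=4, n_cis_effects=3, n_trans_effects=1,
        h2_polygenic=0.4, maf_range=(0.2, 0.5), seed=5,
    )
    return config, simulate_cohort(config)


def toy_genotypes(dosage_rows, chroms=None, positions=None):
    """Build a GenotypeMatrix from a plain list of dosage rows."""
    arr = np.asarray(dosage_rows, dtype=float)
    n, m = arr.shape
    samples = [f"s{i}" for i in range(n)]
    snps = [f"v{j}" for j in range(m)]
    snp_map = pd.DataFrame(
        {
            "chromosome": chroms if chroms is not None else ["1"] * m,
            "position_bp": positions if positions is not None else (np.arange(m) + 1) * 1000,
            "ref": "A",
            "alt": "G",
        },
        index=pd.Index(snps, name="snp_id"),
    )
    return GenotypeMatrix(
        pd.DataFrame(arr, index=samples, columns=snps), snp_map
    )
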