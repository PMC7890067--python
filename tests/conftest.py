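import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from caseonly.simdata import SimConfig, simulate_cohorts


@pytest.fixture(scope="session")
def small_cohorts():
    """A compact two-consortium dataset with one planted interaction, one
    population effect and one carrier-linked variant (4 blocks x 5 SNPs)."""
    cfg = SimConfig(
        n_bcac_cases=1200, n_bcac_controls=1200,
        n_cimba_cases=1200, n_cimba_unaffected=1200,
        n_blocks=4, snps_per_block=5, ld_rho=0.4,
        allele_freq_range=(0.2, 0.4),
        interaction_effects=[("var00002", float(np.log(1.5)))],
        population_effects=[("var00007", 0.3)],
        linked_to_carrier=[("var00012", 0.10)],
        genotyped_fraction=1.0,
        seed=42,
    )
    matrix, samples, truth = simulate_cohorts(cfg)
    return cfg, matrix, samples, truth


@pytest.fixture()
def toy_samples():
    """Minimal valid sample table: two cohorts, two countries."""
    rng = np.random.default_rng(0)
    n = 40
    cohort = np.r_[["CIMBA"] * 20, ["BCAC"] * 20]
    return pd.DataFrame({
        "sample_id": [f"S{i}" for i in range(n)],
        "cohort": cohort,
        "status": ["case"] * n,
        "carrier_gene": np.where(cohort == "CIMBA", "BRCA1", "none"),
        "age": rng.uniform(30, 70, n).round(1),
        "country": np.tile(["C1", "C2"], n // 2),
        "er_status": ["unknown"] * n,
    })
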