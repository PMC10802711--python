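import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gapfseq as g

settings.register_profile(
    "default", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("default")

SMALL_GENOME = {f"chr{i}": 1_000_000 for i in range(1, 23)} | {
    "chrX": 1_000_000,
    "chrY": 1_000_000,
}


@pytest.fixture(scope="session")
def small_binset():
    return g.build_bins(SMALL_GENOME, 1000)


@pytest.fixture(scope="session")
def small_cohort():
    """12-pair cohort on a 24 x 1 Mb toy genome; strong planted clusters."""
    spec = g.CohortSpec(
        n_tumor=12,
        n_normal=12,
        genome=SMALL_GENOME,
        n_artifact_bins=300,
        n_dispersed_hcbs=400,
    )
    return g.simulate_cohort(spec, seed=7)


@pytest.fixture(scope="session")
def small_cohort_profiles(small_cohort):
    co = small_cohort
    bl = g.identify_background_bins(co.coverages, co.labels)
    filtered = [g.apply_blocklist(c, bl) for c in co.coverages]
    profs = [
        g.chromosome_profile(g.top_k_hcbs(c, 1000), co.bins.chrom_names) for c in filtered
    ]
    import pandas as pd

    X = pd.DataFrame({p.sample_id: p.counts for p in profs}).T
    y = np.array([1 if l == "tumor" else 0 for l in co.labels])
    return X, y, bl, filtered, profs


def random_coverage(binset, seed, mapq_min=40, total=10_000_000):
    rng = np.random.default_rng(seed)
    raw = rng.poisson(3.0, binset.n_bins)
    return g.BinCoverage.from_counts(f"rand{seed}", raw, total, binset, mapq_min)
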