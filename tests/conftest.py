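import numpy as np
import pandas as pd
import pytest

from metabomr.sumstats import SUMSTAT_COLUMNS, HarmonizedSet, SumStatTable


def make_table(rows, trait_name="trait", trait_type="continuous"):
    """Build a SumStatTable from a list of row dicts (test convenience)."""
    df = pd.DataFrame(rows)
    for col, default in (("chrom", "1"), ("n", 10_000)):
        if col not in df.columns:
            df[col] = default
    if "pval" not in df.columns:
        from scipy import stats
        df["pval"] = 2 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    df = df[SUMSTAT_COLUMNS].set_index("variant_id", drop=False)
    df.index.name = None
    return SumStatTable(trait_name=trait_name, trait_type=trait_type, df=df)


def make_harmonized(beta_x, se_y, beta_y, se_x=None, n_exposure=100_000,
                    n_outcome=500_000):
    """Small HarmonizedSet straight from arrays."""
    beta_x = np.asarray(beta_x, float)
    k = len(beta_x)
    se_x = np.full(k, 0.01) if se_x is None else np.asarray(se_x, float)
    return HarmonizedSet(
        variant_ids=[f"rs{i}" for i in range(k)],
        beta_x=beta_x, se_x=se_x,
        beta_y=np.asarray(beta_y, float), se_y=np.asarray(se_y, float),
        eaf_x=np.full(k, 0.3), eaf_y=np.full(k, 0.3),
        n_exposure=n_exposure, n_outcome=n_outcome)


@pytest.fixture
def five_variant_set():
    """Deterministic 5-variant harmonized set for closed-form oracles."""
    rng = np.random.default_rng(42)
    beta_x = rng.uniform(0.05, 0.2, 5)
    se_y = rng.uniform(0.01, 0.03, 5)
    beta_y = 0.4 * beta_x + rng.normal(0, se_y)
    return make_harmonized(beta_x, se_y, beta_y)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no metabolite effects (shared across tests)."""
    from metabomr.simulate import CohortSimConfig, simulate_cohort
    return simulate_cohort(CohortSimConfig(n=3000, seed=101))
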