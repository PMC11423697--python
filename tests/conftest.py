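import numpy as np
import pandas as pd
import pytest

from twinsurv.synthetic import CohortConfig, generate_cohort


def make_outcomes(times, events, ids=None) -> pd.DataFrame:
    idx = pd.Index(
        ids if ids is not None else [f"s{i}" for i in range(len(times))],
        name="individual_id",
    )
    return pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int)},
        index=idx,
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """One mid-sized cohort with two strong causal CpGs, reused across tests."""
    cfg = CohortConfig(
        n_pairs=200,
        n_cpgs=40,
        n_causal=2,
        causal_log_shr=(np.log(3.0), -np.log(3.0)),
        base_rate_cause1=0.01,
        missing_rate=0.02,
        seed=314,
    )
    cohort, meth, outcomes, truth = generate_cohort(cfg)
    return cfg, cohort, meth, outcomes, truth


@pytest.fixture(scope="session")
def demo_residuals(demo_cohort):
    from twinsurv import impute_missing, residualize

    _, cohort, meth, _, _ = demo_cohort
    return residualize(impute_missing(meth, cohort), cohort)
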