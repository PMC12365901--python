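import numpy as np
import pandas as pd
import pytest

from idhcal.calls import records_from_counts, records_to_frame
from idhcal.protocol import two_stage_protocol
from idhcal.simulate import CohortSimConfig, simulate_counts


def cohort_frame(n: int, seed: int = 1, cohort_key: int = 1, prefix: str = "A",
                 **overrides) -> pd.DataFrame:
    """Simulated post-ensemble subject records as a DataFrame."""
    cfg = CohortSimConfig(n_subjects=n, seed=seed, cohort_key=cohort_key,
                          subject_prefix=prefix, **overrides)
    _, counts = simulate_counts(cfg)
    recs = records_from_counts(
        counts[["subject_id", "n_mutant", "n_wildtype"]],
        counts[["subject_id", "true_label"]],
    )
    return records_to_frame(recs)


@pytest.fixture(scope="session")
def default_cohorts():
    """The default two-stage cohorts: fit n=1236, eval n=164 (disjoint ids)."""
    fit = cohort_frame(1236, seed=1, cohort_key=1, prefix="A")
    ev = cohort_frame(164, seed=1, cohort_key=2, prefix="B")
    return fit, ev


@pytest.fixture(scope="session")
def default_report(default_cohorts):
    """Two-stage protocol run on the default cohorts (shared: MCMC is the
    expensive part)."""
    fit, ev = default_cohorts
    return two_stage_protocol(fit, ev, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
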