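import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from goalplane.simdata import SimCohortConfig, build_cohort_profiles, simulate_trials


@pytest.fixture(scope="session")
def default_config() -> SimCohortConfig:
    return SimCohortConfig(master_seed=42)


@pytest.fixture(scope="session")
def one_participant(default_config) -> pd.DataFrame:
    """One simulated participant's raw trial table (125 trials)."""
    profile = build_cohort_profiles(default_config)[0]
    return simulate_trials(profile, default_config)


def make_trials(rows, participant_id="P1"):
    """Build a trial table from (block, trial, force, bx, by, dx, errx, valid) rows.

    Responses are placed at ``(bx + errx, by)``; ``b_after = (bx + dx, by)``.
    """
    recs = []
    for block, trial, force, bx, by, dx, errx, valid in rows:
        recs.append(
            dict(
                participant_id=participant_id,
                block=block,
                trial=trial,
                force_cN=force,
                bx_before=bx,
                by_before=by,
                bx_after=bx + dx,
                by_after=by,
                resp_x=bx + errx,
                resp_y=by,
                valid_flight=valid,
                aq=20,
                expert=False,
            )
        )
    return pd.DataFrame(recs)
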