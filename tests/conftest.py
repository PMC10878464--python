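import numpy as np
import pytest

from palscore.cdev import score_team
from palscore.cohort import CohortParams, perfect_record, simulate_cohort


@pytest.fixture(scope="session")
def cohort():
    """A default 27-team stratified synthetic cohort (fixed seed)."""
    return simulate_cohort(CohortParams(seed=2024))


@pytest.fixture(scope="session")
def cohort_scores(cohort):
    return [score_team(r) for r in cohort]


@pytest.fixture(scope="session")
def perfect():
    return perfect_record()


@pytest.fixture(scope="session")
def random_teams():
    """A pool of 300 random synthetic team logs across varied seeds."""
    params = CohortParams()
    out = []
    for i, ss in enumerate(np.random.SeedSequence(777).spawn(300)):
        group = "aid_not_used" if i % 2 else "aid_used"
        from palscore.cohort import simulate_team
        out.append(simulate_team(params, group,
                                 rng=np.random.default_rng(ss),
                                 team_id=f"R{i:03d}"))
    return out
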