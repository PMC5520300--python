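import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cacetrial import Arm, CrossTab, TrialCohort, TrialRecord, motivating_trial_config, generate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: printed arm x quit-status birth-weight summaries of the motivating trial
#: (n, mean g, sd g per cell; 16 + 9 weights missing)
TABLE1_CELLS = {
    (Arm.CONTROL, False): (262, 3075.0, 569.0),
    (Arm.CONTROL, True): (25, 3586.0, 566.0),
    (Arm.INCENTIVES, False): (227, 3053.0, 588.0),
    (Arm.INCENTIVES, True): (68, 3432.0, 527.0),
}
TABLE1_MISSING = {Arm.CONTROL: 16, Arm.INCENTIVES: 9}

#: printed arm-level and quit-status-level summaries (mean, sd, n)
ARM_SUMMARIES = {
    "incentives": (3141.0, 595.0, 295),
    "control": (3120.0, 586.0, 287),
    "quitters": (3473.0, 539.0, 93),
    "smokers": (3065.0, 577.0, 489),
}


@pytest.fixture(scope="session")
def table1() -> CrossTab:
    return CrossTab.from_cell_summaries(TABLE1_CELLS, n_missing=TABLE1_MISSING)


def make_cohort(arm, quit, weight, stratum=None) -> TrialCohort:
    """Build a cohort from parallel sequences (True arm = incentives)."""
    records = []
    for i, (a, q, w) in enumerate(zip(arm, quit, weight)):
        records.append(
            TrialRecord(
                id=str(i),
                arm=Arm.INCENTIVES if a else Arm.CONTROL,
                quit=None if w is None else bool(q),
                birth_weight=w,
                stratum=None if stratum is None else stratum[i],
            )
        )
    return TrialCohort(tuple(records), provenance="test")


@pytest.fixture(scope="session")
def trial_like_cohort() -> TrialCohort:
    """Synthetic cohort matching the trial's headline counts (25 missing)."""
    return generate(motivating_trial_config(seed=22))


def random_cohort(rng: np.random.Generator, n: int = 80) -> TrialCohort:
    """A random estimable cohort: both arms nonempty, all four cells filled."""
    while True:
        arm = rng.random(n) < 0.5
        quit = rng.random(n) < rng.uniform(0.1, 0.6)
        weight = rng.uniform(500.0, 6000.0, size=n)
        cells = {(a, q): ((arm == a) & (quit == q)).sum() for a in (0, 1) for q in (0, 1)}
        if all(v > 0 for v in cells.values()):
            return make_cohort(arm, quit, weight)
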