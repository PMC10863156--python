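import numpy as np
import pytest

from contextfx import ArmSummary


@pytest.fixture
def worked_example_arms():
    """The two-arm example printed alongside the PCE critique.

    The arm whose standardized change is 2.5 sits in the numerator
    (placebo) slot of the ratio, as required for the printed value
    exp(ln(2.5/1)) = 2.50.
    """
    numerator = ArmSummary(
        study_id="worked",
        role="placebo",
        n=100,
        mean_baseline=4.0,
        sd_baseline=1.0,
        mean_followup=1.5,
        sd_followup=1.0,
    )
    denominator = ArmSummary(
        study_id="worked",
        role="active",
        n=100,
        mean_baseline=4.1,
        sd_baseline=1.1,
        mean_followup=3.0,
        sd_followup=1.1,
    )
    return numerator, denominator


def random_arm(rng: np.random.Generator, study_id="S", role="placebo") -> ArmSummary:
    """A random valid arm summary with a strictly positive improvement."""
    baseline = rng.uniform(20, 80)
    return ArmSummary(
        study_id=study_id,
        role=role,
        n=int(rng.integers(10, 500)),
        mean_baseline=baseline,
        sd_baseline=rng.uniform(0.5, 25),
        mean_followup=baseline - rng.uniform(0.1, 15),
        sd_followup=rng.uniform(0.5, 25),
        corr_pre_post=rng.uniform(-0.5, 0.9),
    )
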