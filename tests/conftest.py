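import dataclasses

import pytest

from cogcourse import SimConfig, generate_cohort, null_config, records_to_frame
from cogcourse.battery import GROUP_CONTROL, GROUP_PATIENT


def make_sim(**overrides) -> SimConfig:
    """Default study-like config with keyword overrides."""
    return dataclasses.replace(SimConfig(), **overrides)


@pytest.fixture(scope="session")
def null_cohort_df():
    """Zero-noise, zero-effect cohort: every score equals its configured
    control-baseline mean at both waves."""
    return records_to_frame(generate_cohort(null_config()))


@pytest.fixture(scope="session")
def small_cohort_df():
    """Seeded moderately sized cohort used by several scoring/model tests."""
    return records_to_frame(generate_cohort(make_sim(seed=7)))


def set_all_subtests(config: SimConfig, **subtest_overrides) -> SimConfig:
    """Apply the same generative overrides to every subtest definition."""
    defs = tuple(
        dataclasses.replace(s, **subtest_overrides) for s in config.subtest_defs
    )
    return dataclasses.replace(config, subtest_defs=defs)


def flat_practice(patient: float, control: float) -> dict[str, float]:
    return {GROUP_PATIENT: patient, GROUP_CONTROL: control}
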