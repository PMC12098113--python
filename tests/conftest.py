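"""Shared fixtures: one default synthetic cohort per test session."""

import pytest

from asneo.events import attach_significance, filter_significant
from asneo.synthetic import SimConfig, SyntheticCohort, simulate_cohort, write_cohort


@pytest.fixture(scope="session")
def cohort() -> SyntheticCohort:
    """Default-config cohort with significance already attached."""
    c = simulate_cohort(SimConfig(seed=11))
    attach_significance(c.events)
    return c


@pytest.fixture(scope="session")
def cohort_dir(cohort, tmp_path_factory):
    """The same cohort written to disk (file-level round trips)."""
    outdir = tmp_path_factory.mktemp("cohort")
    write_cohort(cohort, outdir)
    return outdir


@pytest.fixture(scope="session")
def significant_events(cohort):
    return filter_significant(cohort.events)
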