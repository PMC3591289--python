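"""Shared fixtures.

The minimal-burster ground truth (oracle manifest), its scanned bursting
range and its continuation branch are expensive (tens of seconds each), so
they are computed once per session and shared across the scan,
multistability, pipeline and acceptance tests.
"""

import numpy as np
import pytest

from hcoscan.continuation import (branch_from_high_leak, continue_branch,
                                  stable_intervals)
from hcoscan.integrate import settle
from hcoscan.scan import scan_bursting_range
from hcoscan.synthetic import MinimalBurster, characterize_minimal_burster


@pytest.fixture(scope="session")
def burster():
    return MinimalBurster()


@pytest.fixture(scope="session")
def burster_manifest(burster):
    """Oracle-derived ground truth of the shipped minimal burster."""
    return characterize_minimal_burster(burster)


@pytest.fixture(scope="session")
def scanned_range(burster, burster_manifest):
    """Step-refinement scan of the robust-bursting range."""
    man = burster_manifest
    return scan_bursting_range(burster, man.start_g, man.bursting_state)


@pytest.fixture(scope="session")
def burster_branch(burster):
    """Continuation branch of the burster from g = 20 nS."""
    start = branch_from_high_leak(burster, burster.rest_guess(), g_start=20.0)
    return continue_branch(burster, start)


@pytest.fixture(scope="session")
def burster_intervals(burster_branch):
    return stable_intervals(burster_branch)


@pytest.fixture(scope="session")
def bursting_attractor_state(burster_manifest):
    return np.asarray(burster_manifest.bursting_state)


@pytest.fixture(scope="session")
def recovered_hco():
    from hcoscan.synthetic import make_hco_fixture
    return make_hco_fixture("recovered")


@pytest.fixture(scope="session")
def stuck_hco():
    from hcoscan.synthetic import make_hco_fixture
    return make_hco_fixture("both_at_rest")


@pytest.fixture(scope="session")
def recovered_outcome(recovered_hco):
    from hcoscan.hco import run_perturbation
    return run_perturbation(recovered_hco.coupled, recovered_hco.initial_state,
                            recovered_hco.reset_state,
                            recovered_hco.which_cell, keep_trajectory=True)


@pytest.fixture(scope="session")
def stuck_outcome(stuck_hco):
    from hcoscan.hco import run_perturbation
    return run_perturbation(stuck_hco.coupled, stuck_hco.initial_state,
                            stuck_hco.reset_state, stuck_hco.which_cell,
                            keep_trajectory=True)
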