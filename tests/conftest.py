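"""Shared fixtures: synthetic sessions analyzed once per test run.

The coding session uses half the emulated experiment's trial count
(48 trials per category); the control sessions use a quarter (24). The
statistical structure (coupling depth 0.8, von Mises concentration 4,
1 Hz modulator, 84 Hz carrier, category phases 0/90/180/270 or a shared
180 deg) is the study configuration itself.
"""

import numpy as np
import pytest

from phasecode.pipeline import analyze_electrode
from phasecode.synth import SimulationConfig, generate_null_session, generate_session


@pytest.fixture(scope="session")
def coding_config():
    return SimulationConfig(n_trials_per_category=48, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(n_trials_per_category=24, seed=7)


@pytest.fixture(scope="session")
def coding_session(coding_config):
    return generate_session(coding_config)


@pytest.fixture(scope="session")
def pac_no_coding_session(small_config):
    return generate_null_session(small_config, "pac_no_coding")


@pytest.fixture(scope="session")
def no_pac_session(small_config):
    return generate_null_session(small_config, "no_pac")


@pytest.fixture(scope="session")
def locked_session(small_config):
    return generate_null_session(small_config, "coding_no_pac")


@pytest.fixture(scope="session")
def coding_analysis(coding_session):
    """Full single-electrode analysis of the coding session (cached)."""
    session, truth = coding_session
    report, inter = analyze_electrode(
        session,
        name="coding",
        seed=11,
        n_electrodes_family=167,
        ground_truth=truth,
        run_mi=False,
        run_fmin=True,
    )
    return {"session": session, "truth": truth, "report": report, "inter": inter}


@pytest.fixture(scope="session")
def shared_analysis(pac_no_coding_session):
    """Analysis of the shared-preferred-phase (coupling-without-coding) session."""
    session, truth = pac_no_coding_session
    report, inter = analyze_electrode(
        session,
        name="shared",
        seed=13,
        n_electrodes_family=167,
        ground_truth=truth,
        run_mi=True,
        run_fmin=False,
    )
    return {"session": session, "truth": truth, "report": report, "inter": inter}


@pytest.fixture(scope="session")
def no_pac_analysis(no_pac_session):
    session, truth = no_pac_session
    report, inter = analyze_electrode(
        session,
        name="no_pac",
        seed=17,
        n_electrodes_family=167,
        ground_truth=truth,
        run_mi=False,
        run_fmin=False,
    )
    return {"session": session, "truth": truth, "report": report, "inter": inter}


@pytest.fixture(scope="session")
def locked_analysis(locked_session):
    session, truth = locked_session
    report, inter = analyze_electrode(
        session,
        name="locked",
        seed=19,
        n_electrodes_family=167,
        ground_truth=truth,
        run_mi=False,
        run_fmin=False,
    )
    return {"session": session, "truth": truth, "report": report, "inter": inter}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
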