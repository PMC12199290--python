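"""Shared fixtures: thermodynamic context and the heavy toy-study runs.

The bidirectional SMD batch and the metadynamics run of the double-well
study are session-scoped so the end-to-end and cross-check tests share one
simulation each.
"""

import pytest
from hypothesis import settings

from pathwork import benchmarks
from pathwork.neq_estimators import build_segment_work_set, cft_profile
from pathwork.thermo import ThermoContext

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def thermo300() -> ThermoContext:
    return ThermoContext(300.0)


@pytest.fixture(scope="session")
def dw_study():
    return benchmarks.make_double_well_study()


@pytest.fixture(scope="session")
def smd_slow(dw_study):
    """30+30 bidirectional SMD traces at the slow (40 ps) schedule."""
    return benchmarks.run_smd_batch(dw_study, seed=11)


@pytest.fixture(scope="session")
def smd_fast(dw_study):
    """30+30 traces at double pulling speed (20 ps) for dissipation checks."""
    return benchmarks.run_smd_batch(dw_study, duration=20.0, seed=13)


@pytest.fixture(scope="session")
def cft_fes(dw_study, smd_slow):
    fwd, bwd = smd_slow
    segments = build_segment_work_set(fwd, bwd, dw_study.path)
    return cft_profile(segments, dw_study.thermo, n_boot=200, seed=12)


@pytest.fixture(scope="session")
def metad_result(dw_study):
    return benchmarks.run_metad(dw_study, seed=17)
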