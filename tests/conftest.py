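"""Shared fixtures.

Expensive solves (flow fields, concentration fields, Dean cross-sections,
the default-geometry Reynolds sweep) are session-scoped so each is computed
once for the whole suite.  Oracle fixtures use moderate resolutions chosen
for runtime; the acceptance sweep uses the default study resolution.
"""


import pytest

from stentflow import (
    FluidProperties,
    InletSpec,
    SolverSettings,
    TransportProperties,
    make_fixture,
    solve_drug,
    solve_flow,
)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def straight_case(fluid):
    """Strut-free straight channel at 10 cells/mm, Re ~ 200 (Poiseuille oracle)."""
    geo, mesh = make_fixture("straight_channel", resolution=10)
    flow = solve_flow(mesh, fluid, InletSpec(v_char=0.22))
    return geo, mesh, flow


@pytest.fixture(scope="session")
def bend_case(fluid):
    """Strut-free 90-degree bend at low Re (fully developed well before the
    bend), for the curved-channel ODE oracle."""
    geo, mesh = make_fixture("bare_bend", resolution=10)
    flow = solve_flow(mesh, fluid, InletSpec(v_char=0.05))
    return geo, mesh, flow


@pytest.fixture(scope="session")
def dean_sweep():
    """Dean cross-section solutions for the four study Reynolds numbers
    (32x64 polar grid: the summary trends are resolution-insensitive)."""
    from stentflow import solve_dean_cross_section
    return [solve_dean_cross_section(Re, 0.15, n_r=32, n_theta=64)
            for Re in (200.0, 400.0, 600.0, 800.0)]


@pytest.fixture(scope="session")
def stented_straight_case(fluid):
    """Straight channel with the six struts at 10 cells/mm: a mid-cost case
    exercising strut blockage, recirculation and the drug solve."""
    geo, mesh = make_fixture("straight_channel", resolution=10, n_struts=6)
    flow = solve_flow(mesh, fluid, InletSpec(v_char=0.22))
    conc = solve_drug(mesh, flow, TransportProperties())
    return geo, mesh, flow, conc
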