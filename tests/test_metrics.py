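"""Metrics: WSS evaluation, low-WSS fractions, line profiles, segments."""

import numpy as np
import pytest

from stentflow import (
    FluidProperties,
    LineProfile,
    TransportProperties,
    WSSProfile,
    compute_wss,
    concentration_ratios,
    line_profile,
    low_wss_fraction,
    make_fixture,
    segment_stats,
    solve_drug,
)
from stentflow.drug_transport import ConcentrationField
from stentflow.metrics import LINE_IDS


def make_wss(wss_values, sides=None, lengths=None):
    n = len(wss_values)
    s = np.linspace(0.031, 0.045, n)
    return WSSProfile(
        s=s,
        side=np.asarray(sides if sides is not None else ["inner_bend"] * n,
                        dtype=object),
        wss=np.asarray(wss_values, dtype=float),
        length=np.asarray(lengths if lengths is not None else [1e-4] * n),
        stent_span=(0.030, 0.046),
    )


class TestComputeWSS:
    def test_poiseuille_closed_form(self, straight_case, fluid):
        """Plane Poiseuille: wall shear = 6 mu U / h on both walls."""
        geo, mesh, flow = straight_case
        prof = compute_wss(flow, mesh, fluid)
        exact = 6 * fluid.mu * 0.22 / geo.lumen_diameter
        mid = (prof.s > 0.03) & (prof.s < 0.045)
        assert np.abs(prof.wss[mid] - exact).max() / exact < 0.01

    def test_zero_flow_gives_zero_wss(self, straight_case, fluid):
        import copy
        _, mesh, flow = straight_case
        still = copy.copy(flow)
        still.u = np.zeros_like(flow.u)
        still.v = np.zeros_like(flow.v)
        prof = compute_wss(still, mesh, fluid)
        assert np.all(prof.wss == 0.0)

    def test_wss_linear_in_viscosity(self, straight_case, fluid):
        _, mesh, flow = straight_case
        p1 = compute_wss(flow, mesh, fluid)
        p2 = compute_wss(flow, mesh, FluidProperties(rho=fluid.rho,
                                                     mu=2 * fluid.mu))
        assert np.allclose(p2.wss, 2 * p1.wss)

    def test_face_lengths_cover_stented_arc(self, stented_straight_case):
        geo, mesh, flow, _ = stented_straight_case
        prof = compute_wss(flow, mesh).restrict(mesh.stent_span)
        # per side: interface + strut tops + 2 sides per strut of height w
        expected = geo.stent_length + 2 * geo.n_struts * geo.strut_size
        for side in ("inner_bend", "outer_bend"):
            got = prof.length[prof.side == side].sum()
            assert got == pytest.approx(expected, rel=0.02)

    def test_unconverged_flow_rejected(self, straight_case):
        import copy
        _, mesh, flow = straight_case
        bad = copy.copy(flow)
        bad.converged = False
        with pytest.raises(ValueError):
            compute_wss(bad, mesh)


class TestLowWSSFraction:
    def test_uniform_above_threshold(self):
        assert low_wss_fraction(make_wss([1.0] * 10)).total == 0.0

    def test_uniform_below_threshold(self):
        assert low_wss_fraction(make_wss([0.2] * 10)).total == 1.0

    def test_half_and_half(self):
        frac = low_wss_fraction(make_wss([0.2] * 5 + [1.0] * 5))
        assert frac.total == pytest.approx(0.5)

    def test_per_side_breakdown(self):
        prof = make_wss([0.2, 0.2, 1.0, 1.0],
                        sides=["inner_bend", "inner_bend",
                               "outer_bend", "outer_bend"])
        frac = low_wss_fraction(prof)
        assert frac.inner == 1.0 and frac.outer == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            low_wss_fraction(make_wss([1.0]), threshold=-1.0)
        empty = make_wss([])
        with pytest.raises(ValueError):
            low_wss_fraction(empty)


@pytest.fixture(scope="module")
def conc_constant():
    _, mesh = make_fixture("straight_channel", resolution=10, n_struts=6)
    phi = np.full(mesh.shape, 0.3)
    return mesh, ConcentrationField(mesh=mesh, phi=phi,
                                    props=TransportProperties(),
                                    converged=True)


class TestLineProfile:
    def test_constant_field(self, conc_constant):
        mesh, conc = conc_constant
        for lid in LINE_IDS:
            p = line_profile(conc, mesh, lid)
            assert np.allclose(p.concentration, 0.3)

    def test_linear_field_reproduced(self, conc_constant):
        mesh, conc0 = conc_constant
        L = mesh.s_faces[-1]
        phi = (mesh.s_c[:, None] / L) * np.ones(mesh.shape[1])[None, :]
        conc = ConcentrationField(mesh=mesh, phi=phi,
                                  props=TransportProperties(), converged=True)
        p = line_profile(conc, mesh, "A_outer")
        exact = p.s / L
        assert np.abs(p.concentration - exact).max() < 1e-6

    def test_lines_at_study_radii(self, conc_constant):
        # offsets of 0.25 mm from the interface sit at |n| = 1.25 / 1.75 mm
        mesh, conc = conc_constant
        pA = line_profile(conc, mesh, "A_inner")
        pB = line_profile(conc, mesh, "B_outer")
        assert pA.s.min() == pytest.approx(mesh.stent_span[0])
        assert pB.s.max() == pytest.approx(mesh.stent_span[1])

    def test_invalid_offset_rejected(self, conc_constant):
        mesh, conc = conc_constant
        with pytest.raises(ValueError):
            line_profile(conc, mesh, "B_outer", offset=0.002)
        with pytest.raises(ValueError):
            line_profile(conc, mesh, "C_outer")


class TestSegments:
    def make_profile(self, vals):
        s = np.linspace(0.0, 0.015, len(vals))
        return LineProfile(line_id="B_inner", s=s,
                           concentration=np.asarray(vals))

    def test_constant_profile_equal_means(self):
        st = segment_stats(self.make_profile([0.4] * 300))
        assert st.means["proximal"] == st.means["middle"] == st.means["distal"]

    def test_linear_profile_ordering_and_values(self):
        n = 301
        st = segment_stats(self.make_profile(np.linspace(0, 1, n)))
        # closed-form thirds of a linear ramp: means 1/6, 1/2, 5/6
        assert st.means["proximal"] == pytest.approx(1 / 6, abs=0.01)
        assert st.means["middle"] == pytest.approx(1 / 2, abs=0.01)
        assert st.means["distal"] == pytest.approx(5 / 6, abs=0.01)
        assert st.peaks["distal"] == pytest.approx(1.0)

    def test_peak_at_least_mean(self):
        rng = np.random.default_rng(7)
        st = segment_stats(self.make_profile(rng.random(90)))
        for seg in st.means:
            assert st.peaks[seg] >= st.means[seg]

    def test_short_profile_rejected(self):
        p = self.make_profile([0.1] * 50)
        with pytest.raises(ValueError):
            segment_stats(p, stent_span=(0.0, 0.020))


class TestRatios:
    def make_set(self, scale_inner=1.0):
        s = np.linspace(0, 0.015, 100)
        base = 0.2 + 0.1 * np.sin(s / 0.015 * np.pi)
        out = {}
        for lid in LINE_IDS:
            c = base * (scale_inner if lid.endswith("inner") else 1.0)
            out[lid] = LineProfile(line_id=lid, s=s, concentration=c)
        return out

    def test_identical_profiles_give_unit_ratios(self):
        rep = concentration_ratios(self.make_set())
        assert rep.peak_ratio_A == pytest.approx(1.0)
        assert rep.mean_ratio_B == pytest.approx(1.0)

    def test_doubled_inner_doubles_ratios(self):
        rep = concentration_ratios(self.make_set(scale_inner=2.0))
        assert rep.peak_ratio_A == pytest.approx(2.0)
        assert rep.mean_ratio_A == pytest.approx(2.0)

    def test_reference_drop(self):
        rep = concentration_ratios(self.make_set(),
                                   reference=self.make_set())
        assert rep.b_mean_drop == pytest.approx(0.0)

    def test_missing_profile_rejected(self):
        s = self.make_set()
        del s["B_outer"]
        with pytest.raises(ValueError):
            concentration_ratios(s)
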