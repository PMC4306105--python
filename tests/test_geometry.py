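"""Geometry and meshing: invariants, fixtures, error handling."""

import numpy as np
import pytest

from stentflow import (
    LUMEN,
    STRUT,
    WALL,
    GeometryError,
    StentGeometry,
    build_geometry,
    make_fixture,
)


class TestStentGeometry:
    def test_defaults_match_study_setup(self):
        g = StentGeometry()
        assert g.lumen_diameter == pytest.approx(0.003)
        assert g.bend_radius == pytest.approx(0.010)
        assert g.n_struts == 6
        assert g.strut_size == pytest.approx(1e-4)
        assert g.extension_length == pytest.approx(0.030)

    @pytest.mark.parametrize("bad", [
        dict(lumen_diameter=-1e-3),
        dict(bend_radius=1e-3),            # smaller than lumen radius
        dict(bend_angle=270.0),
        dict(wall_thickness=0.0),
        dict(strut_size=0.002),            # >= d/2
        dict(n_struts=200),                # struts do not fit
    ])
    def test_invariant_violations_raise(self, bad):
        with pytest.raises(GeometryError):
            StentGeometry(**bad)


class TestBuildGeometry:
    def test_default_mesh_strut_cells(self):
        # direct rectangle-containment enumeration: 2 sides x 6 struts x 2x2
        geo = StentGeometry()
        mesh = build_geometry(geo, resolution=20)
        assert int((mesh.region == STRUT).sum()) == 48
        # independent containment check
        count = 0
        for (slo, shi, nlo, nhi) in mesh.strut_rects:
            sin = (mesh.s_c >= slo) & (mesh.s_c < shi)
            nin = (mesh.n_c >= nlo) & (mesh.n_c < nhi)
            count += int(sin.sum() * nin.sum())
        assert count == 48

    def test_struts_contact_interface(self):
        mesh = build_geometry(StentGeometry(), resolution=20)
        d = mesh.geometry.lumen_diameter
        for (_, _, nlo, nhi) in mesh.strut_rects:
            assert nhi == pytest.approx(d / 2) or nlo == pytest.approx(-d / 2)

    def test_no_struts_means_no_strut_cells(self):
        mesh = build_geometry(StentGeometry(n_struts=0), resolution=10)
        assert int((mesh.region == STRUT).sum()) == 0

    def test_straight_limit_has_unit_metric(self):
        mesh = build_geometry(StentGeometry(bend_angle=0, n_struts=0),
                              resolution=5)
        assert np.allclose(mesh.h_c, 1.0)
        assert np.allclose(mesh.kappa, 0.0)

    def test_area_conservation(self):
        for kwargs, res in [({}, 20),
                            (dict(bend_angle=45.0, stent_length=0.006,
                                  n_struts=3), 12),
                            (dict(bend_angle=0, n_struts=0), 5)]:
            mesh = build_geometry(StentGeometry(**kwargs), resolution=res)
            rel = abs(mesh.total_area() - mesh.analytic_area()) / mesh.analytic_area()
            assert rel < 1e-10

    def test_region_flags_partition(self):
        mesh = build_geometry(StentGeometry(), resolution=20)
        assert set(np.unique(mesh.region)) <= {LUMEN, WALL, STRUT}

    def test_refinement_stability_of_strut_fraction(self):
        def frac(res):
            mesh = build_geometry(StentGeometry(), resolution=res)
            vol = mesh.cell_volumes()
            return vol[mesh.region == STRUT].sum() / vol.sum()
        f20, f40 = frac(20), frac(40)
        assert abs(f40 - f20) / f20 < 0.02

    def test_deterministic_flags(self):
        m1 = build_geometry(StentGeometry(), resolution=20)
        m2 = build_geometry(StentGeometry(), resolution=20)
        assert np.array_equal(m1.region, m2.region)
        assert np.array_equal(m1.s_faces, m2.s_faces)

    def test_coarse_resolution_error_names_minimum(self):
        with pytest.raises(GeometryError, match="10"):
            build_geometry(StentGeometry(), resolution=5)


class TestFixtures:
    def test_study_default(self):
        geo, mesh = make_fixture("study_default")
        assert geo.lumen_diameter == pytest.approx(0.003)
        assert geo.bend_radius == pytest.approx(0.010)
        assert geo.n_struts == 6

    def test_straight_channel(self):
        geo, mesh = make_fixture("straight_channel", resolution=5)
        assert geo.bend_angle == 0
        assert geo.n_struts == 0

    def test_slab_single_column(self):
        geo, mesh = make_fixture("slab_1d")
        assert mesh.shape[0] == 1
        assert mesh.n_wall_inner == 0 and mesh.n_wall_outer >= 8
        assert not mesh.lumen_side_walled

    def test_unknown_fixture_lists_valid_names(self):
        with pytest.raises(GeometryError, match="straight_channel"):
            make_fixture("bogus")
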