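"""Stented curved-vessel geometry and structured curvilinear meshing.

The physical model is a planar (bend-plane) reduction of a stented curved
artery: a channel of width ``d`` (the lumen) flanked by two tissue layers of
thickness ``wall_thickness``, following a centreline made of a straight inlet
extension, a circular arc of radius ``bend_radius`` spanning ``bend_angle``
degrees, and a straight outlet extension.  Square stent struts sit on both
lumen-wall interfaces along the stented arc and protrude into the lumen.

Coordinates are curvilinear: the streamwise station ``s`` is arc length along
the centreline from the inlet, the transverse station ``n`` is the signed
offset from the centreline (positive toward the outer bend).  Inside the arc
the local radius is ``r = R + n`` and the metric factor is ``h = 1 + n/R``;
in the extensions ``h = 1``.

This module doubles as the synthetic-fixture generator for oracle tests:
besides the full stented geometry it emits a straight channel (Poiseuille
oracle), a strut-free bend (curved-channel oracle) and a one-column two-layer
slab (diffusion oracle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LUMEN",
    "WALL",
    "STRUT",
    "StentGeometry",
    "Mesh",
    "GeometryError",
    "build_geometry",
    "make_fixture",
    "FIXTURE_NAMES",
]

LUMEN: int = 0
WALL: int = 1
STRUT: int = 2


class GeometryError(ValueError):
    """Invalid geometry parameters or meshing request."""


@dataclass(frozen=True)
class StentGeometry:
    """Parameterized description of the stented curved vessel (SI units).

    Defaults are the study conditions: a 3 mm lumen bent 90 degrees at a
    10 mm centreline radius, 0.5 mm tissue layers, six 0.10 x 0.10 mm struts
    over a 15 mm stented arc, and 30 mm straight extensions at both ends.
    """

    lumen_diameter: float = 0.003
    bend_radius: float = 0.010
    bend_angle: float = 90.0
    wall_thickness: float = 0.0005
    stent_length: float = 0.015
    n_struts: int = 6
    strut_size: float = 0.0001
    extension_length: float = 0.030

    def __post_init__(self) -> None:
        d, R = self.lumen_diameter, self.bend_radius
        if d <= 0:
            raise GeometryError("lumen_diameter must be positive")
        if self.bend_angle < 0 or self.bend_angle > 180:
            raise GeometryError("bend_angle must lie in [0, 180] degrees")
        if self.bend_angle > 0 and R <= d / 2:
            raise GeometryError("bend_radius must exceed the lumen radius")
        if self.wall_thickness <= 0:
            raise GeometryError("wall_thickness must be positive")
        if self.n_struts < 0:
            raise GeometryError("n_struts must be non-negative")
        if self.n_struts > 0:
            if not 0 < self.strut_size < d / 2:
                raise GeometryError("strut_size must lie in (0, lumen_diameter/2)")
            if self.n_struts * self.strut_size > self.stent_length:
                raise GeometryError("struts do not fit in the stented length")
        if self.extension_length < 0:
            raise GeometryError("extension_length must be non-negative")

    @property
    def arc_length(self) -> float:
        """Centreline length of the curved segment (0 for a straight channel)."""
        return self.bend_radius * math.radians(self.bend_angle)


@dataclass
class Mesh:
    """Structured curvilinear grid with per-cell region flags.

    Cells are indexed ``(i, j)`` with ``i`` streamwise and ``j`` transverse
    (``j`` increasing toward the outer bend).  Region flags are LUMEN, WALL
    or STRUT; struts are blocked rectangles contacting the lumen-wall
    interface.  ``lumen_side_walled`` is False only for the one-sided slab
    fixture, whose inner transverse boundary is an open (lumen-side) face.
    """

    geometry: StentGeometry
    s_faces: np.ndarray          # (Ns+1,) streamwise face stations [m]
    n_faces: np.ndarray          # (Nn+1,) transverse face stations [m]
    kappa: np.ndarray            # (Ns,) centreline curvature per streamwise cell [1/m]
    region: np.ndarray           # (Ns, Nn) int8 flags
    n_wall_inner: int            # wall rows on the inner-bend side
    n_wall_outer: int            # wall rows on the outer-bend side
    stent_span: tuple[float, float]   # (s0, s1) of the stented arc
    bend_span: tuple[float, float]    # (s0, s1) of the curved segment
    strut_rects: list[tuple[float, float, float, float]] = field(default_factory=list)
    lumen_side_walled: bool = True

    # ---- derived metric quantities -------------------------------------
    def __post_init__(self) -> None:
        self.s_faces = np.asarray(self.s_faces, dtype=float)
        self.n_faces = np.asarray(self.n_faces, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.ds = np.diff(self.s_faces)                    # (Ns,)
        self.dn = np.diff(self.n_faces)                    # (Nn,)
        self.s_c = 0.5 * (self.s_faces[1:] + self.s_faces[:-1])
        self.n_c = 0.5 * (self.n_faces[1:] + self.n_faces[:-1])
        # metric factor h = 1 + kappa*n at centres and at transverse faces
        self.h_c = 1.0 + self.kappa[:, None] * self.n_c[None, :]       # (Ns, Nn)
        self.h_nf = 1.0 + self.kappa[:, None] * self.n_faces[None, :]  # (Ns, Nn+1)
        # curvature at streamwise faces (length-weighted between cells)
        kf = np.empty(self.s_faces.shape)
        kf[1:-1] = (self.kappa[:-1] * self.ds[:-1] + self.kappa[1:] * self.ds[1:]) / (
            self.ds[:-1] + self.ds[1:]
        )
        kf[0] = self.kappa[0]
        kf[-1] = self.kappa[-1]
        self.kappa_sf = kf

    @property
    def shape(self) -> tuple[int, int]:
        return self.region.shape

    @property
    def n_lumen(self) -> int:
        return self.shape[1] - self.n_wall_inner - self.n_wall_outer

    @property
    def j_lumen(self) -> slice:
        """Transverse row slice covering the lumen (struts included)."""
        return slice(self.n_wall_inner, self.shape[1] - self.n_wall_outer)

    @property
    def fluid(self) -> np.ndarray:
        """Boolean mask of cells carrying flow (lumen, struts excluded)."""
        return self.region == LUMEN

    def cell_volumes(self) -> np.ndarray:
        """Cell areas per unit depth, h * ds * dn."""
        return self.h_c * self.ds[:, None] * self.dn[None, :]

    def total_area(self) -> float:
        return float(self.cell_volumes().sum())

    def analytic_area(self) -> float:
        """Exact area of the meshed domain (centreline length x width)."""
        width = self.n_faces[-1] - self.n_faces[0]
        length = self.s_faces[-1] - self.s_faces[0]
        # the annular sector contributes R*angle*width only when the
        # transverse span is symmetric about the centreline; otherwise the
        # first-moment term enters through the metric factor.
        n_mid = 0.5 * (self.n_faces[-1] + self.n_faces[0])
        bend_len = self.bend_span[1] - self.bend_span[0]
        g = self.geometry
        kap = 0.0 if g.bend_angle == 0 else 1.0 / g.bend_radius
        return length * width + kap * n_mid * width * bend_len

    def stent_columns(self) -> np.ndarray:
        """Boolean mask over streamwise cells lying within the stented arc."""
        s0, s1 = self.stent_span
        return (self.s_c >= s0) & (self.s_c <= s1)

    def node_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) coordinates of mesh nodes, for export/plotting.

        The inlet extension runs along +x; the bend turns toward +y.
        """
        g = self.geometry
        sb0, sb1 = self.bend_span
        R = g.bend_radius
        x = np.empty((self.s_faces.size, self.n_faces.size))
        y = np.empty_like(x)
        for a, s in enumerate(self.s_faces):
            if g.bend_angle == 0 or s <= sb0:
                cx, cy = s, 0.0
                tx, ty = 1.0, 0.0
            elif s <= sb1 + 1e-15:
                th = (s - sb0) / R
                cx = sb0 + R * math.sin(th)
                cy = R * (1.0 - math.cos(th))
                tx, ty = math.cos(th), math.sin(th)
            else:
                th = math.radians(g.bend_angle)
                bx = sb0 + R * math.sin(th)
                by = R * (1.0 - math.cos(th))
                tx, ty = math.cos(th), math.sin(th)
                cx = bx + (s - sb1) * tx
                cy = by + (s - sb1) * ty
            # outward normal in the bend points away from the centre of
            # curvature located at (sb0, R): normal = (sin th, -cos th)... the
            # centre is at +y, so +n (outer bend) points toward -normal side.
            nx, ny = ty, -tx
            x[a] = cx + self.n_faces * nx
            y[a] = cy + self.n_faces * ny
        return x, y


def _graded_spacings(total: float, fine: float, growth: float = 1.2,
                     cap_ratio: float = 20.0) -> np.ndarray:
    """Spacings for one extension, fine end last, stretched to fit exactly."""
    if total <= 0:
        return np.zeros(0)
    cap = cap_ratio * fine
    steps = [fine]
    acc = fine
    while acc < total:
        nxt = min(steps[-1] * growth, cap)
        steps.append(nxt)
        acc += nxt
    arr = np.array(steps)
    arr *= total / arr.sum()
    return arr[::-1]  # coarse at the far end -> reverse so fine end is last


def build_geometry(params: StentGeometry, resolution: float = 20.0) -> Mesh:
    """Mesh the stented curved channel at ``resolution`` cells per mm.

    The lumen is meshed uniformly at ``resolution`` cells/mm transversely and
    along the curved (stented) segment; the straight extensions are graded
    coarser away from the bend.  Each wall layer gets at least 8 transverse
    cells.  Struts become blocked 2D rectangles flagged STRUT.
    """
    g = params
    delta = 1e-3 / resolution
    if g.n_struts > 0:
        min_res = max(10.0, 1e-3 / g.strut_size)
        if resolution < min_res:
            raise GeometryError(
                f"resolution {resolution:g} cells/mm cannot resolve a "
                f"{g.strut_size * 1e3:g} mm strut; need >= {min_res:g} cells/mm"
            )
    elif resolution < 2:
        raise GeometryError("resolution must be at least 2 cells/mm")

    # transverse faces: inner wall | lumen | outer wall
    d, t = g.lumen_diameter, g.wall_thickness
    n_lum = max(4, round(d / delta))
    n_wal = max(8, math.ceil(t / delta))
    inner = np.linspace(-d / 2 - t, -d / 2, n_wal + 1)
    lum = np.linspace(-d / 2, d / 2, n_lum + 1)
    outer = np.linspace(d / 2, d / 2 + t, n_wal + 1)
    n_faces = np.concatenate([inner[:-1], lum, outer[1:]])

    # streamwise faces: extension | mid (bend or straight test section) | extension
    arc = g.arc_length
    mid_len = arc if g.bend_angle > 0 else max(g.stent_length, g.lumen_diameter)
    n_mid = max(2, round(mid_len / delta))
    E = g.extension_length
    ext = _graded_spacings(E, delta)
    mid = np.full(n_mid, mid_len / n_mid)
    spac = np.concatenate([ext, mid, ext[::-1]])
    s_faces = np.concatenate([[0.0], np.cumsum(spac)])
    s_faces[-1] = 2 * E + mid_len  # kill accumulation round-off

    sb0, sb1 = E, E + mid_len
    Ns, Nn = s_faces.size - 1, n_faces.size - 1
    kappa = np.zeros(Ns)
    if g.bend_angle > 0:
        s_c = 0.5 * (s_faces[1:] + s_faces[:-1])
        kappa[(s_c > sb0) & (s_c < sb1)] = 1.0 / g.bend_radius

    region = np.full((Ns, Nn), LUMEN, dtype=np.int8)
    region[:, :n_wal] = WALL
    region[:, n_wal + n_lum:] = WALL

    # struts: equally spaced over the stented arc centred on the mid segment
    if g.stent_length > mid_len + 1e-12:
        raise GeometryError("stented length exceeds the curved segment")
    st0 = sb0 + (mid_len - g.stent_length) / 2
    st1 = st0 + g.stent_length
    rects: list[tuple[float, float, float, float]] = []
    w = g.strut_size
    for k in range(g.n_struts):
        sc = st0 + (k + 0.5) * g.stent_length / max(g.n_struts, 1)
        rects.append((sc - w / 2, sc + w / 2, d / 2 - w, d / 2))        # outer side
        rects.append((sc - w / 2, sc + w / 2, -d / 2, -d / 2 + w))      # inner side
    s_c = 0.5 * (s_faces[1:] + s_faces[:-1])
    n_c = 0.5 * (n_faces[1:] + n_faces[:-1])
    for (slo, shi, nlo, nhi) in rects:
        ii = np.where((s_c >= slo) & (s_c < shi))[0]
        jj = np.where((n_c >= nlo) & (n_c < nhi))[0]
        region[np.ix_(ii, jj)] = STRUT

    return Mesh(
        geometry=g,
        s_faces=s_faces,
        n_faces=n_faces,
        kappa=kappa,
        region=region,
        n_wall_inner=n_wal,
        n_wall_outer=n_wal,
        stent_span=(st0, st1),
        bend_span=(sb0, sb1),
        strut_rects=rects,
    )


def _build_slab(resolution: float, with_strut: bool) -> tuple[StentGeometry, Mesh]:
    """One-column mesh spanning the lumen plus one wall layer.

    The inner transverse boundary (n = -d/2) is an open lumen-side face; the
    optional strut is a Dirichlet drug-source layer at the lumen-wall
    interface spanning the whole column.
    """
    g = StentGeometry(bend_angle=0.0, n_struts=1 if with_strut else 0,
                      stent_length=0.001, extension_length=0.0)
    d, t, w = g.lumen_diameter, g.wall_thickness, g.strut_size
    delta = 1e-3 / resolution
    n_lum = max(4, round(d / delta))
    n_wal = max(8, math.ceil(t / delta))
    n_faces = np.concatenate([
        np.linspace(-d / 2, d / 2, n_lum + 1),
        np.linspace(d / 2, d / 2 + t, n_wal + 1)[1:],
    ])
    s_faces = np.array([0.0, g.stent_length])
    region = np.full((1, n_faces.size - 1), LUMEN, dtype=np.int8)
    region[:, n_lum:] = WALL
    rects = []
    if with_strut:
        rects.append((0.0, g.stent_length, d / 2 - w, d / 2))
        n_c = 0.5 * (n_faces[1:] + n_faces[:-1])
        region[0, (n_c >= d / 2 - w) & (n_c < d / 2)] = STRUT
    mesh = Mesh(
        geometry=g,
        s_faces=s_faces,
        n_faces=n_faces,
        kappa=np.zeros(1),
        region=region,
        n_wall_inner=0,
        n_wall_outer=n_wal,
        stent_span=(0.0, g.stent_length),
        bend_span=(0.0, 0.0),
        strut_rects=rects,
        lumen_side_walled=False,
    )
    return g, mesh


FIXTURE_NAMES = ("straight_channel", "bare_bend", "slab_1d", "study_default")


def make_fixture(name: str, resolution: float | None = None,
                 **overrides) -> tuple[StentGeometry, Mesh]:
    """Canonical test geometries.

    - ``straight_channel``: strut-free straight channel (plane-Poiseuille oracle)
    - ``bare_bend``: strut-free 90-degree bend (curved-channel ODE oracle)
    - ``slab_1d``: one-column lumen + single wall layer (two-layer diffusion
      oracle); pass ``n_struts=0`` to drop the interface drug-source layer
    - ``study_default``: the full stented default geometry

    ``overrides`` replace StentGeometry fields before meshing.
    """
    if name not in FIXTURE_NAMES:
        raise GeometryError(
            f"unknown fixture {name!r}; valid fixtures: {', '.join(FIXTURE_NAMES)}"
        )
    if name == "slab_1d":
        res = resolution if resolution is not None else 20.0
        with_strut = overrides.pop("n_struts", 1) > 0
        if overrides:
            raise GeometryError("slab_1d accepts only the n_struts override")
        return _build_slab(res, with_strut)

    base: dict = {}
    if name == "straight_channel":
        base = dict(bend_angle=0.0, n_struts=0)
    elif name == "bare_bend":
        base = dict(n_struts=0)
    base.update(overrides)
    geo = StentGeometry(**base)
    res = resolution if resolution is not None else 20.0
    return geo, build_geometry(geo, resolution=res)
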