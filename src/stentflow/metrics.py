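"""Derived hemodynamic and drug-transport metrics.

Wall shear stress is evaluated on the wetted lumen boundary (lumen-wall
interface and strut faces) by a one-sided second-order gradient of the
tangential velocity, exact for a parabolic near-wall profile.  The low-WSS
fraction uses the conventional 0.5 Pa threshold associated with in-stent
restenosis risk.  Drug-concentration "line" profiles mirror the reference
lines used for stented-vessel models: Line A runs 0.25 mm inside the lumen
and Line B 0.25 mm inside the wall, along the stented extent on each bend
side; segment statistics split the stented arc into proximal / middle /
distal thirds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .drug_transport import ConcentrationField
from .flow_solver import FlowField, FluidProperties
from .geometry import STRUT, Mesh

__all__ = [
    "WSSProfile",
    "LowWSSFraction",
    "LineProfile",
    "SegmentStats",
    "RatioReport",
    "compute_wss",
    "low_wss_fraction",
    "line_profile",
    "segment_stats",
    "concentration_ratios",
]

LINE_IDS = ("A_inner", "A_outer", "B_inner", "B_outer")
SEGMENTS = ("proximal", "middle", "distal")


@dataclass
class WSSProfile:
    """Wall-shear-stress samples on the wetted boundary, per bend side."""

    s: np.ndarray            # (N,) streamwise station of each face [m]
    side: np.ndarray         # (N,) 'inner_bend' | 'outer_bend'
    wss: np.ndarray          # (N,) WSS magnitude [Pa]
    length: np.ndarray       # (N,) wetted face length [m]
    stent_span: tuple[float, float]

    def __post_init__(self) -> None:
        if np.any(self.wss < 0):
            raise ValueError("WSS magnitudes must be non-negative")

    def restrict(self, span: tuple[float, float]) -> "WSSProfile":
        m = (self.s >= span[0]) & (self.s <= span[1])
        return WSSProfile(self.s[m], self.side[m], self.wss[m],
                          self.length[m], self.stent_span)

    def to_table(self) -> dict:
        return {"s": self.s, "side": self.side, "wss": self.wss,
                "length": self.length}


@dataclass(frozen=True)
class LowWSSFraction:
    """Arc-length fraction below the WSS threshold, total and per side."""

    total: float
    inner: float
    outer: float
    threshold: float


@dataclass
class LineProfile:
    """Concentration sampled along one reference line."""

    line_id: str
    s: np.ndarray
    concentration: np.ndarray

    def __post_init__(self) -> None:
        if self.line_id not in LINE_IDS:
            raise ValueError(f"line_id must be one of {LINE_IDS}")
        c = self.concentration
        if np.any(c < -1e-9) or np.any(c > 1 + 1e-9):
            raise ValueError("concentrations must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.concentration))

    @property
    def peak(self) -> float:
        return float(np.max(self.concentration))


@dataclass
class SegmentStats:
    """Mean and peak concentration per proximal/middle/distal segment."""

    line_id: str
    means: dict[str, float]
    peaks: dict[str, float]


@dataclass
class RatioReport:
    """Inner/outer-bend concentration ratios (and optional Re-to-Re drop)."""

    peak_ratio_A: float
    mean_ratio_A: float
    peak_ratio_B: float
    mean_ratio_B: float
    b_mean_drop: float | None = None    # fractional drop of the pooled
                                        # Line-B mean vs the reference set


def _one_sided_gradient(v1: float, v2: float, d1: float, d2: float) -> float:
    """Gradient at a no-slip face from two interior samples.

    Quadratic fit through (0, 0), (d1, v1), (d2, v2); reduces to
    (9 v1 - v2) / (3 dn) for samples at dn/2 and 3 dn/2.
    """
    return (v1 * d2**2 - v2 * d1**2) / (d1 * d2 * (d2 - d1))


def compute_wss(flow: FlowField, mesh: Mesh,
                fluid: FluidProperties | None = None) -> WSSProfile:
    """WSS magnitude on every wetted face of both bend sides.

    Covers the lumen-wall interface, strut tops (faces protruding into the
    lumen) and strut side faces.  Station is the face-centre streamwise
    coordinate; face lengths include the metric factor so they integrate to
    the wetted arc length.
    """
    if not flow.converged:
        raise ValueError("flow field is not converged")
    mu = (fluid or flow.fluid_props).mu
    m = mesh
    Ns, Nn = m.shape
    reg = m.region
    u_cell = flow.u_cell
    v_cell = flow.v_cell
    jl = m.j_lumen
    j_lo, j_hi = jl.start, jl.stop - 1          # lumen row range (incl.)

    s_l, side_l, wss_l, len_l = [], [], [], []

    for side, step, j_edge in (("inner_bend", +1, j_lo), ("outer_bend", -1, j_hi)):
        if (side == "inner_bend" and m.n_wall_inner == 0):
            continue
        for i in range(Ns):
            # wetted transverse face of column i on this side
            j = j_edge
            while 0 <= j <= Nn - 1 and reg[i, j] == STRUT:
                j += step
            # face between the last strut/wall entity and the first fluid cell
            jf = j if step == 1 else j + 1       # n-face index
            j1 = j                                # first fluid cell
            j2 = j + step
            if not (0 <= j2 <= Nn - 1) or reg[i, j1] != 0 or reg[i, j2] != 0:
                continue
            nf = m.n_faces[jf]
            d1 = abs(m.n_c[j1] - nf)
            d2 = abs(m.n_c[j2] - nf)
            g = _one_sided_gradient(u_cell[i, j1], u_cell[i, j2], d1, d2)
            h_face = 1.0 + m.kappa[i] * nf
            s_l.append(m.s_c[i])
            side_l.append(side)
            wss_l.append(abs(mu * g))
            len_l.append(h_face * m.ds[i])

        # strut side faces (tangential velocity v, normal s)
        for (slo, shi, nlo, nhi) in m.strut_rects:
            on_side = (nhi <= 0) if side == "inner_bend" else (nlo >= 0)
            if not on_side:
                continue
            rows = np.where((m.n_c > nlo) & (m.n_c < nhi))[0]
            for s_face, direction in ((slo, -1), (shi, +1)):
                # nearest fluid columns on the fluid side of the face
                if direction < 0:
                    cols = np.where(m.s_c < s_face)[0]
                    cols = cols[-2:][::-1]
                else:
                    cols = np.where(m.s_c > s_face)[0][:2]
                if cols.size < 2:
                    continue
                i1, i2 = int(cols[0]), int(cols[1])
                for j in rows:
                    if reg[i1, j] != 0 or reg[i2, j] != 0:
                        continue
                    h_loc = m.h_c[i1, j]
                    d1 = abs(m.s_c[i1] - s_face) * h_loc
                    d2 = abs(m.s_c[i2] - s_face) * h_loc
                    g = _one_sided_gradient(v_cell[i1, j], v_cell[i2, j], d1, d2)
                    s_l.append(s_face)
                    side_l.append(side)
                    wss_l.append(abs(mu * g))
                    len_l.append(m.dn[j])

    s_arr = np.asarray(s_l)
    order = np.argsort(s_arr, kind="stable")
    return WSSProfile(
        s=s_arr[order],
        side=np.asarray(side_l, dtype=object)[order],
        wss=np.asarray(wss_l)[order],
        length=np.asarray(len_l)[order],
        stent_span=m.stent_span,
    )


def low_wss_fraction(wss: WSSProfile, threshold: float = 0.5,
                     restrict_to_stent: bool = True) -> LowWSSFraction:
    """Fraction of wetted arc length with WSS below ``threshold`` [Pa].

    By default only the stented segment enters the numerator and the
    denominator (strut faces included); set ``restrict_to_stent=False`` to
    rate the whole wall including the straight extensions.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    prof = wss.restrict(wss.stent_span) if restrict_to_stent else wss
    if prof.s.size == 0:
        raise ValueError("empty WSS profile")
    out = {}
    low = prof.wss < threshold
    for side in ("inner_bend", "outer_bend"):
        msk = prof.side == side
        tot = prof.length[msk].sum()
        out[side] = float(prof.length[msk & low].sum() / tot) if tot > 0 else 0.0
    total = float(prof.length[low].sum() / prof.length.sum())
    return LowWSSFraction(total=total, inner=out["inner_bend"],
                          outer=out["outer_bend"], threshold=threshold)


def line_profile(conc: ConcentrationField, mesh: Mesh, line_id: str,
                 offset: float = 0.25e-3, n_samples: int = 400) -> LineProfile:
    """Sample the concentration along a reference line.

    Lines run at constant transverse offset from the lumen-wall interface
    (``A``: into the lumen, ``B``: into the wall), spanning the stented
    extent, bilinearly interpolated at uniform streamwise spacing.
    """
    if line_id not in LINE_IDS:
        raise ValueError(f"line_id must be one of {LINE_IDS}")
    if not conc.converged:
        raise ValueError("concentration field is not converged")
    m = mesh
    g = m.geometry
    half = g.lumen_diameter / 2
    n_off = half - offset if line_id.startswith("A") else half + offset
    if line_id.startswith("A") and not 0 < n_off < half:
        raise ValueError("Line A offset places the line outside the lumen")
    if line_id.startswith("B") and not half < n_off < half + g.wall_thickness:
        raise ValueError("Line B offset places the line outside the wall")
    if line_id.endswith("inner"):
        n_off = -n_off
        if m.n_wall_inner == 0 and line_id.startswith("B"):
            raise ValueError("mesh has no inner wall layer")
    interp = RegularGridInterpolator((m.s_c, m.n_c), conc.phi,
                                     bounds_error=True)
    s0, s1 = m.stent_span
    s = np.linspace(s0, s1, n_samples + 1)
    pts = np.column_stack([s, np.full(s.shape, n_off)])
    vals = interp(pts)
    return LineProfile(line_id=line_id, s=s,
                       concentration=np.clip(vals, 0.0, 1.0))


def segment_stats(profile: LineProfile,
                  stent_span: tuple[float, float] | None = None) -> SegmentStats:
    """Mean and peak concentration in equal proximal/middle/distal thirds."""
    s = profile.s
    span = stent_span if stent_span is not None else (float(s[0]), float(s[-1]))
    if s[0] > span[0] + 1e-12 or s[-1] < span[1] - 1e-12:
        raise ValueError("profile does not span the stented extent")
    edges = np.linspace(span[0], span[1], 4)
    means, peaks = {}, {}
    for name, lo, hi in zip(SEGMENTS, edges[:-1], edges[1:]):
        msk = (s >= lo - 1e-15) & (s <= hi + 1e-15)
        seg = profile.concentration[msk]
        means[name] = float(seg.mean())
        peaks[name] = float(seg.max())
    return SegmentStats(line_id=profile.line_id, means=means, peaks=peaks)


def concentration_ratios(profiles: dict[str, LineProfile],
                         reference: dict[str, LineProfile] | None = None,
                         ) -> RatioReport:
    """Inner/outer peak and mean ratios for Lines A and B.

    ``profiles`` maps line ids to profiles at one Reynolds number.  With a
    ``reference`` set (another Reynolds number), also reports the fractional
    drop of the pooled (both-sides) Line-B mean relative to the reference.
    """
    for key in LINE_IDS:
        if key not in profiles:
            raise ValueError(f"missing profile {key!r}")
    for a, b in (("A_inner", "A_outer"), ("B_inner", "B_outer")):
        if profiles[a].s.shape != profiles[b].s.shape:
            raise ValueError("mismatched inner/outer profiles")

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else float("inf")

    def pooled_b_mean(p: dict[str, LineProfile]) -> float:
        return float(np.concatenate([p["B_inner"].concentration,
                                     p["B_outer"].concentration]).mean())

    drop = None
    if reference is not None:
        ref = pooled_b_mean(reference)
        drop = (ref - pooled_b_mean(profiles)) / ref if ref > 0 else float("nan")
    return RatioReport(
        peak_ratio_A=ratio(profiles["A_inner"].peak, profiles["A_outer"].peak),
        mean_ratio_A=ratio(profiles["A_inner"].mean, profiles["A_outer"].mean),
        peak_ratio_B=ratio(profiles["B_inner"].peak, profiles["B_outer"].peak),
        mean_ratio_B=ratio(profiles["B_inner"].mean, profiles["B_outer"].mean),
        b_mean_drop=drop,
    )
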