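"""Steady incompressible Newtonian flow in the stented curved channel.

Finite-volume discretization on the staggered (MAC) curvilinear grid built by
:mod:`stentflow.geometry`: streamwise velocity ``u`` lives on streamwise
faces, transverse velocity ``v`` on transverse faces, pressure at cell
centres.  The momentum equations are the polar-coordinate Navier-Stokes
equations written in the (s, n) frame with metric ``h = 1 + kappa*n``; in the
straight extensions they reduce exactly to the Cartesian equations.

Pressure-velocity coupling is SIMPLEC: segregated momentum solves with
implicit under-relaxation, followed by a pressure-correction solve whose
velocity corrections leave the face fluxes discretely divergence-free to
linear-solver precision.  Convection is first-order upwind implicit with a
deferred second-order upwind correction; convergence is judged on scaled
(first-iterations-normalized) L1 residuals, threshold 1e-4 by default.

Boundary conditions: parabolic inlet profile (mean velocity ``v_char``,
centreline 1.5x), zero-pressure outlet with extrapolated velocity, no-slip
on lumen walls and strut faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Mesh

__all__ = [
    "FluidProperties",
    "InletSpec",
    "SolverSettings",
    "FlowField",
    "SolverError",
    "NonConvergenceError",
    "reynolds_number",
    "velocity_for_reynolds",
    "solve_flow",
]


class SolverError(RuntimeError):
    """Solver-stage failure."""


class NonConvergenceError(SolverError):
    """Iteration budget exhausted before the residual threshold was met."""

    def __init__(self, message: str, history: list[dict]):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class FluidProperties:
    """Blood treated as a constant-property Newtonian fluid (SI units)."""

    rho: float = 1055.0      # density [kg/m^3]
    mu: float = 3.5e-3       # dynamic viscosity [kg/(m s)]

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.mu <= 0:
            raise ValueError("rho and mu must be positive")

    @property
    def nu(self) -> float:
        return self.mu / self.rho


@dataclass(frozen=True)
class InletSpec:
    """Parabolic inlet: mean velocity ``v_char``, no-slip at the lumen walls."""

    v_char: float                 # characteristic (mean) inlet velocity [m/s]
    lumen_half_width: float = 0.0015
    profile: str = "parabolic"

    def __post_init__(self) -> None:
        if self.v_char <= 0:
            raise ValueError("v_char must be positive")
        if self.profile != "parabolic":
            raise ValueError("only the parabolic inlet profile is supported")
        if self.lumen_half_width <= 0:
            raise ValueError("lumen_half_width must be positive")

    def velocity(self, n: np.ndarray) -> np.ndarray:
        """Streamwise velocity at transverse stations ``n`` (2D channel).

        The profile integrates to mean ``v_char``; the centreline value is
        1.5 * v_char.
        """
        a = self.lumen_half_width
        prof = 1.5 * self.v_char * (1.0 - (np.asarray(n) / a) ** 2)
        return np.clip(prof, 0.0, None)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls shared by the flow and scalar solves."""

    residual_tol: float = 1e-4
    max_outer_iterations: int = 2500
    alpha_u: float = 0.8           # momentum under-relaxation
    alpha_p: float = 0.7           # pressure under-relaxation
    convection_scheme: str = "second_order_upwind"
    linear_tol: float = 1e-10      # direct-solve residual check for scalars
    max_scalar_iterations: int = 400

    def __post_init__(self) -> None:
        if not (0 < self.alpha_u <= 1 and 0 < self.alpha_p <= 1):
            raise ValueError("relaxation factors must lie in (0, 1]")
        if self.residual_tol <= 0:
            raise ValueError("residual_tol must be positive")
        if self.convection_scheme not in ("second_order_upwind", "first_order_upwind"):
            raise ValueError("unknown convection scheme")


@dataclass
class FlowField:
    """Converged staggered velocity/pressure field on a mesh."""

    mesh: Mesh
    u: np.ndarray          # (Ns+1, Nn) streamwise face velocities [m/s]
    v: np.ndarray          # (Ns, Nn+1) transverse face velocities [m/s]
    p: np.ndarray          # (Ns, Nn) pressure [Pa], zero reference at outlet
    fluid_props: FluidProperties
    inlet: InletSpec
    settings: SolverSettings
    history: list[dict] = field(default_factory=list)
    converged: bool = False

    @property
    def u_cell(self) -> np.ndarray:
        """Streamwise velocity interpolated to cell centres."""
        return 0.5 * (self.u[1:, :] + self.u[:-1, :])

    @property
    def v_cell(self) -> np.ndarray:
        return 0.5 * (self.v[:, 1:] + self.v[:, :-1])

    def face_fluxes(self) -> tuple[np.ndarray, np.ndarray]:
        """Volumetric fluxes through streamwise and transverse faces."""
        m = self.mesh
        Fs = self.u * m.dn[None, :]
        Fn = self.v * m.h_nf * m.ds[:, None]
        return Fs, Fn

    @property
    def inlet_flux(self) -> float:
        return float((self.u[0] * self.mesh.dn).sum())

    def continuity_error(self) -> float:
        """Max cell mass imbalance relative to the inlet flux."""
        Fs, Fn = self.face_fluxes()
        imb = Fs[1:] - Fs[:-1] + Fn[:, 1:] - Fn[:, :-1]
        return float(np.abs(imb[self.mesh.fluid]).max() / max(self.inlet_flux, 1e-300))


def reynolds_number(fluid: FluidProperties, v_char: float, d: float) -> float:
    """Re = rho * v * d / mu with d the lumen diameter."""
    if v_char < 0 or d <= 0:
        raise ValueError("v_char must be >= 0 and d > 0")
    return fluid.rho * v_char * d / fluid.mu


def velocity_for_reynolds(fluid: FluidProperties, Re: float, d: float) -> float:
    """Characteristic velocity giving Reynolds number ``Re``; inverse of
    :func:`reynolds_number`."""
    if Re <= 0 or d <= 0:
        raise ValueError("Re and d must be positive")
    return Re * fluid.mu / (fluid.rho * d)


# ----------------------------------------------------------------------
# deferred second-order-upwind correction
# ----------------------------------------------------------------------

def _sou_face(phiW, phiP, phiE, phiEE, xW, xP, xE, xEE, xf, F,
              validW, validEE, limit: bool) -> np.ndarray:
    """F * (phi_face_SOU - phi_face_upwind) for faces between P and E.

    Upstream-biased linear reconstruction with actual point spacings; falls
    back to first order (zero correction) where the second upstream point is
    unavailable.  With ``limit`` the slope is minmod-limited against the
    face slope, preserving boundedness for the scalar.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        face_slope = np.where(xE != xP, (phiE - phiP) / np.where(xE != xP, xE - xP, 1.0), 0.0)
        slope_p = np.where(validW, (phiP - phiW) / np.where(xP != xW, xP - xW, 1.0), 0.0)
        slope_m = np.where(validEE, (phiE - phiEE) / np.where(xE != xEE, xE - xEE, 1.0), 0.0)
    if limit:
        slope_p = np.where(slope_p * face_slope > 0,
                           np.sign(slope_p) * np.minimum(np.abs(slope_p), np.abs(face_slope)),
                           0.0)
        slope_m = np.where(slope_m * face_slope > 0,
                           np.sign(slope_m) * np.minimum(np.abs(slope_m), np.abs(face_slope)),
                           0.0)
    corr_p = slope_p * (xf - xP)        # used when F >= 0 (upwind = P)
    corr_m = slope_m * (xf - xE)        # used when F < 0  (upwind = E)
    return np.where(F >= 0, F * corr_p, F * corr_m)


# ----------------------------------------------------------------------
# solver internals
# ----------------------------------------------------------------------

class _Stag:
    """Precomputed geometric arrays and index maps for one mesh."""

    def __init__(self, mesh: Mesh, fluid: FluidProperties, inlet: InletSpec):
        m = mesh
        self.m = m
        self.rho, self.mu = fluid.rho, fluid.mu
        Ns, Nn = m.shape
        F = m.fluid
        self.F = F

        # --- u faces -------------------------------------------------
        wF = np.vstack([F[:1], F])            # (Ns+1, Nn): cell west of face
        eF = np.vstack([F, F[-1:]])           # cell east of face
        self.ufree = wF & eF                  # value defined (fluid-face)
        act = self.ufree.copy()
        act[0] = False
        act[-1] = False
        self.uact = act

        # --- v faces -------------------------------------------------
        sF = np.hstack([F[:, :1], F])         # (Ns, Nn+1): cell south of face
        nF = np.hstack([F, F[:, -1:]])
        vfree = sF & nF
        vfree[:, 0] = False
        vfree[:, -1] = False
        self.vfree = vfree
        self.vact = vfree                      # interior fluid-fluid faces only

        # --- pressure cells ------------------------------------------
        self.p_id = -np.ones((Ns, Nn), dtype=np.int64)
        self.p_id[F] = np.arange(F.sum())

        # --- geometry helpers ----------------------------------------
        ds, dn = m.ds, m.dn
        self.ds_u = np.empty(Ns + 1)
        self.ds_u[1:-1] = 0.5 * (ds[:-1] + ds[1:])
        self.ds_u[0] = ds[0]
        self.ds_u[-1] = ds[-1]
        self.h_u = 1.0 + m.kappa_sf[:, None] * m.n_c[None, :]          # (Ns+1, Nn)
        self.V_u = self.h_u * self.ds_u[:, None] * dn[None, :]
        self.h_v = m.h_nf                                              # (Ns, Nn+1)
        dn_v = np.empty(Nn + 1)
        dn_v[1:-1] = m.n_c[1:] - m.n_c[:-1]
        dn_v[0] = dn[0]
        dn_v[-1] = dn[-1]
        self.dn_v = dn_v
        self.V_v = self.h_v * m.ds[:, None] * dn_v[None, :]
        self.kap_v = np.repeat(m.kappa[:, None], Nn + 1, axis=1)

        # red-black colourings for the Gauss-Seidel momentum sweeps
        chk_u = (np.add.outer(np.arange(Ns + 1), np.arange(Nn)) % 2) == 0
        self.u_colors = (self.uact & chk_u, self.uact & ~chk_u)
        chk_v = (np.add.outer(np.arange(Ns), np.arange(Nn + 1)) % 2) == 0
        self.v_colors = (self.vact & chk_v, self.vact & ~chk_v)

        # inlet profile on u(0, :)
        prof = inlet.velocity(m.n_c)
        prof[~F[0]] = 0.0
        self.u_in = prof
        self.q_in = float((prof * dn).sum())


class _PoissonSolver:
    """Pressure-correction solver reusing a stale LU as preconditioner.

    The correction matrix drifts slowly between outer iterations, so a full
    factorization every iteration is wasteful: BiCGStab preconditioned with
    the last LU usually converges in a handful of steps, and the LU is
    refreshed when it stops being a good preconditioner.
    """

    def __init__(self, refresh_after: int = 12):
        self.lu = None
        self.refresh_after = refresh_after
        self._stale = True

    def solve(self, A, b: np.ndarray) -> np.ndarray:
        if self.lu is None or self._stale:
            self.lu = spla.splu(A.tocsc())
            self._stale = False
            return self.lu.solve(b)
        count = {"n": 0}

        def cb(_):
            count["n"] += 1

        M = spla.LinearOperator(A.shape, self.lu.solve)
        x, info = spla.bicgstab(A, b, M=M, rtol=1e-12, atol=0.0,
                                maxiter=self.refresh_after * 2, callback=cb)
        if info != 0:
            self.lu = spla.splu(A.tocsc())
            return self.lu.solve(b)
        if count["n"] > self.refresh_after:
            self._stale = True
        return x


def _csr(rows, cols, vals, n):
    return sp.csr_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n))


def solve_flow(mesh: Mesh, fluid: FluidProperties, inlet: InletSpec,
               settings: SolverSettings | None = None,
               initial: FlowField | None = None) -> FlowField:
    """SIMPLEC solve of the steady flow on ``mesh``.

    Raises :class:`ValueError` above Re = 2000 (the laminar steady-flow
    assumption) and :class:`NonConvergenceError` if the scaled residuals do
    not reach ``settings.residual_tol`` within the iteration budget.
    """
    settings = settings or SolverSettings()
    Re = reynolds_number(fluid, inlet.v_char, mesh.geometry.lumen_diameter)
    if Re > 2000:
        raise ValueError(
            f"Re = {Re:.0f} exceeds 2000; the steady laminar model does not apply"
        )

    g = _Stag(mesh, fluid, inlet)
    m = mesh
    Ns, Nn = m.shape
    rho, mu = fluid.rho, fluid.mu
    sou = settings.convection_scheme == "second_order_upwind"

    if initial is not None:
        u = initial.u.copy()
        v = initial.v.copy()
        p = initial.p.copy()
    else:
        u = np.zeros((Ns + 1, Nn))
        u[:, :] = g.u_in[None, :]
        u[~g.ufree] = 0.0
        v = np.zeros((Ns, Nn + 1))
        p = np.zeros((Ns, Nn))
    u[0] = g.u_in

    history: list[dict] = []
    norms = {"u": 0.0, "v": 0.0, "c": g.q_in}
    d_u = np.zeros((Ns + 1, Nn))
    d_v = np.zeros((Ns, Nn + 1))
    psolver = _PoissonSolver()

    for it in range(1, settings.max_outer_iterations + 1):
        Fs = u * m.dn[None, :]
        Fn = v * m.h_nf * m.ds[:, None]

        # ---------------- u momentum ---------------------------------
        aE = np.zeros((Ns + 1, Nn)); aW = np.zeros_like(aE)
        aN = np.zeros_like(aE); aS = np.zeros_like(aE)
        aP = np.zeros_like(aE); b = np.zeros_like(aE)
        act = g.uact
        ii, jj = np.where(act)
        iW, iE = ii - 1, ii + 1

        # CV mass fluxes (volumetric)
        Fe = 0.5 * (Fs[ii, jj] + Fs[iE, jj])
        Fw = 0.5 * (Fs[iW, jj] + Fs[ii, jj])
        FnN = 0.5 * (Fn[iW, jj + 1] + Fn[ii, jj + 1])
        FnS = 0.5 * (Fn[iW, jj] + Fn[ii, jj])

        De = mu * m.dn[jj] / (m.h_c[ii, jj] * m.ds[ii])
        Dw = mu * m.dn[jj] / (m.h_c[iW, jj] * m.ds[iW])
        A_nN = (1.0 + m.kappa_sf[ii] * m.n_faces[jj + 1]) * g.ds_u[ii]
        A_nS = (1.0 + m.kappa_sf[ii] * m.n_faces[jj]) * g.ds_u[ii]

        nN_ok = g.ufree[ii, np.minimum(jj + 1, Nn - 1)] & (jj + 1 <= Nn - 1)
        nS_ok = g.ufree[ii, np.maximum(jj - 1, 0)] & (jj - 1 >= 0)
        dnN = np.where(nN_ok, np.where(jj + 1 <= Nn - 1, m.n_c[np.minimum(jj + 1, Nn - 1)] - m.n_c[jj], m.dn[jj]), m.dn[jj])
        dnS = np.where(nS_ok, np.where(jj - 1 >= 0, m.n_c[jj] - m.n_c[np.maximum(jj - 1, 0)], m.dn[jj]), m.dn[jj])
        DnN = mu * A_nN / dnN
        DnS = mu * A_nS / dnS

        aEv = De + np.maximum(-Fe, 0.0) * rho
        aWv = Dw + np.maximum(Fw, 0.0) * rho
        aNv = np.where(nN_ok, DnN + np.maximum(-FnN, 0.0) * rho, 0.0)
        aSv = np.where(nS_ok, DnS + np.maximum(FnS, 0.0) * rho, 0.0)
        aPv = aEv + aWv + aNv + aSv + rho * (Fe - Fw + FnN - FnS)

        # wall shear at solid transverse neighbours: second-order one-sided
        # gradient (9 u_P - u_inner)/(3 dn), exact for a parabolic profile;
        # the second interior point enters the S/N link (correct sign).
        wallN = ~nN_ok
        wallS = ~nS_ok
        dnj = m.dn[jj]
        aPv = aPv + np.where(wallN & nS_ok, 3.0 * mu * A_nN / dnj, 0.0)
        aSv = aSv + np.where(wallN & nS_ok, mu * A_nN / (3.0 * dnj), 0.0)
        aPv = aPv + np.where(wallS & nN_ok, 3.0 * mu * A_nS / dnj, 0.0)
        aNv = aNv + np.where(wallS & nN_ok, mu * A_nS / (3.0 * dnj), 0.0)
        # walls on both sides (not expected at usual resolutions): fall back
        # to the first-order half-distance flux on each wall
        both = wallN & wallS
        aPv = aPv + np.where(both, 2.0 * mu * (A_nN + A_nS) / dnj, 0.0)

        # curvature sources
        kap_u = m.kappa_sf[ii]
        h_u = g.h_u[ii, jj]
        V_u = g.V_u[ii, jj]
        vbar = 0.25 * (v[iW, jj] + v[iW, jj + 1] + v[np.minimum(ii, Ns - 1), jj] + v[np.minimum(ii, Ns - 1), jj + 1])
        cor = rho * vbar * kap_u / h_u * V_u          # coefficient of -u term
        aPv = aPv + np.maximum(cor, 0.0)
        bv = -np.minimum(cor, 0.0) * u[ii, jj]
        aPv = aPv + mu * kap_u ** 2 / h_u ** 2 * V_u
        # cross viscous term + 2 mu k/h^2 dv/ds
        dv_ds = (0.5 * (v[np.minimum(ii, Ns - 1), jj] + v[np.minimum(ii, Ns - 1), jj + 1])
                 - 0.5 * (v[iW, jj] + v[iW, jj + 1])) / g.ds_u[ii]
        bv = bv + 2.0 * mu * kap_u / h_u ** 2 * dv_ds * V_u

        # pressure gradient
        bv = bv + (p[iW, jj] - p[ii, jj]) * m.dn[jj]

        # deferred SOU corrections (convection)
        if sou:
            uW2 = np.where(iW - 1 >= 0, u[np.maximum(iW - 1, 0), jj], 0.0)
            vW2 = (iW - 1 >= 0) & g.ufree[np.maximum(iW - 1, 0), jj]
            uE2 = np.where(iE + 1 <= Ns, u[np.minimum(iE + 1, Ns), jj], 0.0)
            vE2 = (iE + 1 <= Ns) & g.ufree[np.minimum(iE + 1, Ns), jj]
            sf = m.s_faces
            corr_e = _sou_face(u[iW, jj], u[ii, jj], u[iE, jj], uE2,
                               sf[iW], sf[ii], sf[iE], sf[np.minimum(iE + 1, Ns)],
                               m.s_c[ii], rho * Fe,
                               g.ufree[iW, jj], vE2, False)
            corr_w = _sou_face(uW2, u[iW, jj], u[ii, jj], u[iE, jj],
                               sf[np.maximum(iW - 1, 0)], sf[iW], sf[ii], sf[iE],
                               m.s_c[iW], rho * Fw,
                               vW2, g.ufree[iE, jj], False)
            jN2 = np.minimum(jj + 2, Nn - 1)
            jS2 = np.maximum(jj - 2, 0)
            uN = np.where(nN_ok, u[ii, np.minimum(jj + 1, Nn - 1)], 0.0)
            uS = np.where(nS_ok, u[ii, np.maximum(jj - 1, 0)], 0.0)
            uN2 = np.where((jj + 2 <= Nn - 1) & g.ufree[ii, jN2], u[ii, jN2], 0.0)
            vN2 = (jj + 2 <= Nn - 1) & g.ufree[ii, jN2] & nN_ok
            uS2 = np.where((jj - 2 >= 0) & g.ufree[ii, jS2], u[ii, jS2], 0.0)
            vS2 = (jj - 2 >= 0) & g.ufree[ii, jS2] & nS_ok
            nc = m.n_c
            corr_n = np.where(nN_ok, _sou_face(
                uS, u[ii, jj], uN, uN2,
                nc[np.maximum(jj - 1, 0)], nc[jj], nc[np.minimum(jj + 1, Nn - 1)], nc[jN2],
                m.n_faces[jj + 1], rho * FnN, nS_ok, vN2, False), 0.0)
            corr_s = np.where(nS_ok, _sou_face(
                uS2, uS, u[ii, jj], uN,
                nc[jS2], nc[np.maximum(jj - 1, 0)], nc[jj], nc[np.minimum(jj + 1, Nn - 1)],
                m.n_faces[jj], rho * FnS, vS2, nN_ok, False), 0.0)
            bv = bv - (corr_e - corr_w + corr_n - corr_s)

        # gather into full arrays
        aE[act], aW[act], aN[act], aS[act] = aEv, aWv, aNv, aSv
        aP[act], b[act] = aPv, bv

        res_u = _residual(u, aP, aE, aW, aN, aS, b, act)
        u_new = _solve_momentum(u, aP, aE, aW, aN, aS, b, act, g.u_colors,
                                settings.alpha_u)
        d_u[act] = m.dn[jj] / np.maximum(
            aP[act] / settings.alpha_u - (aE[act] + aW[act] + aN[act] + aS[act]), 1e-300)
        u = u_new

        # ---------------- v momentum ---------------------------------
        aE = np.zeros((Ns, Nn + 1)); aW = np.zeros_like(aE)
        aN = np.zeros_like(aE); aS = np.zeros_like(aE)
        aP = np.zeros_like(aE); b = np.zeros_like(aE)
        act = g.vact
        ii, jj = np.where(act)
        jS, jN = jj - 1, jj + 1

        Fe_v = 0.5 * (Fs[ii + 1, jS] + Fs[ii + 1, jj])
        Fw_v = 0.5 * (Fs[ii, jS] + Fs[ii, jj])
        FnN_v = 0.5 * (Fn[ii, jj] + Fn[ii, jN])
        FnS_v = 0.5 * (Fn[ii, jS] + Fn[ii, jj])

        eok = ii + 1 <= Ns - 1
        wok = ii - 1 >= 0
        e_ok = eok & g.vfree[np.minimum(ii + 1, Ns - 1), jj]
        w_ok = wok & g.vfree[np.maximum(ii - 1, 0), jj]
        ds_e = np.where(eok, 0.5 * (m.ds[ii] + m.ds[np.minimum(ii + 1, Ns - 1)]), m.ds[ii])
        ds_w = np.where(wok, 0.5 * (m.ds[np.maximum(ii - 1, 0)] + m.ds[ii]), m.ds[ii])
        h_v = g.h_v[ii, jj]
        De_v = mu * g.dn_v[jj] / (h_v * ds_e)
        Dw_v = mu * g.dn_v[jj] / (h_v * ds_w)
        DnN_v = mu * m.h_c[ii, jj] * m.ds[ii] / m.dn[jj]
        DnS_v = mu * m.h_c[ii, jS] * m.ds[ii] / m.dn[jS]

        aEv = np.where(e_ok, De_v, 0.0) + np.maximum(-Fe_v, 0.0) * rho
        aWv = np.where(w_ok | (ii == 0), Dw_v, 0.0) + np.maximum(Fw_v, 0.0) * rho
        aNv = DnN_v + np.maximum(-FnN_v, 0.0) * rho
        aSv = DnS_v + np.maximum(FnS_v, 0.0) * rho
        aPv = aEv + aWv + aNv + aSv + rho * (Fe_v - Fw_v + FnN_v - FnS_v)
        # tangential walls east/west of the v CV (strut sides, outlet):
        # half-distance no-slip where the neighbour face is solid
        wallE = (~e_ok) & eok & (~g.vfree[np.minimum(ii + 1, Ns - 1), jj])
        wallW = (~w_ok) & wok & (~g.vfree[np.maximum(ii - 1, 0), jj])
        aPv = aPv + np.where(wallE, 2.0 * mu * g.dn_v[jj] / (h_v * m.ds[ii]), 0.0)
        aPv = aPv + np.where(wallW, 2.0 * mu * g.dn_v[jj] / (h_v * m.ds[ii]), 0.0)

        kap_v = g.kap_v[ii, jj]
        V_v = g.V_v[ii, jj]
        ubar = 0.25 * (u[ii, jS] + u[ii, jj] + u[ii + 1, jS] + u[ii + 1, jj])
        bv = rho * ubar ** 2 * kap_v / h_v * V_v
        aPv = aPv + mu * kap_v ** 2 / h_v ** 2 * V_v
        du_ds = (0.5 * (u[ii + 1, jS] + u[ii + 1, jj]) - 0.5 * (u[ii, jS] + u[ii, jj])) / m.ds[ii]
        bv = bv - 2.0 * mu * kap_v / h_v ** 2 * du_ds * V_v
        bv = bv + (p[ii, jS] - p[ii, jj]) * h_v * m.ds[ii]

        if sou:
            sc = m.s_c
            vW = np.where(w_ok, v[np.maximum(ii - 1, 0), jj], 0.0)
            vE = np.where(e_ok, v[np.minimum(ii + 1, Ns - 1), jj], 0.0)
            iW2 = np.maximum(ii - 2, 0)
            iE2 = np.minimum(ii + 2, Ns - 1)
            vW2ok = (ii - 2 >= 0) & g.vfree[iW2, jj] & w_ok
            vE2ok = (ii + 2 <= Ns - 1) & g.vfree[iE2, jj] & e_ok
            corr_e = np.where(e_ok, _sou_face(
                vW, v[ii, jj], vE, np.where(vE2ok, v[iE2, jj], 0.0),
                sc[np.maximum(ii - 1, 0)], sc[ii], sc[np.minimum(ii + 1, Ns - 1)], sc[iE2],
                m.s_faces[ii + 1], rho * Fe_v, w_ok, vE2ok, False), 0.0)
            corr_w = np.where(w_ok, _sou_face(
                np.where(vW2ok, v[iW2, jj], 0.0), vW, v[ii, jj], vE,
                sc[iW2], sc[np.maximum(ii - 1, 0)], sc[ii], sc[np.minimum(ii + 1, Ns - 1)],
                m.s_faces[ii], rho * Fw_v, vW2ok, e_ok, False), 0.0)
            nf = m.n_faces
            vN = np.where(jj + 1 <= Nn - 1, v[ii, np.minimum(jN, Nn - 1)], 0.0)
            vS = np.where(jj - 1 >= 1, v[ii, np.maximum(jS, 0)], 0.0)
            nok = (jj + 1 <= Nn - 1) & g.vfree[ii, np.minimum(jN, Nn - 1)]
            sok = (jj - 1 >= 1) & g.vfree[ii, np.maximum(jS, 0)]
            jN2v = np.minimum(jj + 2, Nn)
            jS2v = np.maximum(jj - 2, 0)
            vN2ok = (jj + 2 <= Nn - 1) & g.vfree[ii, np.minimum(jN2v, Nn)] & nok
            vS2ok = (jj - 2 >= 1) & g.vfree[ii, jS2v] & sok
            corr_n = _sou_face(
                vS, v[ii, jj], vN, np.where(vN2ok, v[ii, np.minimum(jN2v, Nn)], 0.0),
                nf[np.maximum(jS, 0)], nf[jj], nf[np.minimum(jN, Nn)], nf[np.minimum(jN2v, Nn)],
                m.n_c[jj], rho * FnN_v, sok, vN2ok, False)
            corr_s = _sou_face(
                np.where(vS2ok, v[ii, jS2v], 0.0), vS, v[ii, jj], vN,
                nf[jS2v], nf[np.maximum(jS, 0)], nf[jj], nf[np.minimum(jN, Nn)],
                m.n_c[jS], rho * FnS_v, vS2ok, nok, False)
            bv = bv - (corr_e - corr_w + corr_n - corr_s)

        aE[act], aW[act], aN[act], aS[act] = aEv, aWv, aNv, aSv
        aP[act], b[act] = aPv, bv

        res_v = _residual(v, aP, aE, aW, aN, aS, b, act)
        v = _solve_momentum(v, aP, aE, aW, aN, aS, b, act, g.v_colors,
                            settings.alpha_u)
        d_v[act] = g.h_v[ii, jj] * m.ds[ii] / np.maximum(
            aP[act] / settings.alpha_u - (aE[act] + aW[act] + aN[act] + aS[act]), 1e-300)

        # ---------------- outlet & pressure correction ----------------
        u[0] = g.u_in
        out_rows = g.ufree[-1]
        u[-1, out_rows] = u[-2, out_rows]
        q_out = float((u[-1] * m.dn).sum())
        if q_out != 0.0:
            u[-1] *= g.q_in / q_out
        d_u[-1] = d_u[-2]

        Fs = u * m.dn[None, :]
        Fn = v * m.h_nf * m.ds[:, None]
        imb = Fs[1:] - Fs[:-1] + Fn[:, 1:] - Fn[:, :-1]
        res_c = float(np.abs(imb[g.F]).sum())

        pp = _pressure_correction(m, g, d_u, d_v, imb, psolver)
        # correct velocities (full correction) and pressure (relaxed)
        iu, ju = np.where(g.uact)
        u[iu, ju] += d_u[iu, ju] * (pp[iu - 1, ju] - pp[iu, ju])
        u[-1, out_rows] += d_u[-1, out_rows] * pp[-1, out_rows]
        iv, jv = np.where(g.vact)
        v[iv, jv] += d_v[iv, jv] * (pp[iv, jv - 1] - pp[iv, jv])
        p[g.F] += settings.alpha_p * pp[g.F]

        # ---------------- convergence ---------------------------------
        if it <= 5:
            norms["u"] = max(norms["u"], res_u)
            norms["v"] = max(norms["v"], res_v)
        su = res_u / max(norms["u"], 1e-300)
        sv = res_v / max(norms["v"], 1e-300)
        sc_ = res_c / max(norms["c"], 1e-300)
        history.append({"iter": it, "res_u": su, "res_v": sv, "res_c": sc_})
        if it > 5 and max(su, sv, sc_) < settings.residual_tol:
            return FlowField(mesh=m, u=u, v=v, p=p, fluid_props=fluid,
                             inlet=inlet, settings=settings,
                             history=history, converged=True)

    raise NonConvergenceError(
        f"flow solve did not reach residual {settings.residual_tol:g} in "
        f"{settings.max_outer_iterations} iterations "
        f"(last: u={history[-1]['res_u']:.2e}, v={history[-1]['res_v']:.2e}, "
        f"c={history[-1]['res_c']:.2e})", history)


def _nb_sum(phi, aE, aW, aN, aS):
    """Sum of neighbour-coefficient * neighbour-value with zero ghosts."""
    s = np.zeros_like(phi)
    s[:-1] += aE[:-1] * phi[1:]
    s[1:] += aW[1:] * phi[:-1]
    s[:, :-1] += aN[:, :-1] * phi[:, 1:]
    s[:, 1:] += aS[:, 1:] * phi[:, :-1]
    return s


def _residual(phi, aP, aE, aW, aN, aS, b, act, _=None):
    """L1 imbalance of the unrelaxed equations at the current iterate."""
    r = aP * phi - _nb_sum(phi, aE, aW, aN, aS) - b
    return float(np.abs(r[act]).sum())


def _solve_momentum(phi, aP, aE, aW, aN, aS, b, act, colors, alpha,
                    sweeps: int = 8):
    """Red-black Gauss-Seidel sweeps of one under-relaxed momentum system.

    An inexact momentum solve is sufficient inside the SIMPLEC outer loop
    (the outer iterations polish it); the sweeps are fully vectorized per
    colour, and the under-relaxed diagonal makes them robustly convergent.
    """
    diag = np.where(act, aP / alpha, 1.0)
    rhs = b + (1.0 - alpha) / alpha * aP * phi
    out = phi.copy()
    for _ in range(sweeps):
        for color in colors:
            upd = (rhs + _nb_sum(out, aE, aW, aN, aS)) / diag
            out[color] = upd[color]
    return out


def _pressure_correction(m: Mesh, g: _Stag, d_u, d_v, imb,
                         psolver: "_PoissonSolver") -> np.ndarray:
    """Solve the SIMPLEC pressure-correction Poisson equation."""
    Ns, Nn = m.shape
    F = g.F
    ii, jj = np.where(F)
    n = ii.size
    me = g.p_id[F]
    rows_l, cols_l, vals_l = [], [], []
    diag = np.zeros(n)
    # streamwise faces: west face (i, j) links (i-1, j); east face (i+1, j)
    cW = np.where((ii >= 1) & g.ufree[ii, jj], d_u[ii, jj] * m.dn[jj], 0.0)
    cW[ii == 0] = 0.0                      # inlet: fixed velocity
    cE = np.where(g.ufree[ii + 1, jj], d_u[ii + 1, jj] * m.dn[jj], 0.0)
    cE_out = (ii == Ns - 1) & g.ufree[ii + 1, jj]
    # transverse faces
    cS = np.where(g.vfree[ii, jj], d_v[ii, jj] * m.h_nf[ii, jj] * m.ds[ii], 0.0)
    cN = np.where(g.vfree[ii, jj + 1], d_v[ii, jj + 1] * m.h_nf[ii, jj + 1] * m.ds[ii], 0.0)

    for (c, di, dj, interior) in (
        (cW, -1, 0, ii >= 1),
        (cE, 1, 0, ii + 1 <= Ns - 1),
        (cS, 0, -1, jj >= 1),
        (cN, 0, 1, jj + 1 <= Nn - 1),
    ):
        diag += c
        ok = interior & (c != 0.0)
        ni = np.clip(ii + di, 0, Ns - 1)
        nj = np.clip(jj + dj, 0, Nn - 1)
        nid = g.p_id[ni, nj]
        ok = ok & (nid >= 0)
        rows_l.append(me[ok]); cols_l.append(nid[ok]); vals_l.append(-c[ok])
    # outlet ghost p' = 0 is already in the diagonal via cE at i = Ns-1
    diag = np.where(diag > 0, diag, 1.0)   # isolated cells (none expected)
    rows_l.append(me); cols_l.append(me); vals_l.append(diag)
    A = _csr(rows_l, cols_l, vals_l, n)
    rhs = -imb[F]
    sol = psolver.solve(A, rhs)
    pp = np.zeros((Ns, Nn))
    pp[F] = sol
    return pp
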