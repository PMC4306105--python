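"""Fully developed secondary (Dean-vortex) flow in a loosely curved pipe.

The classical reduced model for curved-pipe secondary flow: steady, fully
developed flow in a circular pipe of radius ``a`` coiled at bend radius
``R``, in the loose-curvature limit ``a/R -> 0``.  On the unit disc (lengths
scaled by ``a``), with the axial velocity ``w`` scaled by ``W0 = G a^2 /
(4 mu)`` (``G`` the axial pressure gradient) and the secondary stream
function ``psi`` scaled by the kinematic viscosity ``nu``:

    lap(w)    = -4 + (psi_y w_x - psi_x w_y)
    lap(zeta) = (psi_y zeta_x - psi_x zeta_y) - 2 Dn_p^2 * w * w_y
    lap(psi)  = zeta,      w = psi = dpsi/dn = 0 on r = 1

with ``x`` toward the outer bend, ``y`` normal to the bend plane,
``zeta`` the secondary vorticity, and the pressure-gradient Dean number
``Dn_p = (W0 a / nu) sqrt(a/R)``.  The centrifugal source ``w w_y`` drives a
pair of counter-rotating vortices mirror-symmetric about the bend plane; the
fast core is advected toward the outer bend.

The solver works with the flow-rate Dean number ``Dn = Re sqrt(a/R)``
(``Re = 2 a w_mean / nu``), matching ``Dn_p`` to the requested ``Re`` by a
short outer iteration.  Reported fields are rescaled so the axial velocity
is in units of the mean axial velocity and secondary velocities in units of
``nu / a``; the perturbation-series oracle shares those scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .flow_solver import NonConvergenceError

__all__ = [
    "DeanSolution",
    "dean_number",
    "classify_dean_regime",
    "solve_dean_cross_section",
    "dean_series_oracle",
]

SERIES_VALID_DN = 20.0


def dean_number(Re: float, r: float, R: float) -> float:
    """Dn = Re * sqrt(r / R), with ``r`` the lumen (pipe) radius."""
    if Re < 0:
        raise ValueError("Re must be non-negative")
    if r <= 0 or R <= 0 or r >= R:
        raise ValueError("need 0 < r < R (pipe radius smaller than bend radius)")
    return Re * math.sqrt(r / R)


def classify_dean_regime(Dn: float) -> str:
    """'unstable' for Dn above the instability threshold 36, else 'stable'."""
    if Dn < 0:
        raise ValueError("Dn must be non-negative")
    return "unstable" if Dn > 36.0 else "stable"


@dataclass
class DeanSolution:
    """Axial velocity and secondary flow on the pipe cross-section.

    ``w`` is in units of the mean axial velocity (area mean 1), ``psi`` in
    units of ``nu`` (secondary velocities in ``nu / a``).  ``x = r cos(theta)``
    points toward the outer bend; the bend plane is ``theta in {0, pi}``.
    """

    r: np.ndarray                # (Nr,) radial nodes in (0, 1)
    theta: np.ndarray            # (Nt,) azimuthal nodes, periodic
    w: np.ndarray                # (Nr, Nt) axial velocity / mean axial velocity
    psi: np.ndarray              # (Nr, Nt) secondary stream function / nu
    zeta: np.ndarray             # (Nr, Nt) secondary vorticity / (nu / a^2)
    Dn: float                    # flow-rate Dean number Re sqrt(a/R)
    Dn_pressure: float           # pressure-gradient Dean number
    curvature_ratio: float       # a / R
    Re: float
    converged: bool = True
    series_warning: bool = False # set when a series result is used beyond
                                 # its documented validity (Dn > 20)
    history: list[float] = field(default_factory=list)

    # ---- secondary velocities and summary scalars ----------------------
    def secondary_velocities(self) -> tuple[np.ndarray, np.ndarray]:
        """(u_r, u_theta) of the in-plane flow, units nu / a."""
        dr = self.r[1] - self.r[0]
        dt = self.theta[1] - self.theta[0]
        psi_p = _pad_disc(self.psi, dirichlet_wall=True)
        psi_r = (psi_p[2:] - psi_p[:-2]) / (2 * dr)
        psi_t = (np.roll(self.psi, -1, axis=1) - np.roll(self.psi, 1, axis=1)) / (2 * dt)
        u_r = psi_t / self.r[:, None]
        u_t = -psi_r
        return u_r, u_t

    @property
    def peak_axial(self) -> float:
        """Peak axial velocity in units of the mean axial velocity."""
        return float(self.w.max())

    @property
    def peak_secondary_speed(self) -> float:
        """Peak in-plane secondary speed, units nu / a."""
        u_r, u_t = self.secondary_velocities()
        return float(np.hypot(u_r, u_t).max())

    def peak_total_speed(self, nu_over_a_over_vmean: float) -> float:
        """Peak of the full speed |(u_sec, w)| in mean-axial-velocity units.

        ``nu_over_a_over_vmean`` converts secondary units to axial units:
        (nu/a) / v_mean = 2 / Re.
        """
        u_r, u_t = self.secondary_velocities()
        sec = np.hypot(u_r, u_t) * nu_over_a_over_vmean
        return float(np.sqrt(sec**2 + self.w**2).max())

    @property
    def axial_max_location(self) -> float:
        """Signed x-position of the axial-velocity maximum (+ = outer bend)."""
        j, k = np.unravel_index(np.argmax(self.w), self.w.shape)
        return float(self.r[j] * math.cos(self.theta[k]))

    @property
    def secondary_kinetic_energy(self) -> float:
        """Area-integrated (1/2)|u_sec|^2, units (nu/a)^2."""
        u_r, u_t = self.secondary_velocities()
        dr = self.r[1] - self.r[0]
        dt = self.theta[1] - self.theta[0]
        dA = self.r[:, None] * dr * dt
        return float((0.5 * (u_r**2 + u_t**2) * dA).sum())


def _pad_disc(f: np.ndarray, dirichlet_wall: bool) -> np.ndarray:
    """Add ghost rings across the pipe centre and outside the wall."""
    Nt = f.shape[1]
    centre = np.roll(f[:1], Nt // 2, axis=1)           # across r = 0
    wall = -f[-1:] if dirichlet_wall else f[-1:]       # linear through 0 at r=1
    return np.vstack([centre, f, wall])


def _disc_laplacian(Nr: int, Nt: int):
    """FV Laplacian on the disc with a Dirichlet-0 wall.

    Returns ``(L, wall_coef, r, dr, dt)``: ``wall_coef`` gives, per
    azimuthal node of the outermost ring, the factor multiplying a non-zero
    Dirichlet wall value when moved to the right-hand side.
    """
    dr = 1.0 / Nr
    dt = 2 * math.pi / Nt
    r = (np.arange(Nr) + 0.5) * dr
    idx = lambda j, k: j * Nt + (k % Nt)
    rows, cols, vals = [], [], []
    wall_coef = np.zeros(Nt)
    for j in range(Nr):
        rp = (j + 1) * dr        # outer face radius
        rm = j * dr              # inner face radius
        for k in range(Nt):
            me = idx(j, k)
            diag = 0.0
            # radial neighbours
            if j + 1 < Nr:
                c = rp / (dr * dr * r[j])
                rows.append(me); cols.append(idx(j + 1, k)); vals.append(c)
                diag -= c
            else:
                c = rp / (dr * (dr / 2) * r[j])        # wall at r = 1
                diag -= c
                wall_coef[k] = c
            if j > 0:
                c = rm / (dr * dr * r[j])
                rows.append(me); cols.append(idx(j - 1, k)); vals.append(c)
                diag -= c
            # (j = 0: zero-area face at the axis, no flux)
            c = 1.0 / (r[j] * r[j] * dt * dt)
            rows.append(me); cols.append(idx(j, k + 1)); vals.append(c)
            rows.append(me); cols.append(idx(j, k - 1)); vals.append(c)
            diag -= 2 * c
            rows.append(me); cols.append(me); vals.append(diag)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(Nr * Nt, Nr * Nt))
    return L, wall_coef, r, dr, dt


def _disc_operator(Nr: int, Nt: int):
    """Laplacian plus the psi-coupling of the wall-vorticity closure.

    The zeta equation's wall flux uses zeta_wall = 8 psi_last / dr^2
    implicitly (the segregated Thom iteration is unstable); returns the raw
    Laplacian ``L``, the coupling diagonal ``C`` and grid arrays.
    """
    L, wall_coef, r, dr, dt = _disc_laplacian(Nr, Nt)
    n = Nr * Nt
    crow = np.zeros(n)
    crow[(Nr - 1) * Nt:] = wall_coef * 8.0 / dr**2
    C = sp.diags(crow)
    return L.tocsr(), C, r, dr, dt


def _advection_matrix(psi: np.ndarray, r: np.ndarray, dr: float, dt: float):
    """First-order upwind advection operator (per unit volume) for the
    secondary flow described by ``psi``.

    Face volumetric fluxes are stream-function differences between cell
    corners, so the discrete advection field is exactly divergence-free and
    the operator has zero row sums (conservative, monotone).
    """
    Nr, Nt = psi.shape
    n = Nr * Nt
    # corner values at radius j*dr, theta (k + 1/2) dt
    psi_k = 0.5 * (psi + np.roll(psi, -1, axis=1))
    corner = np.empty((Nr + 1, Nt))
    corner[1:Nr] = 0.5 * (psi_k[:-1] + psi_k[1:])
    corner[0] = psi_k[0].mean()     # axis: single point, no net flux
    corner[Nr] = 0.0                # wall: psi = 0, no flux
    Cor = corner[1:]                # outer-face corners of each cell ring
    Fr_out = Cor - np.roll(Cor, 1, axis=1)          # (Nr, Nt): outer radial face
    Ft = corner[:-1] - corner[1:]                   # (Nr, Nt): face (j, k+1/2)

    V = (r * dr * dt)[:, None] * np.ones((1, Nt))
    jj, kk = np.meshgrid(np.arange(Nr), np.arange(Nt), indexing="ij")
    me = (jj * Nt + kk).ravel()
    rows, cols, vals = [], [], []

    def add(F, nb_idx, valid):
        Fv = (F / V).ravel()
        nb = nb_idx.ravel()
        ok = valid.ravel()
        pos = np.maximum(Fv, 0.0)
        neg = np.minimum(Fv, 0.0)
        rows.append(me); cols.append(me); vals.append(pos)
        rows.append(me[ok]); cols.append(nb[ok]); vals.append(neg[ok])

    nb_out = np.clip(jj + 1, 0, Nr - 1) * Nt + kk
    add(Fr_out, nb_out, jj + 1 <= Nr - 1)           # wall face flux is 0 anyway
    F_in_out = -np.vstack([np.zeros((1, Nt)), Fr_out[:-1]])
    nb_in = np.clip(jj - 1, 0, Nr - 1) * Nt + kk
    add(F_in_out, nb_in, jj - 1 >= 0)
    nb_e = jj * Nt + (kk + 1) % Nt
    add(Ft, nb_e, np.ones_like(jj, dtype=bool))
    F_w = -np.roll(Ft, 1, axis=1)
    nb_w = jj * Nt + (kk - 1) % Nt
    add(F_w, nb_w, np.ones_like(jj, dtype=bool))

    return sp.csr_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n, n))


def _jacobian(psi, f, r, dr, dt, f_dirichlet: bool):
    """psi_y f_x - psi_x f_y = (psi_theta f_r - psi_r f_theta) / r."""
    psi_p = _pad_disc(psi, True)
    f_p = _pad_disc(f, f_dirichlet)
    psi_r = (psi_p[2:] - psi_p[:-2]) / (2 * dr)
    f_r = (f_p[2:] - f_p[:-2]) / (2 * dr)
    psi_t = (np.roll(psi, -1, 1) - np.roll(psi, 1, 1)) / (2 * dt)
    f_t = (np.roll(f, -1, 1) - np.roll(f, 1, 1)) / (2 * dt)
    return (psi_t * f_r - psi_r * f_t) / r[:, None]


def solve_dean_cross_section(Re: float, curvature_ratio: float,
                             n_r: int = 40, n_theta: int = 80,
                             tol: float = 1e-8, max_iter: int = 2000,
                             relax: float = 0.7) -> DeanSolution:
    """Solve the loose-curvature Dean equations at flow-rate Reynolds ``Re``.

    ``curvature_ratio`` is a/R (pipe radius over bend radius).  Returns the
    fields rescaled to mean-axial-velocity units plus summary scalars.
    """
    if not 0 < curvature_ratio < 1:
        raise ValueError("curvature_ratio must lie in (0, 1)")
    if Re < 0:
        raise ValueError("Re must be non-negative")
    if n_theta % 2:
        raise ValueError("n_theta must be even (centre ghost uses theta + pi)")
    L, C, r, dr, dt = _disc_operator(n_r, n_theta)
    I = sp.identity(n_r * n_theta, format="csr")
    theta = np.arange(n_theta) * dt
    sin_t = np.sin(theta)[None, :]
    cos_t = np.cos(theta)[None, :]
    shape = (n_r, n_theta)
    w = np.zeros(shape)
    psi = np.zeros(shape)
    zeta = np.zeros(shape)
    area = math.pi

    history: list[float] = []

    n = n_r * n_theta

    def picard_map(x: np.ndarray) -> np.ndarray:
        """One composite Gauss-Seidel step of the lagged-coefficient system.

        Advection by the secondary flow is implicit (upwind, fluxes from the
        lagged psi); the centrifugal source uses the freshly solved w.
        ``x`` stacks (w, psi, zeta).
        """
        K = picard_map.K
        w_s = x[:n].reshape(shape)
        psi_s = x[n:2 * n].reshape(shape)
        Adv = _advection_matrix(psi_s, r, dr, dt)
        w_new = spla.spsolve((L - Adv).tocsc(), np.full(n, -4.0)).reshape(shape)

        w_p = _pad_disc(w_new, True)
        w_r = (w_p[2:] - w_p[:-2]) / (2 * dr)
        w_t = (np.roll(w_new, -1, 1) - np.roll(w_new, 1, 1)) / (2 * dt)
        w_y = sin_t * w_r + cos_t / r[:, None] * w_t

        A = sp.bmat([[L, -I], [C, L - Adv]], format="csc")
        rhs = np.concatenate([np.zeros(n), (-K * w_new * w_y).ravel()])
        sol = spla.splu(A).solve(rhs)
        return np.concatenate([w_new.ravel(), sol])

    picard_map.K = 0.0

    def picard(K: float, stage_tol: float, alpha: float,
               iter_budget: int, anderson_depth: int = 3) -> bool:
        """Anderson-accelerated fixed-point iteration at source strength K.

        Plain (even damped) Picard limit-cycles at the higher Dean numbers;
        Anderson mixing over a short residual history removes the
        oscillatory mode.
        """
        nonlocal w, psi, zeta
        picard_map.K = K
        x = np.concatenate([w.ravel(), psi.ravel(), zeta.ravel()])
        X: list[np.ndarray] = []      # iterate history
        G: list[np.ndarray] = []      # residual history
        for it in range(iter_budget):
            fx = picard_map(x)
            g = fx - x
            scale = max(float(np.abs(fx[n:2 * n]).max()), 1e-14)
            rel = float(np.abs(g[n:2 * n]).max()) / scale
            history.append(rel)
            if not np.isfinite(rel) or rel > 1e6:
                return False          # blown up: caller shrinks the K step
            if rel < stage_tol:
                w = fx[:n].reshape(shape)
                psi = fx[n:2 * n].reshape(shape)
                zeta = fx[2 * n:].reshape(shape)
                return True
            X.append(x.copy())
            G.append(g.copy())
            if len(X) > anderson_depth + 1:
                X.pop(0); G.pop(0)
            if len(X) >= 2:
                dG = np.column_stack([G[k + 1] - G[k] for k in range(len(G) - 1)])
                dX = np.column_stack([X[k + 1] - X[k] for k in range(len(X) - 1)])
                gamma, *_ = np.linalg.lstsq(dG, g, rcond=None)
                x = x + alpha * g - (dX + alpha * dG) @ gamma
            else:
                x = x + alpha * g
            if not np.all(np.isfinite(x)):
                return False
        w = x[:n].reshape(shape)
        psi = x[n:2 * n].reshape(shape)
        zeta = x[2 * n:].reshape(shape)
        return False

    # continuation in the centrifugal source strength K = 2 Dn_p^2 (the
    # direct iteration diverges at the strongly nonlinear Dean numbers of
    # interest), interleaved with flow-rate matching for Re.  On a failed
    # stage the step is halved and the last converged state restored.
    def mean_w() -> float:
        return float((w * r[:, None] * dr * dt).sum() / area)

    wbar = 0.5
    K_cur = 0.0
    Dn_flow = Re * math.sqrt(curvature_ratio)
    if Re > 0:
        factor = 4.0
        good = (w.copy(), psi.copy(), zeta.copy())
        total_budget = max_iter
        for _ in range(200):
            wbar = mean_w() if K_cur else 0.5
            K_target = 2.0 * (Re * math.sqrt(curvature_ratio) / (2 * wbar)) ** 2
            final = K_cur >= K_target * 0.999
            if final:
                K_try = K_target
            elif K_cur == 0.0:
                K_try = min(K_target, 1250.0)    # Dn_p = 25: safely linear
            else:
                K_try = min(K_target, K_cur * factor)
            n0 = len(history)
            ok = picard(K_try, tol if K_try >= K_target * 0.999 else max(tol, 1e-7),
                        relax, iter_budget=min(250, max(total_budget, 50)))
            total_budget -= len(history) - n0
            if ok:
                K_cur = K_try
                good = (w.copy(), psi.copy(), zeta.copy())
                factor = min(factor * 1.3, 4.0)
                wbar_new = mean_w()
                if final and abs(wbar_new - wbar) < 1e-9 * abs(wbar):
                    wbar = wbar_new
                    break
                wbar = wbar_new
            else:
                w, psi, zeta = (a.copy() for a in good)
                factor = 1.0 + (factor - 1.0) / 2.0
                if factor - 1.0 < 5e-3 or total_budget <= 0:
                    raise NonConvergenceError(
                        f"Dean continuation stalled near K = {K_try:.3g} "
                        f"(last update {history[-1]:.2e})",
                        [{"dpsi": h} for h in history])
        else:
            raise NonConvergenceError(
                "Dean continuation did not settle", [{"dpsi": h} for h in history])
    else:
        picard(0.0, tol, 1.0, iter_budget=max_iter)
        wbar = mean_w()

    Re_G = math.sqrt(K_cur / (2 * curvature_ratio)) if K_cur else 0.0
    Dn = Dn_flow
    return DeanSolution(
        r=r, theta=theta,
        w=w / wbar,                      # mean-axial-velocity units
        psi=psi, zeta=zeta,
        Dn=Dn, Dn_pressure=Re_G * math.sqrt(curvature_ratio),
        curvature_ratio=curvature_ratio, Re=Re,
        converged=True, history=history)


def dean_series_oracle(Dn: float, n_r: int = 40, n_theta: int = 80) -> DeanSolution:
    """Leading-order perturbation series for the loose-curvature Dean flow.

    Classical result: the first secondary-flow term is

        psi_1 = (Dn^2 / 288) * r (1 - r^2)^2 (4 - r^2) sin(theta)

    with the Poiseuille axial profile ``w = 2 (1 - r^2)`` (mean-velocity
    units) unchanged at this order.  Documented validity Dn <= 20; beyond
    that the returned solution carries ``series_warning``.
    """
    if Dn < 0:
        raise ValueError("Dn must be non-negative")
    if n_theta % 2:
        raise ValueError("n_theta must be even")
    dr = 1.0 / n_r
    dt = 2 * math.pi / n_theta
    r = (np.arange(n_r) + 0.5) * dr
    theta = np.arange(n_theta) * dt
    rr = r[:, None]
    st = np.sin(theta)[None, :]
    f = rr * (1 - rr**2) ** 2 * (4 - rr**2) / 288.0
    psi = Dn**2 * f * st
    w = 2.0 * (1 - rr**2) * np.ones_like(st)
    # zeta = lap(psi): analytic, lap(f sin t) = L[f] sin t with
    # L[f] = f'' + f'/r - f/r^2; f = (-r^7 + 6 r^5 - 9 r^3 + 4 r)/288
    Lf = (-48 * rr**5 + 144 * rr**3 - 72 * rr) / 288.0
    zeta = Dn**2 * Lf * st
    return DeanSolution(
        r=r, theta=theta, w=w, psi=psi, zeta=zeta,
        Dn=Dn, Dn_pressure=Dn, curvature_ratio=float("nan"), Re=float("nan"),
        converged=True, series_warning=Dn > SERIES_VALID_DN)
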