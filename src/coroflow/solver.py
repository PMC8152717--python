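"""Steady axisymmetric Navier–Stokes flow through a vessel lumen.

The flow of an incompressible Newtonian fluid through an axisymmetric,
rigid-walled lumen is computed in the streamfunction–vorticity form of
the steady Navier–Stokes equations,

    E²ψ = −r·ω,                      E²ψ = ψ_zz + ψ_rr − ψ_r/r
    u·∇ω − (u_r/r)·ω = ν(∇²ω − ω/r²)

with u_z = ψ_r/r and u_r = −ψ_z/r (Stokes streamfunction), no-slip walls,
symmetry axis, a parabolic inlet profile scaled to the volumetric flow Q,
and a fully developed (streamwise-invariant) outlet. The equations are
discretised by finite differences on the body-fitted structured mesh in
mapped coordinates (ξ = z, η = r/R(z)): second-order central diffusion,
upwind-biased second-order convection, and solved as one coupled
nonlinear system by damped Newton iteration with pseudo-transient
continuation (sparse Jacobian by colored finite differences, direct LU).
Mass is conserved exactly by construction of the streamfunction.

Two modes mirror catheter-laboratory use:

* forward  — impose Q, report the translesional pressure drop ΔP between
  the proximal (Pa) and distal (Pd) pressure planes;
* inverse  — impose the measured ΔP, recover the absolute flow Q_CFD by
  root-finding on the forward model (ΔP(Q) is strictly increasing, so
  the root is unique). This inversion realises pressure boundary
  conditions while retaining the robustness of a flow-driven solve.

The pressure drop is recovered by integrating the axial momentum balance
along the symmetry axis. A quasi-steady pulsatile mode inverts the
steady model sample-by-sample along a measured pressure waveform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import CubicSpline
from scipy.sparse.linalg import splu

from .geometry import StructuredMesh, VesselGeometry, mesh_generate

__all__ = [
    "MMHG_PA",
    "ML_MIN_M3_S",
    "FluidProperties",
    "SolverSettings",
    "FlowSolution",
    "PressureWaveform",
    "FlowModel",
    "SolverError",
    "solve_forward",
    "solve_flow_from_pressure",
    "reduced_order_dp",
    "reynolds_number",
    "solve_pulsatile_quasi_steady",
    "mesh_convergence_check",
    "MeshConvergenceReport",
]

MMHG_PA = 133.322          # 1 mmHg in Pa
ML_MIN_M3_S = 1e-6 / 60.0  # 1 mL/min in m^3/s

#: Throat Reynolds number beyond which the laminar steady model is flagged.
RE_SUPERCRITICAL = 2000.0
#: Physiological-regime threshold used for subsetting accuracy reports.
RE_PHYSIOLOGICAL = 500.0


class SolverError(RuntimeError):
    """Raised when the nonlinear solve or the flow inversion fails."""


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: dynamic viscosity (Pa·s) and density (kg/m³)."""

    viscosity_Pa_s: float
    density_kg_m3: float

    def __post_init__(self) -> None:
        if not (self.viscosity_Pa_s > 0 and self.density_kg_m3 > 0):
            raise ValueError("viscosity and density must be positive")

    @classmethod
    def blood(cls) -> "FluidProperties":
        """In vivo default: μ = 3.5 mPa·s, ρ = 1056 kg/m³."""
        return cls(0.0035, 1056.0)

    @classmethod
    def analogue(cls) -> "FluidProperties":
        """Bench blood analogue (40/60 glycerol/water): μ = 3.5 mPa·s, ρ = 1082 kg/m³."""
        return cls(0.0035, 1082.0)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical controls for the flow solver.

    ``residual_target`` is the scaled steady-state residual below which a
    solution counts as converged; ``flow_tol_mL_min``/``flow_tol_rel`` set
    the inverse-mode tolerance (the larger of the two applies);
    ``ptc_dt0`` is the initial pseudo-time step of the continuation
    (nondimensional, in convective units).
    """

    residual_target: float = 1e-6
    max_iterations: int = 80
    mesh_resolution: str | tuple[int, int] = "standard"
    flow_tol_mL_min: float = 0.1
    flow_tol_rel: float = 0.001
    ptc_dt0: float = 2.0
    advection_scheme: str = "upwind2"  # or "upwind1"

    def __post_init__(self) -> None:
        if not self.residual_target > 0:
            raise ValueError("residual_target must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.advection_scheme not in ("upwind1", "upwind2"):
            raise ValueError("advection_scheme must be 'upwind1' or 'upwind2'")


@dataclass(frozen=True)
class PressureWaveform:
    """Sampled Pa/Pd pressure traces (time in s, pressures in mmHg)."""

    time_s: np.ndarray
    pa_mmHg: np.ndarray
    pd_mmHg: np.ndarray
    period_s: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        pa = np.asarray(self.pa_mmHg, dtype=float)
        pd = np.asarray(self.pd_mmHg, dtype=float)
        for name, arr in (("time_s", t), ("pa_mmHg", pa), ("pd_mmHg", pd)):
            object.__setattr__(self, name, arr)
        if t.size == 0:
            raise ValueError("empty pressure waveform")
        if t.ndim != 1 or pa.shape != t.shape or pd.shape != t.shape:
            raise ValueError("waveform arrays must be 1-D and equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("waveform time must be strictly increasing")

    def covers_full_period(self) -> bool:
        if self.period_s is None:
            return True  # caller takes the whole span as one period
        return (self.time_s[-1] - self.time_s[0]) >= self.period_s - 1e-12


@dataclass(frozen=True)
class FlowSolution:
    """Converged solver state for one (geometry, fluid, Q) triple."""

    Q_mL_min: float
    dP_mmHg: float
    residual: float
    converged: bool
    Re_stenosis: float
    mesh: StructuredMesh = field(repr=False)
    psi: np.ndarray = field(repr=False)       # Stokes streamfunction, m^3/s
    omega: np.ndarray = field(repr=False)     # azimuthal vorticity, 1/s
    u_z_m_s: np.ndarray = field(repr=False)   # axial velocity, (Nz, Nr)
    u_r_m_s: np.ndarray = field(repr=False)   # radial velocity, (Nz, Nr)
    p_axis_mmHg: np.ndarray = field(repr=False)  # axis pressure rel. outlet
    iterations: int = 0
    warnings: tuple[str, ...] = ()

    def flux_profile_mL_min(self) -> np.ndarray:
        """Volumetric flux through every cross-section by velocity quadrature.

        Computed by trapezoidal integration of 2π·r·u_z over each station —
        an independent check that the discrete velocity field transports
        the imposed flow (streamfunction construction conserves mass; the
        quadrature agreement is the non-trivial part).
        """
        r = self.mesh.r_mm * 1e-3
        integrand = 2.0 * np.pi * r * self.u_z_m_s
        return np.trapezoid(integrand, r, axis=1) / ML_MIN_M3_S

    def peak_velocity_at(self, s_mm: float) -> float:
        """Peak (on-axis) axial velocity at an arclength station, m/s."""
        i = int(np.argmin(np.abs(self.mesh.z_mm - s_mm)))
        return float(self.u_z_m_s[i].max())


# ---------------------------------------------------------------------------
# finite differences on a nonuniform grid
# ---------------------------------------------------------------------------

def _central_coeffs(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """3-point first/second derivative coefficients at interior nodes.

    Returns (c1, c2), each of shape (n-2, 3) for nodes 1..n-2.
    """
    hm = np.diff(x)[:-1]
    hp = np.diff(x)[1:]
    c1 = np.stack([-hp / (hm * (hm + hp)),
                   (hp - hm) / (hm * hp),
                   hm / (hp * (hm + hp))], axis=1)
    c2 = np.stack([2.0 / (hm * (hm + hp)),
                   -2.0 / (hm * hp),
                   2.0 / (hp * (hm + hp))], axis=1)
    return c1, c2


def _one_sided_coeffs(x0: float, x1: float, x2: float) -> np.ndarray:
    """First-derivative coefficients at x2 from points (x0, x1, x2)."""
    d20, d21, d10 = x2 - x0, x2 - x1, x1 - x0
    return np.array([d21 / (d10 * d20), -d20 / (d10 * d21),
                     (d20 + d21) / (d20 * d21)])


class _Discretization:
    """Nondimensional discrete operator set for one mesh.

    All quantities are scaled by the inlet radius R_ref and the inlet mean
    velocity U_ref = Q/(π R_ref²); the nondimensional problem depends on
    the flow only through the Reynolds number Re = ρ U_ref R_ref / μ, so
    converged fields can warm-start neighbouring flows directly.
    """

    N_COLORS_AXIS = 5  # stencil extent per direction (offsets −2..2)
    #: half-width (nondimensional velocity) of the smooth upwind switch —
    #: a hard sign switch makes the residual non-differentiable inside
    #: recirculation zones and defeats the Newton line search
    UPWIND_BLEND = 0.05

    def __init__(self, mesh: StructuredMesh, settings: SolverSettings):
        self.mesh = mesh
        self.settings = settings
        g = mesh.geometry
        self.R_ref_m = float(mesh.radius_mm[0]) * 1e-3

        # radius profile spline gives smooth R, R', R'' for the metric terms
        spl = CubicSpline(g.arclength_mm, g.radius_mm)
        z = mesh.z_mm
        self.xi = (z - z[0]) * 1e-3 / self.R_ref_m          # (Nz,)
        self.eta = mesh.eta.copy()                           # (Nr,)
        Rh = spl(z) * 1e-3 / self.R_ref_m
        Rp = np.asarray(spl(z, 1))                 # dR/dz in mm/mm, dimensionless
        Rpp = np.asarray(spl(z, 2)) * self.R_ref_m * 1e3   # (1/mm) · R_ref
        self.Rh, self.Rp, self.Rpp = Rh, Rp, Rpp

        nz, nr = mesh.shape
        self.nz, self.nr = nz, nr
        self.n = nz * nr

        self.r2 = Rh[:, None] * self.eta[None, :]            # physical r, (nz, nr)
        self.a = self.eta[None, :] * (Rp / Rh)[:, None]
        self.b = (-self.eta[None, :] * (Rpp / Rh)[:, None]
                  + 2.0 * self.eta[None, :] * ((Rp / Rh) ** 2)[:, None])

        self.c1x, self.c2x = _central_coeffs(self.xi)
        self.c1e, self.c2e = _central_coeffs(self.eta)
        # one-sided first derivative at the outlet (points Nz-3, Nz-2, Nz-1)
        self.out_c = _one_sided_coeffs(self.xi[-3], self.xi[-2], self.xi[-1])
        # wall-normal spacing for the vorticity wall condition
        d_eta_w = self.eta[-1] - self.eta[-2]
        cos_th = 1.0 / np.sqrt(1.0 + self.Rp**2)
        self.dn_wall = d_eta_w * Rh * cos_th                 # (nz,)

        self._build_upwind()
        self._build_jacobian_pattern()
        self._plane_fractions()

    # -- upwind coefficient tables -------------------------------------------
    def _build_upwind(self) -> None:
        def tables(x):
            n = x.size
            cm = np.zeros((n, 3))  # backward-biased: points (k-2, k-1, k)
            cp = np.zeros((n, 3))  # forward-biased:  points (k, k+1, k+2)
            for k in range(1, n - 1):
                if k >= 2:
                    cm[k] = _one_sided_coeffs(x[k - 2], x[k - 1], x[k])
                else:  # first-order fallback beside the boundary
                    h = x[k] - x[k - 1]
                    cm[k] = [0.0, -1.0 / h, 1.0 / h]
                if k <= n - 3:
                    c = _one_sided_coeffs(x[k + 2], x[k + 1], x[k])
                    cp[k] = c[::-1]
                else:
                    h = x[k + 1] - x[k]
                    cp[k] = [-1.0 / h, 1.0 / h, 0.0]
            return cm, cp

        if self.settings.advection_scheme == "upwind1":
            def tables1(x):
                n = x.size
                cm = np.zeros((n, 3))
                cp = np.zeros((n, 3))
                for k in range(1, n - 1):
                    cm[k] = [0.0, -1.0 / (x[k] - x[k - 1]), 1.0 / (x[k] - x[k - 1])]
                    cp[k] = [-1.0 / (x[k + 1] - x[k]), 1.0 / (x[k + 1] - x[k]), 0.0]
                return cm, cp
            self.upx = tables1(self.xi)
            self.upe = tables1(self.eta)
        else:
            self.upx = tables(self.xi)
            self.upe = tables(self.eta)

    def _plane_fractions(self) -> None:
        g = self.mesh.geometry
        z = self.mesh.z_mm
        self.inlet_plane_idx = (g.inlet_plane_mm - z[0]) * 1e-3 / self.R_ref_m
        self.outlet_plane_idx = (g.outlet_plane_mm - z[0]) * 1e-3 / self.R_ref_m

    # -- derivative helpers (vectorized over the grid) -------------------------
    def dxi(self, f: np.ndarray) -> np.ndarray:
        out = np.zeros_like(f)
        c = self.c1x
        out[1:-1] = (c[:, 0, None] * f[:-2] + c[:, 1, None] * f[1:-1]
                     + c[:, 2, None] * f[2:])
        return out

    def dxixi(self, f: np.ndarray) -> np.ndarray:
        out = np.zeros_like(f)
        c = self.c2x
        out[1:-1] = (c[:, 0, None] * f[:-2] + c[:, 1, None] * f[1:-1]
                     + c[:, 2, None] * f[2:])
        return out

    def deta(self, f: np.ndarray) -> np.ndarray:
        out = np.zeros_like(f)
        c = self.c1e
        out[:, 1:-1] = (c[None, :, 0] * f[:, :-2] + c[None, :, 1] * f[:, 1:-1]
                        + c[None, :, 2] * f[:, 2:])
        return out

    def detaeta(self, f: np.ndarray) -> np.ndarray:
        out = np.zeros_like(f)
        c = self.c2e
        out[:, 1:-1] = (c[None, :, 0] * f[:, :-2] + c[None, :, 1] * f[:, 1:-1]
                        + c[None, :, 2] * f[:, 2:])
        return out

    def dxi_upwind(self, f: np.ndarray, vel: np.ndarray) -> np.ndarray:
        cm, cp = self.upx
        fm = np.zeros_like(f)
        fp = np.zeros_like(f)
        fm[2:-1] = (cm[2:-1, 0, None] * f[:-3] + cm[2:-1, 1, None] * f[1:-2]
                    + cm[2:-1, 2, None] * f[2:-1])
        fm[1] = cm[1, 1] * f[0] + cm[1, 2] * f[1]
        fp[1:-2] = (cp[1:-2, 0, None] * f[1:-2] + cp[1:-2, 1, None] * f[2:-1]
                    + cp[1:-2, 2, None] * f[3:])
        fp[-2] = cp[-2, 0] * f[-2] + cp[-2, 1] * f[-1]
        w = 0.5 * (1.0 + np.tanh(vel / self.UPWIND_BLEND))
        return w * fm + (1.0 - w) * fp

    def deta_upwind(self, f: np.ndarray, vel: np.ndarray) -> np.ndarray:
        cm, cp = self.upe
        fm = np.zeros_like(f)
        fp = np.zeros_like(f)
        fm[:, 2:-1] = (cm[None, 2:-1, 0] * f[:, :-3] + cm[None, 2:-1, 1] * f[:, 1:-2]
                       + cm[None, 2:-1, 2] * f[:, 2:-1])
        fm[:, 1] = cm[1, 1] * f[:, 0] + cm[1, 2] * f[:, 1]
        fp[:, 1:-2] = (cp[None, 1:-2, 0] * f[:, 1:-2] + cp[None, 1:-2, 1] * f[:, 2:-1]
                       + cp[None, 1:-2, 2] * f[:, 3:])
        fp[:, -2] = cp[-2, 0] * f[:, -2] + cp[-2, 1] * f[:, -1]
        w = 0.5 * (1.0 + np.tanh(vel / self.UPWIND_BLEND))
        return w * fm + (1.0 - w) * fp

    # -- boundary profiles ------------------------------------------------------
    def inlet_psi(self) -> np.ndarray:
        # parabolic profile scaled to unit nondimensional mean velocity
        return 0.5 * self.eta**2 * (2.0 - self.eta**2)

    def inlet_omega(self) -> np.ndarray:
        return 4.0 * self.eta  # R̂(0) = 1 by construction

    def initial_guess(self) -> tuple[np.ndarray, np.ndarray]:
        """Locally parabolic (lubrication) fields — exact for a straight tube."""
        psi = np.broadcast_to(self.inlet_psi()[None, :], (self.nz, self.nr)).copy()
        omega = 4.0 * self.eta[None, :] / self.Rh[:, None] ** 3
        return psi, omega.copy()

    # -- velocities -------------------------------------------------------------
    def velocities(self, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nondimensional (u_z, u_r) at all nodes; axis values by quartic fit."""
        psi_eta = self.deta(psi)
        # one-sided eta-derivative on axis/wall rows for completeness
        e = self.eta
        psi_eta[:, 0] = (psi[:, 1] - psi[:, 0]) / (e[1] - e[0])
        psi_eta[:, -1] = (psi[:, -1] - psi[:, -2]) / (e[-1] - e[-2])
        psi_xi = self.dxi(psi)
        psi_xi[0] = (psi[1] - psi[0]) / (self.xi[1] - self.xi[0])
        psi_xi[-1] = (psi[-1] - psi[-2]) / (self.xi[-1] - self.xi[-2])

        with np.errstate(divide="ignore", invalid="ignore"):
            u_z = psi_eta / (self.Rh[:, None] ** 2 * self.eta[None, :])
            u_r = -(psi_xi - self.a * psi_eta) / self.r2
        u_z[:, 0] = self._axis_fit(psi)[0]
        u_r[:, 0] = 0.0
        return u_z, u_r

    def _axis_fit(self, psi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fit ψ ≈ a·r² + b·r⁴ near the axis; returns (u_axis, u_rr_axis)."""
        r1 = self.r2[:, 1]
        r2_ = self.r2[:, 2]
        p1, p2 = psi[:, 1], psi[:, 2]
        det = r1**2 * r2_**4 - r2_**2 * r1**4
        a_c = (p1 * r2_**4 - p2 * r1**4) / det
        b_c = (p2 * r1**2 - p1 * r2_**2) / det
        return 2.0 * a_c, 8.0 * b_c

    # -- residual ---------------------------------------------------------------
    def residual(self, psi: np.ndarray, omega: np.ndarray, nu: float) -> np.ndarray:
        nz, nr = self.nz, self.nr
        a, b, r = self.a, self.b, self.r2
        Rh = self.Rh[:, None]

        psi_eta = self.deta(psi)
        psi_ee = self.detaeta(psi)
        psi_xx = self.dxixi(psi)
        psi_xe = self.deta(self.dxi(psi))

        om_eta = self.deta(omega)
        om_ee = self.detaeta(omega)
        om_xx = self.dxixi(omega)
        om_xe = self.deta(self.dxi(omega))

        u_z, u_r = self.velocities(psi)

        with np.errstate(divide="ignore", invalid="ignore"):
            # streamfunction equation: E²ψ + rω = 0
            lap_psi = (psi_xx - 2.0 * a * psi_xe + a**2 * psi_ee + b * psi_eta
                       + psi_ee / Rh**2 - psi_eta / (Rh * r))
            R_psi = lap_psi + r * omega

            # vorticity transport
            Uxi = u_z
            Ueta = u_r / Rh - a * u_z
            om_xi_up = self.dxi_upwind(omega, Uxi)
            om_eta_up = self.deta_upwind(omega, Ueta)
            adv = Uxi * om_xi_up + Ueta * om_eta_up - u_r * omega / r
            diff = (om_xx - 2.0 * a * om_xe + a**2 * om_ee + b * om_eta
                    + om_ee / Rh**2 + om_eta / (Rh * r) - omega / r**2)
            R_om = -adv + nu * diff

        # ---- boundary residuals override the interior expressions ----
        # outlet: streamwise-invariant (one-sided first derivative = 0)
        oc = self.out_c
        R_psi[-1] = oc[0] * psi[-3] + oc[1] * psi[-2] + oc[2] * psi[-1]
        R_om[-1] = oc[0] * omega[-3] + oc[1] * omega[-2] + oc[2] * omega[-1]
        # wall: Dirichlet ψ; vorticity from the no-slip condition (Thom)
        R_psi[:, -1] = psi[:, -1] - 0.5
        omega_wall = 2.0 * (psi[:, -1] - psi[:, -2]) / (self.Rh * self.dn_wall**2)
        R_om[:, -1] = omega[:, -1] - omega_wall
        # axis: ψ = 0, ω = 0
        R_psi[:, 0] = psi[:, 0]
        R_om[:, 0] = omega[:, 0]
        # inlet: prescribed parabolic profile
        R_psi[0] = psi[0] - self.inlet_psi()
        R_om[0] = omega[0] - self.inlet_omega()

        return np.concatenate([R_psi.ravel(), R_om.ravel()])

    # -- Jacobian sparsity + coloring -------------------------------------------
    _OFFSETS = {
        # (row_field, col_field): iterable of (di, dj)
        (0, 0): [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
                + [(-2, 0), (2, 0), (0, -2), (0, 2)],
        (0, 1): [(0, 0)],
        (1, 1): [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
                + [(-2, 0), (2, 0), (0, -2), (0, 2)],
        (1, 0): [(0, 0), (-1, 0), (1, 0), (0, -1), (0, 1), (-2, 0), (0, -2),
                 (-1, -1), (-1, 1), (1, -1), (1, 1)],
    }
    # the (1, 0) block covers the velocity dependence of the advection terms
    # and the wall (Thom) vorticity row, which references ψ one node off-wall

    def _build_jacobian_pattern(self) -> None:
        nz, nr, n = self.nz, self.nr, self.n
        I, J = np.meshgrid(np.arange(nz), np.arange(nr), indexing="ij")
        rows_list, cols_list = [], []
        for (fr, fc), offs in self._OFFSETS.items():
            for (di, dj) in offs:
                ii, jj = I + di, J + dj
                ok = (ii >= 0) & (ii < nz) & (jj >= 0) & (jj < nr)
                rows = (fr * n + (I * nr + J))[ok]
                cols = (fc * n + (ii * nr + jj))[ok]
                rows_list.append(rows.ravel())
                cols_list.append(cols.ravel())
        self.jac_rows = np.concatenate(rows_list)
        self.jac_cols = np.concatenate(cols_list)
        k = self.N_COLORS_AXIS
        ci = (self.jac_cols % n) // nr % k
        cj = (self.jac_cols % n) % nr % k
        cf = self.jac_cols // n
        self.jac_col_color = (ci * k + cj) * 2 + cf
        col_i = (np.arange(2 * n) % n) // nr % k
        col_j = (np.arange(2 * n) % n) % nr % k
        col_f = np.arange(2 * n) // n
        self.col_colors = (col_i * k + col_j) * 2 + col_f
        self.n_colors = 2 * k * k

    def jacobian(self, psi: np.ndarray, omega: np.ndarray, nu: float,
                 F0: np.ndarray) -> sparse.csc_matrix:
        n = self.n
        x = np.concatenate([psi.ravel(), omega.ravel()])
        delta = 1e-7 * (1.0 + np.abs(x))
        dR = np.empty((self.n_colors, 2 * n))
        for c in range(self.n_colors):
            mask = self.col_colors == c
            xp = x.copy()
            xp[mask] += delta[mask]
            Fp = self.residual(xp[:n].reshape(self.nz, self.nr),
                               xp[n:].reshape(self.nz, self.nr), nu)
            dR[c] = Fp - F0
        vals = dR[self.jac_col_color, self.jac_rows] / delta[self.jac_cols]
        J = sparse.coo_matrix((vals, (self.jac_rows, self.jac_cols)),
                              shape=(2 * n, 2 * n))
        return J.tocsc()

    # -- residual scale for the convergence criterion ----------------------------
    def residual_scale(self, psi: np.ndarray, omega: np.ndarray, nu: float) -> float:
        """Typical magnitude of the equation terms, used to scale residuals."""
        u_z, _ = self.velocities(psi)
        adv_mag = np.abs(u_z * self.dxi(omega))
        lap_mag = (np.abs(self.detaeta(psi)) / self.Rh[:, None] ** 2
                   + np.abs(self.r2 * omega))
        s = 0.5 * (np.sqrt(np.mean(adv_mag[1:-1, 1:-1] ** 2))
                   + np.sqrt(np.mean(lap_mag[1:-1, 1:-1] ** 2)))
        return max(float(s), 1.0)


# ---------------------------------------------------------------------------
# nonlinear solve
# ---------------------------------------------------------------------------

def _newton_solve(disc: _Discretization, nu: float, psi0, omega0,
                  settings: SolverSettings) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Damped Newton with pseudo-transient continuation (SER time stepping)."""
    n = disc.n
    psi, omega = psi0.copy(), omega0.copy()
    F = disc.residual(psi, omega, nu)
    scale = disc.residual_scale(psi, omega, nu)
    res0 = res = float(np.sqrt(np.mean(F**2))) / scale
    dt = settings.ptc_dt0
    target = settings.residual_target

    # pseudo-time mass term applies to the transport (vorticity) rows only
    ptc_diag = np.zeros(2 * n)
    interior = np.zeros((disc.nz, disc.nr), dtype=bool)
    interior[1:-1, 1:-1] = True
    ptc_diag[n:] = interior.ravel()

    it = 0
    history = [res]
    while res > target and it < settings.max_iterations:
        # stagnation guard: let the caller fall back to a fresh start early
        if len(history) > 12 and res > 0.5 * history[-12]:
            break
        use_ptc = res > 1e-2
        J = disc.jacobian(psi, omega, nu, F)
        A = (J + sparse.diags(ptc_diag / dt)).tocsc() if use_ptc else J
        try:
            lu = splu(A)
        except RuntimeError as exc:  # singular factorisation
            raise SolverError(f"Jacobian factorisation failed: {exc}") from exc
        dx = lu.solve(-F)
        lam = 1.0
        accepted = False
        for _ in range(8):
            psi_t = psi + lam * dx[:n].reshape(disc.nz, disc.nr)
            om_t = omega + lam * dx[n:].reshape(disc.nz, disc.nr)
            F_t = disc.residual(psi_t, om_t, nu)
            with np.errstate(over="ignore", invalid="ignore"):
                res_t = float(np.sqrt(np.mean(F_t**2))) / scale
            if np.isfinite(res_t) and res_t < (1.0 - 1e-4 * lam) * res:
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            # stuck: shrink the pseudo-time step and rebuild the system
            dt = max(dt * 0.2, 1e-3)
            history.append(res)
            it += 1
            continue
        if use_ptc:
            # switched-evolution relaxation: grow dt as the residual falls
            dt = min(dt * max(res / max(res_t, 1e-30), 1.5), 1e12)
        psi, omega, F, res = psi_t, om_t, F_t, res_t
        history.append(res)
        it += 1
    return psi, omega, res, it


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def reynolds_number(g: VesselGeometry, f: FluidProperties, Q_mL_min: float) -> float:
    """Reynolds number ρVD/μ at the minimal-diameter (stenosis) station.

    V is the mean velocity Q/A over the circular cross-section at the
    location of minimum diameter, D that station's diameter.
    """
    if Q_mL_min < 0:
        raise ValueError("Q must be non-negative")
    _, d_min_mm = g.min_diameter()
    D = d_min_mm * 1e-3
    A = math.pi * (D / 2.0) ** 2
    V = Q_mL_min * ML_MIN_M3_S / A
    return f.density_kg_m3 * V * D / f.viscosity_Pa_s


def reynolds_regime(re: float, threshold: float = RE_PHYSIOLOGICAL) -> str:
    """Classify a stenosis Reynolds number against the laminar threshold."""
    return "physiological" if re < threshold else "supra-physiological"


def reduced_order_dp(g: VesselGeometry, f: FluidProperties, Q_mL_min: float) -> float:
    """Fast reduced-order pressure drop estimate in mmHg.

    Sum of the fully developed viscous loss (8μQ/π)·∫ds/R⁴ and a
    Borda–Carnot expansion loss (ρQ²/2)·(1/A_min − 1/A_out)². This is an
    approximation used to seed and sanity-check the full solver — never a
    substitute for it in reported outputs.
    """
    if Q_mL_min < 0:
        raise ValueError("Q must be non-negative")
    Q = Q_mL_min * ML_MIN_M3_S
    s0, s1 = g.inlet_plane_mm, g.outlet_plane_mm
    s = np.linspace(s0, s1, 4000)
    R = g.radius_at(s) * 1e-3
    visc = 8.0 * f.viscosity_Pa_s * Q / math.pi * np.trapezoid(1.0 / R**4, s * 1e-3)
    mask = (g.arclength_mm >= s0) & (g.arclength_mm <= s1)
    R_seg = g.radius_mm[mask] * 1e-3
    A_min = math.pi * R_seg.min() ** 2
    A_out = math.pi * R_seg[-1] ** 2
    inert = 0.5 * f.density_kg_m3 * Q**2 * (1.0 / A_min - 1.0 / A_out) ** 2
    return float((visc + inert) / MMHG_PA)


class FlowModel:
    """Pressure–flow model of one vessel: forward and inverse steady solves.

    Owns the mesh, the discrete operators and a cache of converged states,
    so repeated solves (flow sweeps, waveform inversion, root-finding) warm
    start from the nearest previously solved flow. Deterministic: identical
    inputs and settings produce identical outputs.
    """

    def __init__(self, geometry: VesselGeometry, fluid: FluidProperties | None = None,
                 settings: SolverSettings | None = None):
        self.geometry = geometry
        self.fluid = fluid or FluidProperties.blood()
        self.settings = settings or SolverSettings()
        self._disc: dict = {}
        self._cache: dict = {}  # resolution -> list[(Re, psi, omega)]
        self._solved: dict = {}  # (resolution, round(Q, 9)) -> FlowSolution
        self._pairs: dict = {}   # resolution -> {Q: dP} of converged solves

    # -- internals -------------------------------------------------------------
    def _resolution_key(self, resolution):
        res = resolution if resolution is not None else self.settings.mesh_resolution
        return res if isinstance(res, str) else tuple(res)

    def discretization(self, resolution=None) -> _Discretization:
        key = self._resolution_key(resolution)
        if key not in self._disc:
            mesh = mesh_generate(self.geometry, key)
            self._disc[key] = _Discretization(mesh, self.settings)
        return self._disc[key]

    def _re_ref(self, Q_mL_min: float, disc: _Discretization) -> float:
        U = Q_mL_min * ML_MIN_M3_S / (math.pi * disc.R_ref_m**2)
        return self.fluid.density_kg_m3 * U * disc.R_ref_m / self.fluid.viscosity_Pa_s

    def _attempt_nondim(self, disc, Re: float, psi0, omega0, re_start: float):
        """Continuation in Reynolds number from a given starting state."""
        steps = [Re]
        if Re > 1.5 * re_start and Re > 100.0:
            nstep = int(np.ceil(math.log(Re / max(re_start, 50.0)) / math.log(2.0)))
            steps = list(np.geomspace(max(re_start, 50.0), Re, nstep + 1)[1:])
        psi, omega = psi0, omega0
        res, its_total = np.inf, 0
        for re_k in steps:
            psi, omega, res, its = _newton_solve(disc, 1.0 / re_k, psi, omega,
                                                 self.settings)
            its_total += its
            if res > self.settings.residual_target:
                raise SolverError(
                    f"steady solve did not converge (Re={re_k:.0f}, scaled "
                    f"residual {res:.2e} after {its} iterations)")
        return psi, omega, res, its_total

    def _solve_nondim(self, disc, key, Re: float):
        cache = self._cache.setdefault(key, [])
        # prefer the closest converged state from *below* in Re: growing a
        # recirculation region under increasing Re continues far more easily
        # than shrinking one, and a cold start handles the decreasing case
        below = [c for c in cache if c[0] <= 1.05 * Re]
        if below:
            nearest = max(below, key=lambda c: c[0])
        elif cache:
            nearest = min(cache, key=lambda c: c[0])
        else:
            nearest = None
        attempts = []
        if nearest is not None:
            attempts.append((nearest[1], nearest[2], nearest[0]))
        psi_cold, omega_cold = disc.initial_guess()
        attempts.append((psi_cold, omega_cold, min(Re, 50.0)))
        last_err: SolverError | None = None
        for psi0, omega0, re_start in attempts:
            try:
                psi, omega, res, its = self._attempt_nondim(disc, Re, psi0,
                                                            omega0, re_start)
                break
            except SolverError as err:
                last_err = err
        else:
            raise last_err
        cache.append((Re, psi.copy(), omega.copy()))
        if len(cache) > 12:  # keep the cache bounded
            cache.pop(0)
        return psi, omega, res, its

    def _pressure_drop(self, disc, psi, omega, Re) -> tuple[float, np.ndarray]:
        """Axis-integrated nondimensional pressure; returns (ΔP*, p*(ξ)).

        On the symmetry axis the axial momentum balance reduces to
        p_z = −ρ·u₀·u₀′ − 2μ·(ω/r)|axis: the viscous term follows from
        u_rr|axis = −½u₀″ − (ω/r)|axis (continuity plus the vorticity
        definition), which cancels the fragile second derivatives of u and
        leaves only the well-conditioned near-axis slope of the solved
        vorticity field.
        """
        u0, _ = disc._axis_fit(psi)
        # (ω/r) extrapolated to the axis from the first two off-axis nodes
        r1, r2_ = disc.r2[:, 1], disc.r2[:, 2]
        w1, w2 = omega[:, 1] / r1, omega[:, 2] / r2_
        w_axis = (w1 * r2_**2 - w2 * r1**2) / (r2_**2 - r1**2)
        xi = disc.xi
        du = np.gradient(u0, xi)
        p_z = -u0 * du - (2.0 / Re) * w_axis
        p = np.concatenate([[0.0], cumulative_trapezoid(p_z, xi)])
        p_in = float(np.interp(disc.inlet_plane_idx, xi, p))
        p_out = float(np.interp(disc.outlet_plane_idx, xi, p))
        return p_in - p_out, p - p_out

    # -- public API --------------------------------------------------------------
    def forward(self, Q_mL_min: float, resolution=None) -> FlowSolution:
        """Solve at imposed flow; returns the solution with ΔP between planes."""
        if Q_mL_min < 0:
            raise ValueError("Q must be non-negative")
        key = self._resolution_key(resolution)
        memo_key = (key, round(float(Q_mL_min), 9))
        if memo_key in self._solved:
            return self._solved[memo_key]
        disc = self.discretization(key)
        warnings: list[str] = []
        re_sten = reynolds_number(self.geometry, self.fluid, Q_mL_min)
        if Q_mL_min == 0.0:
            zeros = np.zeros((disc.nz, disc.nr))
            sol = FlowSolution(
                Q_mL_min=0.0, dP_mmHg=0.0, residual=0.0, converged=True,
                Re_stenosis=0.0, mesh=disc.mesh, psi=zeros, omega=zeros.copy(),
                u_z_m_s=zeros.copy(), u_r_m_s=zeros.copy(),
                p_axis_mmHg=np.zeros(disc.nz))
            self._solved[memo_key] = sol
            return sol
        if re_sten > RE_SUPERCRITICAL:
            warnings.append(
                f"stenosis Reynolds number {re_sten:.0f} exceeds {RE_SUPERCRITICAL:.0f}; "
                "the laminar steady model is outside its validity range")
        Re = self._re_ref(Q_mL_min, disc)
        psi, omega, res, its = self._solve_nondim(disc, key, Re)
        dp_star, p_star = self._pressure_drop(disc, psi, omega, Re)
        U_ref = Q_mL_min * ML_MIN_M3_S / (math.pi * disc.R_ref_m**2)
        dyn = self.fluid.density_kg_m3 * U_ref**2
        u_z, u_r = disc.velocities(psi)
        sol = FlowSolution(
            Q_mL_min=float(Q_mL_min),
            dP_mmHg=float(dp_star * dyn / MMHG_PA),
            residual=res, converged=True, Re_stenosis=re_sten,
            mesh=disc.mesh,
            psi=psi * U_ref * disc.R_ref_m**2,
            omega=omega * U_ref / disc.R_ref_m,
            u_z_m_s=u_z * U_ref, u_r_m_s=u_r * U_ref,
            p_axis_mmHg=p_star * dyn / MMHG_PA,
            iterations=its, warnings=tuple(warnings))
        self._solved[memo_key] = sol
        self._pairs.setdefault(key, {})[sol.Q_mL_min] = sol.dP_mmHg
        return sol

    def _flow_tolerance(self, Q: float) -> float:
        return max(self.settings.flow_tol_mL_min, self.settings.flow_tol_rel * abs(Q))

    def invert(self, dP_mmHg: float, resolution=None) -> FlowSolution:
        """Recover the flow that reproduces a measured pressure drop (Q_CFD).

        ΔP(Q) is strictly increasing for Q > 0 on a fixed geometry, so the
        root is unique; it is found by a bracketed secant iteration in
        log–log space, seeded by the reduced-order loss model.
        """
        if dP_mmHg < 0:
            raise ValueError("pressure drop must be non-negative")
        if dP_mmHg == 0.0:
            return self.forward(0.0, resolution)

        key = self._resolution_key(resolution)
        evals: dict[float, float] = dict(self._pairs.get(key, {}))

        def dp_at(q: float) -> float:
            v = self.forward(q, resolution).dP_mmHg
            evals[q] = v
            return v

        # bracket the unique root of the monotone response ΔP(Q), reusing
        # every previously solved (Q, ΔP) pair on this mesh
        below = [q for q, v in evals.items() if v <= dP_mmHg]
        above = [q for q, v in evals.items() if v >= dP_mmHg]
        q_lo = max(below) if below else None
        q_hi = min(above) if above else None
        if q_lo is None and q_hi is None:
            # cold start: seed from the reduced-order model a·Q + b·Q² = ΔP
            g, f = self.geometry, self.fluid
            a_lin = reduced_order_dp(g, f, 1.0)
            b_quad = max(reduced_order_dp(g, f, 100.0) - 100.0 * a_lin,
                         0.0) / 100.0**2
            if b_quad > 0:
                q0 = (-a_lin + math.sqrt(a_lin**2 + 4.0 * b_quad * dP_mmHg)) \
                    / (2.0 * b_quad)
            else:
                q0 = dP_mmHg / a_lin
            q0 = max(q0, 1e-3)
            if dp_at(q0) <= dP_mmHg:
                q_lo = q0
            else:
                q_hi = q0
        n_ev = 0
        while q_hi is None:
            # extrapolate upward along the local log-log slope
            qs = sorted(q for q in evals if evals[q] > 0)
            if len(qs) >= 2 and evals[qs[-1]] > evals[qs[-2]] > 0:
                m_loc = ((math.log(evals[qs[-1]]) - math.log(evals[qs[-2]]))
                         / (math.log(qs[-1]) - math.log(qs[-2])))
                m_loc = min(max(m_loc, 1.0), 2.5)
                q_try = qs[-1] * (dP_mmHg / evals[qs[-1]]) ** (1.0 / m_loc) * 1.1
            else:
                q_try = max(q_lo, 1e-3) * 1.7
            v = dp_at(q_try)
            if v >= dP_mmHg:
                q_hi = q_try
            else:
                q_lo = q_try
            n_ev += 1
            if n_ev > 40:
                raise SolverError(
                    f"could not bracket the flow for dP={dP_mmHg:.3g} mmHg "
                    f"(reached Q={q_try:.3g} mL/min)")
        while q_lo is None:
            q_try = q_hi / 1.7
            if dp_at(q_try) <= dP_mmHg:
                q_lo = q_try
            else:
                q_hi = q_try
            n_ev += 1
            if q_try < 1e-4 or n_ev > 60:
                q_lo = 0.0
                evals[0.0] = 0.0
                break

        # bracketed secant in log-log space (bisection-safeguarded)
        for _ in range(60):
            v_lo, v_hi = evals[q_lo], evals[q_hi]
            if abs(v_lo - dP_mmHg) < 1e-12:
                q_best = q_lo
                break
            tol = self._flow_tolerance(q_hi)
            slope = (v_hi - v_lo) / (q_hi - q_lo) if q_hi > q_lo else 0.0
            close_enough = min(abs(v_lo - dP_mmHg), abs(v_hi - dP_mmHg)) \
                < 0.5 * slope * tol
            if q_hi - q_lo < tol or close_enough:
                q_best = min((q for q in (q_lo, q_hi)),
                             key=lambda q: abs(evals[q] - dP_mmHg))
                break
            if q_lo > 0 and v_lo > 0:
                t = ((math.log(dP_mmHg) - math.log(v_lo))
                     / (math.log(v_hi) - math.log(v_lo)))
                q_new = math.exp(math.log(q_lo) + t * (math.log(q_hi) - math.log(q_lo)))
            else:
                q_new = q_hi * dP_mmHg / v_hi  # low-flow limit is linear
            # keep strictly inside the bracket, fall back to bisection
            gap = q_hi - q_lo
            if not (q_lo + 0.02 * gap <= q_new <= q_hi - 0.02 * gap):
                q_new = 0.5 * (q_lo + q_hi)
            v_new = dp_at(q_new)
            if v_new < dP_mmHg:
                q_lo = q_new
            else:
                q_hi = q_new
        else:
            raise SolverError("flow inversion did not converge within 60 evaluations")
        return self.forward(q_best, resolution)


def solve_forward(g: VesselGeometry, f: FluidProperties, Q_mL_min: float,
                  settings: SolverSettings | None = None) -> FlowSolution:
    """Impose flow Q, compute the translesional pressure drop (one-shot API)."""
    return FlowModel(g, f, settings).forward(Q_mL_min)


def solve_flow_from_pressure(g: VesselGeometry, f: FluidProperties, dP_mmHg: float,
                             settings: SolverSettings | None = None) -> FlowSolution:
    """Impose the measured pressure drop, recover the absolute flow Q_CFD."""
    return FlowModel(g, f, settings).invert(dP_mmHg)


def solve_pulsatile_quasi_steady(g: VesselGeometry, f: FluidProperties,
                                 w: PressureWaveform,
                                 settings: SolverSettings | None = None,
                                 model: FlowModel | None = None):
    """Quasi-steady pulsatile flow: invert the steady model per waveform sample.

    Each time sample's gradient Pa(t) − Pd(t) is inverted for Q(t);
    negative gradients are clipped to zero and flagged. Returns
    ``(Q_mean_mL_min, time_s, Q_mL_min_series, flags)`` where the mean is
    the trapezoidal time average over the largest whole number of periods
    (the full span when no period is given).
    """
    if model is None:
        model = FlowModel(g, f, settings)
    dp = w.pa_mmHg - w.pd_mmHg
    flags: list[str] = []
    if np.any(dp < 0):
        flags.append("negative-gradient-samples-clipped")
        dp = np.clip(dp, 0.0, None)
    if not w.covers_full_period():
        raise ValueError("waveform does not cover one full period")
    Q = np.array([model.invert(float(d)).Q_mL_min for d in dp])
    t = w.time_s
    if w.period_s is not None:
        n_per = int(np.floor((t[-1] - t[0]) / w.period_s + 1e-9))
        t_end = t[0] + n_per * w.period_s
        mask = t <= t_end + 1e-12
        tt, qq = t[mask], Q[mask]
    else:
        tt, qq = t, Q
    q_mean = float(np.trapezoid(qq, tt) / (tt[-1] - tt[0]))
    return q_mean, t, Q, flags


@dataclass(frozen=True)
class MeshConvergenceReport:
    """Grid-refinement study of the inverse solve at fixed pressure drop."""

    levels: tuple
    Q_mL_min: tuple
    rel_delta_fine_standard: float
    passed: bool


def mesh_convergence_check(g: VesselGeometry, f: FluidProperties, dP_mmHg: float,
                           settings: SolverSettings | None = None,
                           levels=("coarse", "standard", "fine"),
                           tol: float = 0.005) -> MeshConvergenceReport:
    """Solve the inverse problem at successive mesh levels and compare flows.

    Passes when the two finest levels agree to within ``tol`` (relative).
    """
    if len(levels) < 2:
        raise ValueError("mesh convergence needs at least 2 resolution levels")
    model = FlowModel(g, f, settings)
    qs = tuple(model.invert(dP_mmHg, resolution=lv).Q_mL_min for lv in levels)
    rel = abs(qs[-1] - qs[-2]) / abs(qs[-1])
    return MeshConvergenceReport(levels=tuple(levels), Q_mL_min=qs,
                                 rel_delta_fine_standard=float(rel),
                                 passed=bool(rel < tol))
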