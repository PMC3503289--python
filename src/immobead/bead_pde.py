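"""Reaction-diffusion of substrate and product inside a spherical bead.

The dimensionless steady problem on the bead's axisymmetric quarter
cross-section {(r, z): r^2 + z^2 <= 1, r >= 0, z >= 0} is

    (1/r) d/dr (r dCs/dr) + d2Cs/dz2 = 9 phi^2 Cs / (1 + beta Cs),

with Cs = 1 on the curved surface and zero normal derivative on the axis
(r = 0) and midplane (z = 0). The transient counterpart adds dCs/dtau on
the left, and the product obeys the same diffusion operator scaled by
lambda = Dp/Ds with the reaction term as a source:

    dCp/dtau = lambda * Laplacian(Cp) + 9 phi^2 Cs / (1 + beta Cs),

with Cp = 0 on the surface. At lambda = 1 the sum W = Cs + Cp satisfies a
pure diffusion equation with W = 1 on the boundary and therefore relaxes
to W == 1 — a built-in conservation check.

Discretization
--------------
* 1-D radially symmetric solver: second-order finite differences on a
  uniform grid in rho, with the symmetry-limit stencil 6(C1-C0)/h^2 at the
  center.
* 2-D axisymmetric solver: linear finite elements on a polar-structured
  triangulation of the quarter disc, with the cylindrical weight r in the
  stiffness integrals. The reaction/mass term uses row-sum lumping of the
  exact weighted mass matrix, m_i = sum_T A_T (r_i + 3 rbar_T) / 12; this
  keeps a positive lumped weight on the symmetry axis, where vertex
  quadrature would annihilate the reaction term and wreck accuracy near
  the pole.

Both nonlinear solves run Picard iteration with the Michaelis-Menten
denominator frozen (an M-matrix linearization that respects the maximum
principle), then finish with damped Newton for machine-level residuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.integrate import simpson
from scipy.linalg import solve_banded
from scipy.sparse.linalg import splu

__all__ = [
    "AxiMesh",
    "BeadField",
    "EffectivenessResult",
    "SolverError",
    "steady_sphere_1d",
    "steady_axisymmetric",
    "transient_solve",
    "effectiveness_factor",
    "extract_radial_profile",
    "write_field_csv",
    "write_profile_csv",
]

MESH_TOL = 1e-9
MIN_RESOLUTION = 16
STEADY_TOL_1D = 1e-10
STEADY_TOL_2D = 1e-8
MAX_PICARD = 500
PICARD_RELAX = 0.8


class SolverError(RuntimeError):
    """Nonlinear or time-stepping failure, carrying the last residual."""


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------


@dataclass
class AxiMesh:
    """Polar-structured triangulation of the quarter cross-section.

    Nodes sit on rings rho_j = j/n (j = 0..n) at angles theta_k uniformly
    spaced in [0, pi/2] (theta measured from the z-axis), plus a single
    center node; triangles fan from the center and fill the ring strips.
    ``n`` is the resolution parameter (nodes per unit length along a
    radius); the angular count tracks n so elements stay near-isotropic.
    """

    n: int
    nodes: np.ndarray = field(repr=False)  # (N, 2) columns r_dot, z_dot
    triangles: np.ndarray = field(repr=False)  # (T, 3) int
    surface: np.ndarray = field(repr=False)  # bool mask, rho == 1
    axis: np.ndarray = field(repr=False)  # bool mask, r_dot == 0
    midplane: np.ndarray = field(repr=False)  # bool mask, z_dot == 0
    ntheta: int = 0

    @classmethod
    def build(cls, n: int) -> "AxiMesh":
        if n < MIN_RESOLUTION:
            raise ValueError(f"mesh resolution n must be >= {MIN_RESOLUTION}, got {n}")
        ntheta = max(4, int(math.ceil(n * math.pi / 2)))
        theta = np.linspace(0.0, math.pi / 2, ntheta + 1)
        sin_t, cos_t = np.sin(theta), np.cos(theta)
        pts = [np.zeros((1, 2))]
        for j in range(1, n + 1):
            rho = j / n
            ring = np.column_stack([rho * sin_t, rho * cos_t])  # (r, z)
            ring[0, 0] = 0.0  # exact axis
            ring[-1, 1] = 0.0  # exact midplane
            pts.append(ring)
        nodes = np.vstack(pts)
        ring_start = lambda j: 1 + (j - 1) * (ntheta + 1)
        tris = []
        s1 = ring_start(1)
        for k in range(ntheta):
            tris.append((0, s1 + k, s1 + k + 1))
        for j in range(1, n):
            a, b = ring_start(j), ring_start(j + 1)
            for k in range(ntheta):
                tris.append((a + k, b + k, b + k + 1))
                tris.append((a + k, b + k + 1, a + k + 1))
        triangles = np.asarray(tris, dtype=np.int64)
        nn = len(nodes)
        surface = np.zeros(nn, bool)
        surface[ring_start(n):] = True
        axis = np.abs(nodes[:, 0]) < MESH_TOL
        midplane = np.abs(nodes[:, 1]) < MESH_TOL
        mesh = cls(
            n=n,
            nodes=nodes,
            triangles=triangles,
            surface=surface,
            axis=axis,
            midplane=midplane,
            ntheta=ntheta,
        )
        rho2 = np.einsum("ij,ij->i", nodes, nodes)
        assert np.all(rho2 <= 1.0 + MESH_TOL)
        assert np.all(np.abs(rho2[surface] - 1.0) < MESH_TOL)
        return mesh

    @cached_property
    def _operators(self) -> tuple[sp.csr_matrix, np.ndarray]:
        """Weighted P1 stiffness matrix and row-sum lumped mass vector."""
        pts, tris = self.nodes, self.triangles
        r = pts[:, 0]
        i0, i1, i2 = tris[:, 0], tris[:, 1], tris[:, 2]
        x0, x1, x2 = pts[i0, 0], pts[i1, 0], pts[i2, 0]
        y0, y1, y2 = pts[i0, 1], pts[i1, 1], pts[i2, 1]
        det = (x1 - x0) * (y2 - y0) - (x2 - x0) * (y1 - y0)
        area = 0.5 * np.abs(det)
        rbar = (r[i0] + r[i1] + r[i2]) / 3.0
        b = np.stack([y1 - y2, y2 - y0, y0 - y1], axis=1) / det[:, None]
        c = np.stack([x2 - x1, x0 - x2, x1 - x0], axis=1) / det[:, None]
        rows, cols, vals = [], [], []
        for a_ in range(3):
            for b_ in range(3):
                rows.append(tris[:, a_])
                cols.append(tris[:, b_])
                vals.append(rbar * area * (b[:, a_] * b[:, b_] + c[:, a_] * c[:, b_]))
        nn = len(pts)
        stiffness = sp.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(nn, nn),
        )
        lumped = np.zeros(nn)
        for a_ in range(3):
            np.add.at(lumped, tris[:, a_], area * (r[tris[:, a_]] + 3.0 * rbar) / 12.0)
        return stiffness, lumped

    @property
    def stiffness(self) -> sp.csr_matrix:
        return self._operators[0]

    @property
    def lumped_mass(self) -> np.ndarray:
        return self._operators[1]

    def __len__(self) -> int:
        return len(self.nodes)


# ---------------------------------------------------------------------------
# fields
# ---------------------------------------------------------------------------


@dataclass
class BeadField:
    """Discrete concentration field(s), on a 2-D mesh or a 1-D radial grid."""

    phi: float
    beta: float
    cs: np.ndarray
    cp: np.ndarray | None = None
    lam: float = 1.0
    mesh: AxiMesh | None = None
    rho: np.ndarray | None = None
    tau: float | None = None
    converged: bool = False
    residual_norm: float = math.nan

    def __post_init__(self) -> None:
        if (self.mesh is None) == (self.rho is None):
            raise ValueError("exactly one of mesh (2-D) or rho (1-D) must be set")
        lo, hi = float(np.min(self.cs)), float(np.max(self.cs))
        if lo < -1e-9 or hi > 1.0 + 1e-9:
            raise ValueError(f"Cs violates the maximum principle: range [{lo}, {hi}]")

    @property
    def center_concentration(self) -> float:
        """Cs at the bead center (node rho = 0)."""
        return float(self.cs[0])


@dataclass(frozen=True)
class EffectivenessResult:
    """Effectiveness factor eta plus the operating point it belongs to.

    eta is the volume-averaged reaction rate over the rate at surface
    conditions; eta -> 1 means kinetic control, small eta means the bead
    core is starved of substrate (diffusion control).
    """

    eta: float
    phi: float
    beta: float
    center_concentration: float

    def __post_init__(self) -> None:
        if not 0.0 < self.eta <= 1.0:
            raise ValueError(f"eta must lie in (0, 1], got {self.eta}")


# ---------------------------------------------------------------------------
# nonlinear steady solvers
# ---------------------------------------------------------------------------


def _source(c: np.ndarray, phi: float, beta: float) -> np.ndarray:
    return 9.0 * phi**2 * c / (1.0 + beta * c)


def _source_deriv(c: np.ndarray, phi: float, beta: float) -> np.ndarray:
    return 9.0 * phi**2 / (1.0 + beta * c) ** 2


def steady_sphere_1d(
    phi: float,
    beta: float,
    n_radial: int = 64,
    tol: float = STEADY_TOL_1D,
) -> BeadField:
    """Steady radial profile C(rho) for the radially symmetric problem.

    Solves (1/rho^2) d/drho (rho^2 dC/drho) = 9 phi^2 C/(1 + beta C) with
    C(1) = 1, C'(0) = 0 by second-order finite differences; Picard with the
    frozen MM denominator, then Newton to the requested residual.
    """
    if phi < 0 or beta < 0:
        raise ValueError("phi and beta must be nonnegative")
    if n_radial < MIN_RESOLUTION:
        raise ValueError(f"n_radial must be >= {MIN_RESOLUTION}, got {n_radial}")
    n = n_radial
    h = 1.0 / n
    rho = np.linspace(0.0, 1.0, n + 1)
    if phi == 0.0:
        return BeadField(
            phi=phi, beta=beta, cs=np.ones(n + 1), rho=rho,
            converged=True, residual_norm=0.0,
        )

    # Tridiagonal Laplacian rows for unknowns i = 0..n-1 (C_n = 1 Dirichlet).
    lo = np.zeros(n)
    di = np.zeros(n)
    up = np.zeros(n)
    di[0], up[0] = -6.0 / h**2, 6.0 / h**2
    idx = np.arange(1, n)
    lo[idx] = 1.0 / h**2 - 1.0 / (h * rho[idx])
    di[idx] = -2.0 / h**2
    up[idx] = 1.0 / h**2 + 1.0 / (h * rho[idx])
    bc = np.zeros(n)
    bc[n - 1] = (1.0 / h**2 + 1.0 / (h * rho[n - 1])) * 1.0  # C_n = 1

    def lap(cf: np.ndarray) -> np.ndarray:
        out = di * cf + bc
        out[:-1] += up[:-1] * cf[1:]
        out[1:] += lo[1:] * cf[:-1]
        return out

    def residual(cf: np.ndarray) -> np.ndarray:
        return lap(cf) - _source(cf, phi, beta)

    def banded(diag_extra: np.ndarray) -> np.ndarray:
        ab = np.zeros((3, n))
        ab[0, 1:] = up[:-1]
        ab[1, :] = di - diag_extra
        ab[2, :-1] = lo[1:]
        return ab

    c = np.ones(n)
    res = np.inf
    for it in range(MAX_PICARD):
        coeff = 9.0 * phi**2 / (1.0 + beta * c)
        c_new = solve_banded((1, 1), banded(coeff), -bc)
        c = c_new if it == 0 else PICARD_RELAX * c_new + (1 - PICARD_RELAX) * c
        res = float(np.max(np.abs(residual(c))))
        if res < max(tol, 1e-6) or (beta == 0.0 and it >= 1):
            break
    # Newton polish (quadratic convergence near the Picard iterate).
    for _ in range(50):
        r = residual(c)
        res = float(np.max(np.abs(r)))
        if res < tol:
            break
        delta = solve_banded((1, 1), banded(_source_deriv(c, phi, beta)), -r)
        step = 1.0
        for _ in range(30):
            trial = c + step * delta
            if np.max(np.abs(residual(trial))) < res:
                c = trial
                break
            step *= 0.5
        else:
            break
    res = float(np.max(np.abs(residual(c))))
    converged = res < tol
    if not converged:
        raise SolverError(
            f"1-D steady solve did not converge (phi={phi}, beta={beta}, "
            f"n={n}); last residual {res:.3e}"
        )
    cs = np.clip(np.append(c, 1.0), 0.0, 1.0)
    return BeadField(
        phi=phi, beta=beta, cs=cs, rho=rho, converged=True, residual_norm=res
    )


def _solve_dirichlet(
    mat: sp.spmatrix, rhs: np.ndarray
) -> np.ndarray:
    return splu(mat.tocsc()).solve(rhs)


def steady_axisymmetric(
    phi: float,
    beta: float,
    mesh: AxiMesh | None = None,
    n: int = 64,
    tol: float = STEADY_TOL_2D,
) -> BeadField:
    """Steady substrate field on the quarter cross-section (P1 FEM).

    Cs = 1 on the curved surface; the symmetry conditions on the axis and
    midplane are natural (do-nothing) boundaries of the weak form.
    """
    if phi < 0 or beta < 0:
        raise ValueError("phi and beta must be nonnegative")
    if mesh is None:
        mesh = AxiMesh.build(n)
    stiff, lumped = mesh.stiffness, mesh.lumped_mass
    free = ~mesh.surface
    nn = len(mesh)
    if phi == 0.0:
        return BeadField(
            phi=phi, beta=beta, cs=np.ones(nn), mesh=mesh,
            converged=True, residual_norm=0.0,
        )
    k_ff = stiff[free][:, free].tocsr()
    k_fs = stiff[free][:, ~free]
    bc = k_fs @ np.ones(int((~free).sum()))
    m_f = lumped[free]

    def residual(cf: np.ndarray) -> np.ndarray:
        return k_ff @ cf + bc + m_f * _source(cf, phi, beta)

    c = np.ones(int(free.sum()))
    res = np.inf
    for it in range(MAX_PICARD):
        coeff = 9.0 * phi**2 / (1.0 + beta * c)
        c_new = _solve_dirichlet(k_ff + sp.diags(m_f * coeff), -bc)
        c = c_new if it == 0 else PICARD_RELAX * c_new + (1 - PICARD_RELAX) * c
        res = float(np.max(np.abs(residual(c))))
        if res < max(tol, 1e-5) or (beta == 0.0 and it >= 1):
            break
    for _ in range(50):
        r = residual(c)
        res = float(np.max(np.abs(r)))
        if res < tol:
            break
        jac = k_ff + sp.diags(m_f * _source_deriv(c, phi, beta))
        delta = _solve_dirichlet(jac, -r)
        step = 1.0
        for _ in range(30):
            trial = c + step * delta
            if np.max(np.abs(residual(trial))) < res:
                c = trial
                break
            step *= 0.5
        else:
            break
    res = float(np.max(np.abs(residual(c))))
    if res >= tol:
        raise SolverError(
            f"2-D steady solve did not converge (phi={phi}, beta={beta}, "
            f"n={mesh.n}); last residual {res:.3e}"
        )
    cs = np.ones(nn)
    cs[free] = np.clip(c, 0.0, 1.0)
    return BeadField(
        phi=phi, beta=beta, cs=cs, mesh=mesh, converged=True, residual_norm=res
    )


# ---------------------------------------------------------------------------
# transient solver
# ---------------------------------------------------------------------------


def transient_solve(
    phi: float,
    beta: float,
    lam: float = 1.0,
    tau_end: float = 10.0,
    mesh: AxiMesh | None = None,
    n: int = 64,
    n_snapshots: int = 5,
    dt0: float = 1e-4,
    dt_growth: float = 1.25,
    dt_max: float = 0.25,
) -> list[BeadField]:
    """Integrate the coupled substrate/product transient to ``tau_end``.

    Backward Euler on the lumped-mass FEM system, with a geometrically
    growing step (the early dynamics are fast near the surface; the late
    approach to steady state tolerates large implicit steps, whose fixed
    point is exactly the discrete steady state). Within each step the MM
    source is resolved by Picard iteration; the product update uses the
    identical discrete source term, so at lambda = 1 the sum W = Cs + Cp
    obeys the exact discrete heat equation and relaxes to W == 1.

    Returns fields at ``n_snapshots`` times evenly spaced up to ``tau_end``
    (each snapshot taken at the first step boundary past its target time).
    """
    if tau_end <= 0:
        raise ValueError(f"tau_end must be positive, got {tau_end}")
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if phi < 0 or beta < 0:
        raise ValueError("phi and beta must be nonnegative")
    if mesh is None:
        mesh = AxiMesh.build(n)
    stiff, lumped = mesh.stiffness, mesh.lumped_mass
    free = ~mesh.surface
    nn = len(mesh)
    k_ff = stiff[free][:, free].tocsr()
    k_fs = stiff[free][:, ~free]
    ones_s = np.ones(int((~free).sum()))
    bc_s = k_fs @ ones_s  # substrate Dirichlet load (Cs = 1 on surface)
    m_f = lumped[free]

    cs = np.zeros(int(free.sum()))
    cp = np.zeros(int(free.sum()))
    snap_times = np.linspace(tau_end / n_snapshots, tau_end, n_snapshots)
    snaps: list[BeadField] = []
    tau = 0.0
    dt = dt0
    next_snap = 0
    max_steps = 100000
    for _ in range(max_steps):
        if tau >= tau_end or next_snap >= n_snapshots:
            break
        dt = min(dt, tau_end - tau)
        a_s = None
        cs_new = cs
        # Picard on the frozen MM denominator within the implicit step.
        for _ in range(60):
            coeff = 9.0 * phi**2 / (1.0 + beta * cs_new)
            mat = sp.diags(m_f / dt) + k_ff + sp.diags(m_f * coeff)
            rhs = m_f * cs / dt - bc_s
            nxt = _solve_dirichlet(mat, rhs)
            if np.max(np.abs(nxt - cs_new)) < 1e-12:
                cs_new = nxt
                a_s = coeff
                break
            cs_new = nxt
            a_s = coeff
        source = m_f * a_s * cs_new  # identical term enters the product update
        mat_p = sp.diags(m_f / dt) + lam * k_ff
        cp_new = _solve_dirichlet(mat_p, m_f * cp / dt + source)
        cs, cp = cs_new, cp_new
        tau += dt
        dt = min(dt * dt_growth, dt_max)
        while next_snap < n_snapshots and tau >= snap_times[next_snap] - 1e-12:
            cs_full = np.ones(nn)
            cs_full[free] = np.clip(cs, 0.0, 1.0)
            cp_full = np.zeros(nn)
            cp_full[free] = np.maximum(cp, 0.0)
            snaps.append(
                BeadField(
                    phi=phi, beta=beta, lam=lam, cs=cs_full, cp=cp_full,
                    mesh=mesh, tau=float(tau), converged=False,
                    residual_norm=math.nan,
                )
            )
            next_snap += 1
    if next_snap < n_snapshots:
        raise SolverError(
            f"transient integration stalled at tau={tau:.4g} before reaching "
            f"tau_end={tau_end}"
        )
    return snaps


# ---------------------------------------------------------------------------
# diagnostics and output
# ---------------------------------------------------------------------------


def effectiveness_factor(field: BeadField) -> EffectivenessResult:
    """Effectiveness factor of a converged steady field.

    eta = (1 + beta) * <Cs/(1 + beta Cs)> where <.> is the volume average
    over the bead — equivalently 3(1+beta) * int_0^1 Cs/(1+beta Cs) rho^2
    drho for a radial profile. The normalization is the rate at surface
    conditions (Cs = 1).
    """
    if not field.converged:
        raise ValueError("effectiveness factor requires a converged steady field")
    g = field.cs / (1.0 + field.beta * field.cs)
    if field.rho is not None:
        avg = 3.0 * simpson(g * field.rho**2, x=field.rho)
    else:
        w = field.mesh.lumped_mass
        avg = float(np.sum(w * g) / np.sum(w))
    eta = (1.0 + field.beta) * avg
    eta = min(eta, 1.0)
    return EffectivenessResult(
        eta=float(eta),
        phi=field.phi,
        beta=field.beta,
        center_concentration=field.center_concentration,
    )


def extract_radial_profile(
    field: BeadField, theta: float = math.pi / 4
) -> tuple[np.ndarray, np.ndarray]:
    """Nodal Cs along the mesh ray closest to angle ``theta`` from the z-axis.

    The polar-structured mesh places nodes on exact radii rho_j = j/n along
    every angular grid line, so the profile is read off nodal values with no
    interpolation error.
    """
    if field.mesh is None:
        return field.rho.copy(), field.cs.copy()
    mesh = field.mesh
    k = int(round(theta / (math.pi / 2) * mesh.ntheta))
    k = min(max(k, 0), mesh.ntheta)
    idx = [0] + [1 + (j - 1) * (mesh.ntheta + 1) + k for j in range(1, mesh.n + 1)]
    rho = np.arange(mesh.n + 1) / mesh.n
    return rho, field.cs[np.asarray(idx)]


def write_field_csv(field: BeadField, path) -> None:
    """2-D fields as ``r_dot,z_dot,Cs,Cp``; radial profiles as ``rho,Cs``."""
    if field.mesh is not None:
        data = {
            "r_dot": field.mesh.nodes[:, 0],
            "z_dot": field.mesh.nodes[:, 1],
            "Cs": field.cs,
            "Cp": field.cp if field.cp is not None else np.full(len(field.cs), np.nan),
        }
    else:
        data = {"rho": field.rho, "Cs": field.cs}
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.12g")


def write_profile_csv(rho: np.ndarray, cs: np.ndarray, path) -> None:
    pd.DataFrame({"rho": rho, "Cs": cs}).to_csv(path, index=False, float_format="%.12g")


def plot_field(field: BeadField, path, what: str = "Cs") -> None:
    """Render the full-disc reflected field as a color map (presentation
    convenience; requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if field.mesh is None:
        raise ValueError("plot_field needs a 2-D field")
    vals = field.cs if what == "Cs" else field.cp
    r, z = field.mesh.nodes[:, 0], field.mesh.nodes[:, 1]
    tri = field.mesh.triangles
    fig, ax = plt.subplots(figsize=(5, 5))
    for sr, sz in ((1, 1), (-1, 1), (1, -1), (-1, -1)):
        tc = ax.tricontourf(sr * r, sz * z, tri, vals, levels=41, cmap="jet",
                            vmin=0.0, vmax=1.0)
    fig.colorbar(tc, ax=ax, label=what)
    ax.set_aspect("equal")
    ax.set_xlabel("dimensionless radius")
    ax.set_ylabel("dimensionless z")
    ax.set_title(f"{what}  (phi={field.phi:.3g}, beta={field.beta:.3g})")
    fig.savefig(path, dpi=150)
    plt.close(fig)
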