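"""Numerical field-equation solvers used to validate the closed forms.

Everything in :mod:`vertigrow.model_core` is an analytic consequence of a
small set of field equations: a quasi-static reaction--diffusion balance for
the nutrient, a local volume-growth rate, a Darcy pressure closure, and a
kinematic condition moving the colony roof with the top-surface velocity.
This module solves those equations numerically on the rescaled column
z' = z/h in [0, 1], so that each closed form can be checked against an
independent discrete solution:

* :func:`solve_resource_bvp` -- finite-difference solution of
  d2R/dz2 = (alpha / (epsilon R*)) R with a clamped base and no-flux roof.
* :func:`solve_resource_transient` -- implicit time stepping of the full
  time-dependent resource equation, used to quantify how fast it relaxes to
  the quasi-static profile when the Péclet number is small.
* :func:`pressure_field` / :func:`velocity_field` -- double integration of
  the pressure Poisson equation and the Darcy velocity it induces.
* :func:`simulate_growth` -- the whole moving-boundary loop, stepping the
  colony height with the numerically computed top-surface velocity.

The moving boundary is handled entirely through the z' rescaling: the
quasi-static solves see a fixed unit domain and the height enters as a
coefficient.  The anti-circularity rule of the module is that the growth
field fed to the pressure solver always comes from the *numerically* solved
resource profile (g* = alpha R/R* - beta), never from the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_simpson
from scipy.linalg import solve_banded

from .model_core import (
    GrowthParams,
    NondimScales,
    ResourceProfile,
    TransportParams,
    characteristic_length,
    peclet,
)

__all__ = [
    "ColumnGrid",
    "FieldState",
    "PressureField",
    "SimulatedTrajectory",
    "solve_resource_bvp",
    "solve_resource_transient",
    "pressure_field",
    "velocity_field",
    "top_velocity",
    "simulate_growth",
]


@dataclass(frozen=True)
class ColumnGrid:
    """Uniform grid on the rescaled column z' = z/h in [0, 1]."""

    n_points: int = 256
    colony_height: float | None = None
    z_prime_nodes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_points < 8:
            raise ValueError(f"n_points must be >= 8, got {self.n_points}")
        object.__setattr__(
            self, "z_prime_nodes", np.linspace(0.0, 1.0, self.n_points)
        )

    @property
    def spacing(self) -> float:
        return 1.0 / (self.n_points - 1)


@dataclass(frozen=True)
class PressureField:
    """Pressure and its z'-gradient from the double integration.

    Keeping the analytically integrated gradient avoids re-differentiating
    the pressure numerically when the Darcy velocity is formed.
    """

    values: np.ndarray
    gradient: np.ndarray


@dataclass(frozen=True)
class FieldState:
    """Snapshot of the interior fields on the grid nodes."""

    resource: np.ndarray
    pressure: np.ndarray
    velocity: np.ndarray


@dataclass(frozen=True)
class SimulatedTrajectory:
    """Height history of a moving-boundary simulation."""

    times: np.ndarray
    heights: np.ndarray
    final_fields: FieldState

    def to_height_trajectory(self):
        from .trajectories import HeightTrajectory

        return HeightTrajectory(
            times=self.times, heights=self.heights, model_tag="active"
        )


# ---------------------------------------------------------------------------
# quasi-static resource boundary-value problem
# ---------------------------------------------------------------------------


def solve_resource_bvp(
    h: float,
    transport: TransportParams,
    alpha: float,
    grid: ColumnGrid,
    *,
    order: int = 2,
) -> ResourceProfile:
    """Discrete quasi-static nutrient profile in a colony of height ``h``.

    Solves d2R/dz2 = R / L^2 (L^2 = D_R epsilon R* / alpha) on z' in [0, 1]
    with R(0) = R* and a no-flux roof imposed through a symmetric ghost
    node.  ``order=2`` uses plain central differences (error ~ dz^2);
    ``order=4`` uses the Numerov stencil for y'' = k^2 y (error ~ dz^4),
    which the velocity pipeline needs to resolve tall columns accurately.
    The even symmetry of the true solution about z = h makes the ghost
    reflection exact, so the Neumann side does not degrade either order.
    """
    if not (h > 0):
        raise ValueError(f"h must be > 0, got {h}")
    if order not in (2, 4):
        raise ValueError("order must be 2 or 4")
    L = characteristic_length(transport, alpha)
    n = grid.n_points
    dz = grid.spacing
    s = (h * dz / L) ** 2  # (k * dz')^2 with k = h/L

    # rows 0..n-2 are the unknowns R_1..R_{n-1}; R_0 = R* is eliminated
    if order == 2:
        diag_main = -(2.0 + s)
        diag_off = 1.0
    else:
        diag_main = -(2.0 + 10.0 * s / 12.0)
        diag_off = 1.0 - s / 12.0

    m = n - 1
    ab = np.zeros((3, m))
    ab[0, 1:] = diag_off  # superdiagonal
    ab[1, :] = diag_main
    ab[2, :-1] = diag_off  # subdiagonal
    # no-flux roof: ghost node R_n = R_{n-2}
    ab[2, m - 2] = 2.0 * diag_off

    rhs = np.zeros(m)
    rhs[0] = -diag_off * transport.R_star

    try:
        interior = solve_banded((1, 1), ab, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"resource BVP solve failed on {n}-point grid: {exc}")

    R = np.concatenate(([transport.R_star], interior))
    return ResourceProfile(
        heights_z=grid.z_prime_nodes * h, values_R=R, colony_height=h
    )


# ---------------------------------------------------------------------------
# transient resource equation
# ---------------------------------------------------------------------------


def solve_resource_transient(
    h: float,
    transport: TransportParams,
    alpha: float,
    duration: float,
    grid: ColumnGrid,
    *,
    initial_resource: np.ndarray | None = None,
    velocity: np.ndarray | None = None,
    n_steps: int = 400,
    scales: NondimScales | None = None,
) -> ResourceProfile:
    """Advance the time-dependent resource equation and return the profile.

    Works in the nondimensional frame (time in advection units 1/alpha,
    space in units of the initial height h0):

        dR'/dt' + d(u'R')/dz = (1/Pe) d2R'/dz2 - (alpha'/(eps' Pe)) R'

    with R'(0) = 1 and a no-flux roof.  The stiff 1/Pe diffusion makes
    explicit stepping impractical at realistic Pe ~ 1e-4, so an implicit
    (backward Euler) scheme is used; it is unconditionally stable and
    first-order in time, which is ample for relaxation studies.

    Parameters
    ----------
    h
        Colony height, um (fixed during the solve; the quasi-static check
        asks how the field relaxes at frozen geometry).
    duration
        Integration time in advection units t' = alpha * t.
    initial_resource
        Dimensionless initial profile R' on the grid nodes; defaults to the
        uniform well-fed state R' = 1.
    velocity
        Optional dimensionless velocity u' on the nodes for the advection
        term (central differences); omitted by default since advection is
        O(Pe) smaller than diffusion in the regime of interest.
    scales
        Precomputed nondimensional scales; derived from ``transport`` and
        ``alpha`` when not given.
    """
    if not (h > 0 and duration > 0):
        raise ValueError("h and duration must be > 0")
    if scales is None:
        scales = peclet(alpha, transport.h0, transport.D_R)
    Pe = scales.Pe
    eps_prime = transport.epsilon * transport.R_star
    n = grid.n_points
    dz = grid.spacing * (h / transport.h0)  # node spacing in units of h0

    R = (
        np.ones(n)
        if initial_resource is None
        else np.asarray(initial_resource, dtype=float).copy()
    )
    if R.shape != (n,):
        raise ValueError("initial_resource must match the grid")
    R[0] = 1.0

    dt = duration / n_steps
    diff = 1.0 / (Pe * dz * dz)
    uptake = scales.alpha_prime / (eps_prime * Pe)

    # implicit matrix (I - dt A) for unknowns R_1..R_{n-1}
    m = n - 1
    ab = np.zeros((3, m))
    ab[0, 1:] = -dt * diff
    ab[2, :-1] = -dt * diff
    ab[1, :] = 1.0 + dt * (2.0 * diff + uptake)
    ab[2, m - 2] = -2.0 * dt * diff  # ghost reflection at the roof

    adv = None
    if velocity is not None:
        u = np.asarray(velocity, dtype=float)
        if u.shape != (n,):
            raise ValueError("velocity must match the grid")
        adv = u

    for _ in range(n_steps):
        rhs = R[1:].copy()
        rhs[0] += dt * diff * 1.0  # Dirichlet base folded into the RHS
        if adv is not None:
            flux = adv * R
            dflux = np.gradient(flux, dz)
            rhs -= dt * dflux[1:]
        R[1:] = solve_banded((1, 1), ab, rhs)

    return ResourceProfile(
        heights_z=grid.z_prime_nodes * h,
        values_R=R * transport.R_star,
        colony_height=h,
    )


# ---------------------------------------------------------------------------
# pressure and velocity
# ---------------------------------------------------------------------------


def pressure_field(
    growth_values: np.ndarray,
    h: float,
    lambda_mobility: float,
    grid: ColumnGrid,
) -> PressureField:
    """Pressure from the growth field via double integration.

    Integrates d2p/dz'2 = -(h^2/lambda) g*(z') with dp/dz'(0) = 0 (no flow
    into the substrate) and p(1) = 0 (free roof).  Composite Simpson
    quadrature keeps the quadrature error far below the BVP error at any
    grid size.
    """
    if not (h > 0):
        raise ValueError(f"h must be > 0, got {h}")
    g = np.asarray(growth_values, dtype=float)
    if g.shape != grid.z_prime_nodes.shape:
        raise ValueError("growth_values must be sampled on the grid nodes")
    rhs = -(h * h / lambda_mobility) * g
    dpdz = cumulative_simpson(rhs, x=grid.z_prime_nodes, initial=0.0)
    p = cumulative_simpson(dpdz, x=grid.z_prime_nodes, initial=0.0)
    p -= p[-1]  # pin the roof at zero
    return PressureField(values=p, gradient=dpdz)


def velocity_field(
    pressure: PressureField | np.ndarray,
    h: float,
    lambda_mobility: float,
    grid: ColumnGrid,
) -> np.ndarray:
    """Darcy velocity u = -(lambda/h) dp/dz' on the grid nodes.

    Accepts either the :class:`PressureField` (whose analytically
    accumulated gradient is reused exactly) or a bare pressure array, which
    is differentiated with second-order finite differences.
    """
    if not (h > 0):
        raise ValueError(f"h must be > 0, got {h}")
    if isinstance(pressure, PressureField):
        dpdz = pressure.gradient
    else:
        dpdz = np.gradient(np.asarray(pressure, dtype=float), grid.z_prime_nodes)
    return -(lambda_mobility / h) * dpdz


def top_velocity(
    h: float,
    params: GrowthParams,
    grid: ColumnGrid,
    *,
    transport: TransportParams | None = None,
    order: int = 4,
) -> float:
    """Top-surface velocity from the full numerical pipeline.

    Resource BVP -> growth field g* = alpha R/R* - beta -> pressure ->
    Darcy velocity at z' = 1.  This is the quantity the closed form
    alpha L tanh(h/L) - beta h summarises; the Darcy mobility cancels.
    """
    if transport is None:
        transport = TransportParams.for_length(params.L, params.alpha)
    profile = solve_resource_bvp(h, transport, params.alpha, grid, order=order)
    g = params.alpha * profile.values_R / transport.R_star - params.beta
    p = pressure_field(g, h, transport.lambda_mobility, grid)
    u = velocity_field(p, h, transport.lambda_mobility, grid)
    return float(u[-1])


# ---------------------------------------------------------------------------
# moving-boundary simulation
# ---------------------------------------------------------------------------

_H_FLOOR = 0.5  # um; about half a cell length


def simulate_growth(
    params: GrowthParams,
    transport: TransportParams | None,
    h0: float,
    t_end: float,
    step: float,
    grid: ColumnGrid | None = None,
    *,
    refine_tol: float = 1e-6,
    max_halvings: int = 6,
    order: int = 4,
) -> SimulatedTrajectory:
    """Moving-boundary simulation of the colony height.

    Each height evaluation runs the quasi-static pipeline (resource solve,
    growth field, pressure integration, Darcy velocity) and the roof is
    advanced with classical fourth-order Runge--Kutta steps on
    dh/dt = u_top(h).  The step is halved until two successive refinements
    agree to ``refine_tol`` in relative sup-norm, so the returned trajectory
    is step-converged rather than tied to the requested resolution.

    Raises
    ------
    RuntimeError
        If the height becomes non-finite.  A collapse below half a cell
        length stops the run and flags it the same way.
    """
    if not (h0 > 0 and t_end > 0 and step > 0):
        raise ValueError("h0, t_end and step must be > 0")
    if grid is None:
        grid = ColumnGrid(256)
    if transport is None:
        transport = TransportParams.for_length(params.L, params.alpha, h0=h0)

    def rate(h: float) -> float:
        return top_velocity(h, params, grid, transport=transport, order=order)

    def run(dt: float) -> tuple[np.ndarray, np.ndarray]:
        n_steps = max(1, int(round(t_end / dt)))
        dt = t_end / n_steps
        times = np.linspace(0.0, t_end, n_steps + 1)
        heights = np.empty(n_steps + 1)
        heights[0] = h0
        h = h0
        for i in range(n_steps):
            k1 = rate(h)
            k2 = rate(max(h + 0.5 * dt * k1, _H_FLOOR))
            k3 = rate(max(h + 0.5 * dt * k2, _H_FLOOR))
            k4 = rate(max(h + dt * k3, _H_FLOOR))
            h = h + dt * (k1 + 2.0 * k2 + 2.0 * k3 + k4) / 6.0
            if not np.isfinite(h):
                raise RuntimeError(f"height became non-finite at t={times[i + 1]:.3f} h")
            if h < _H_FLOOR:
                raise RuntimeError(
                    f"colony collapsed below {_H_FLOOR} um at t={times[i + 1]:.3f} h"
                )
            heights[i + 1] = h
        return times, heights

    times, heights = run(step)
    for _ in range(max_halvings):
        step /= 2.0
        times_f, heights_f = run(step)
        err = np.max(np.abs(heights_f[::2] - heights) / np.abs(heights_f[::2]))
        times, heights = times_f, heights_f
        if err < refine_tol:
            break

    h_final = float(heights[-1])
    profile = solve_resource_bvp(h_final, transport, params.alpha, grid, order=order)
    g = params.alpha * profile.values_R / transport.R_star - params.beta
    p = pressure_field(g, h_final, transport.lambda_mobility, grid)
    u = velocity_field(p, h_final, transport.lambda_mobility, grid)
    return SimulatedTrajectory(
        times=times,
        heights=heights,
        final_fields=FieldState(resource=profile.values_R, pressure=p.values, velocity=u),
    )
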