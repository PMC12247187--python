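"""Closed-form quantities of the active-fluid model of vertical biofilm growth.

A biofilm colony is treated as an incompressible, growing "bio-fluid" column
of height ``h`` above a nutrient-supplying substrate.  Nutrient diffuses up
from the base (held at concentration ``R*``), is consumed by cells, and in
the rapid-diffusion (low Péclet number) limit its vertical profile is the
quasi-static solution of a linear reaction--diffusion balance.  Integrating
the resulting growth field through a Darcy pressure closure collapses the
whole column dynamics onto a single ODE for the colony height,

    dh/dt = alpha * L * tanh(h / L) - beta * h,

where ``alpha`` is the specific growth rate (1/h), ``beta`` the volume decay
rate (1/h) and ``L = sqrt(D_R * epsilon * R* / alpha)`` the characteristic
depth (um) of the metabolically active layer.  The older piecewise heuristic
("interface model") dh/dt = (alpha-beta)h for h <= L, alpha*L - beta*h for
h >= L is the kinked limit of the same law.

All public functions use hours and micrometres and accept scalars or NumPy
arrays; invalid domains raise :class:`ValueError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GrowthParams",
    "TransportParams",
    "NondimScales",
    "ResourceCoefficients",
    "ResourceProfile",
    "arcsech",
    "characteristic_length",
    "resource_coefficients",
    "resource_profile",
    "growth_profile",
    "dhdt_active",
    "dhdt_interface",
    "hstar",
    "steady_state_height",
    "peclet",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthParams:
    """Phenomenological rates of vertical colony growth.

    Parameters
    ----------
    alpha
        Specific growth rate of the bio-fluid, 1/h.  Must be positive.
    beta
        Volume decay rate (cell death with fast breakdown of the dead
        material), 1/h.  Non-negative; ``beta < alpha`` is required for a
        net-growing colony and is enforced by the operations that need it
        (`hstar`, `steady_state_height`) rather than by the type.
    L
        Characteristic nutrient penetration depth, um.  Must be positive.
    """

    alpha: float
    beta: float
    L: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta >= 0):
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if not (self.L > 0):
            raise ValueError(f"L must be > 0, got {self.L}")

    @property
    def ratio(self) -> float:
        """Decay-to-growth ratio beta/alpha (dimensionless)."""
        return self.beta / self.alpha


@dataclass(frozen=True)
class TransportParams:
    """Microscopic transport parameters behind the characteristic length.

    Only the combination ``D_R * epsilon * R_star / alpha`` (= L**2) is
    identifiable from height data; the individual components matter only for
    the field-level simulations.  ``rho`` (specific cell mass density) is
    carried for documentation: the volume-fraction formulation eliminates it.

    Parameters
    ----------
    D_R
        Resource diffusion coefficient, um^2/h.
    epsilon
        Yield: volume fraction of bio-fluid produced per unit concentration
        of resource consumed.
    R_star
        Resource concentration clamped at the colony base (agar interface).
    lambda_mobility
        Darcy mobility coupling velocity to the pressure gradient.  It
        cancels from dh/dt and only sets the internal pressure scale.
    h0
        Initial colony height, um (about one cell length).
    rho
        Specific cell mass density; never used in computations.
    """

    D_R: float
    epsilon: float = 1.0
    R_star: float = 1.0
    lambda_mobility: float = 1.0
    h0: float = 1.0
    rho: float | None = None

    def __post_init__(self) -> None:
        for name in ("D_R", "epsilon", "R_star", "lambda_mobility", "h0"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @classmethod
    def for_length(
        cls,
        L: float,
        alpha: float,
        *,
        epsilon: float = 1.0,
        R_star: float = 1.0,
        lambda_mobility: float = 1.0,
        h0: float = 1.0,
    ) -> "TransportParams":
        """Transport parameters realising a target characteristic length.

        Fixes ``epsilon`` and ``R_star`` and back-solves the diffusivity
        ``D_R = alpha * L**2 / (epsilon * R_star)``; any split would do, as
        only the product is observable.
        """
        if not (L > 0 and alpha > 0):
            raise ValueError("L and alpha must be > 0")
        return cls(
            D_R=alpha * L * L / (epsilon * R_star),
            epsilon=epsilon,
            R_star=R_star,
            lambda_mobility=lambda_mobility,
            h0=h0,
        )


@dataclass(frozen=True)
class NondimScales:
    """Characteristic time scales and the Péclet number.

    ``Pe = T_diff / T_adv = alpha * h0**2 / D_R``; under the scalings used
    here the rescaled growth rate ``alpha_prime`` is numerically identical
    to ``Pe``.
    """

    T_adv: float
    T_diff: float
    Pe: float
    alpha_prime: float

    def __post_init__(self) -> None:
        for name in ("T_adv", "T_diff", "Pe", "alpha_prime"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class ResourceCoefficients:
    """Coefficients of the exponential form of the quasi-static profile.

    ``C1`` multiplies the growing exponential exp(+z/L), ``C2`` the decaying
    one; they always sum to ``R_star`` exactly, and the growing term's weight
    C1 decays from R_star/2 at h = 0 towards 0 as the colony gets tall.
    """

    C1: float
    C2: float


@dataclass(frozen=True)
class ResourceProfile:
    """Sampled nutrient concentration over the colony column."""

    heights_z: np.ndarray
    values_R: np.ndarray
    colony_height: float

    def __post_init__(self) -> None:
        z = np.asarray(self.heights_z, dtype=float)
        R = np.asarray(self.values_R, dtype=float)
        if z.shape != R.shape:
            raise ValueError("heights_z and values_R must have equal shape")
        object.__setattr__(self, "heights_z", z)
        object.__setattr__(self, "values_R", R)


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------


def arcsech(x):
    """Inverse hyperbolic secant on (0, 1].

    Evaluated as ``log((1 + sqrt(1 - x^2)) / x)``, which is the principal
    (positive) branch and numerically stable as x -> 1.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(x > 1):
        raise ValueError("arcsech requires 0 < x <= 1")
    out = np.log((1.0 + np.sqrt((1.0 - x) * (1.0 + x))) / x)
    return out.item() if out.ndim == 0 else out


def _cosh_ratio(numer_arg, denom_arg):
    """cosh(numer_arg)/cosh(denom_arg) without overflow.

    Requires |numer_arg| <= |denom_arg| so every exponent is non-positive:
    cosh(a)/cosh(b) = (e^(|a|-|b|) + e^(-|a|-|b|)) / (1 + e^(-2|b|)).
    """
    a = np.abs(numer_arg)
    b = np.abs(denom_arg)
    return (np.exp(a - b) + np.exp(-a - b)) / (1.0 + np.exp(-2.0 * b))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def characteristic_length(transport: TransportParams, alpha: float) -> float:
    """Depth of the metabolically active layer, L = sqrt(D_R eps R* / alpha).

    Decreasing in the growth rate (faster uptake shortens the supplied
    layer), increasing in diffusivity, yield and base concentration.
    """
    if not (alpha > 0):
        raise ValueError(f"alpha must be > 0, got {alpha}")
    return math.sqrt(transport.D_R * transport.epsilon * transport.R_star / alpha)


def resource_coefficients(h: float, L: float, R_star: float) -> ResourceCoefficients:
    """Exponential-form coefficients of the quasi-static nutrient profile.

    C1 = R*/(exp(2h/L) + 1) weights the growing exponential and C2 =
    R*/(exp(-2h/L) + 1) the decaying one; C1 + C2 = R* identically.
    """
    if h < 0:
        raise ValueError(f"h must be >= 0, got {h}")
    if not (L > 0 and R_star > 0):
        raise ValueError("L and R_star must be > 0")
    x = 2.0 * h / L
    # writing C1 via exp(-x) keeps it finite for very tall colonies
    e_neg = math.exp(-x)
    C1 = R_star * e_neg / (1.0 + e_neg)
    C2 = R_star / (1.0 + e_neg)
    return ResourceCoefficients(C1=C1, C2=C2)


def resource_profile(z, h: float, L: float, R_star: float):
    """Quasi-static nutrient concentration R(z) inside a colony of height h.

    R(z) = R* cosh((z - h)/L) / cosh(h/L): the Dirichlet base condition
    R(0) = R* and the no-flux roof dR/dz(h) = 0 make the profile an even
    function about the colony top.  The no-flux "reflection" is why short
    colonies see systematically more nutrient at a given depth than the
    naive exp(-z/L) decay would give.
    """
    if not (L > 0 and R_star > 0):
        raise ValueError("L and R_star must be > 0")
    if h < 0:
        raise ValueError(f"h must be >= 0, got {h}")
    z = np.asarray(z, dtype=float)
    if np.any(z < 0) or np.any(z > h):
        raise ValueError("z must lie within [0, h]")
    out = R_star * _cosh_ratio((z - h) / L, h / L)
    return out.item() if out.ndim == 0 else out


def growth_profile(z_prime, h: float, params: GrowthParams):
    """Net volumetric growth rate g*(z') on the rescaled column z' = z/h.

    g*(z') = alpha * cosh((h/L)(z' - 1)) / cosh(h/L) - beta.  Growth is
    maximal (alpha - beta) at the base where nutrient is clamped, decays
    with height, and the deep interior of a tall colony tends to -beta.
    """
    if h < 0:
        raise ValueError(f"h must be >= 0, got {h}")
    z_prime = np.asarray(z_prime, dtype=float)
    if np.any(z_prime < 0) or np.any(z_prime > 1):
        raise ValueError("z_prime must lie within [0, 1]")
    k = h / params.L
    out = params.alpha * _cosh_ratio(k * (z_prime - 1.0), k) - params.beta
    return out.item() if out.ndim == 0 else out


def dhdt_active(h, params: GrowthParams):
    """Height velocity of the active-fluid model: alpha L tanh(h/L) - beta h.

    Smooth in h, zero at h = 0, saturating growth term alpha*L for tall
    colonies and linear decay everywhere.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("h must be >= 0")
    out = params.alpha * params.L * np.tanh(h / params.L) - params.beta * h
    return out.item() if out.ndim == 0 else out


def dhdt_interface(h, params: GrowthParams):
    """Height velocity of the piecewise heuristic interface model.

    (alpha - beta) h below the characteristic depth L, alpha L - beta h
    above it; the branches agree at h = L, where the rate is kinked.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("h must be >= 0")
    out = np.where(
        h <= params.L,
        (params.alpha - params.beta) * h,
        params.alpha * params.L - params.beta * h,
    )
    return out.item() if out.ndim == 0 else out


def hstar(params: GrowthParams) -> float:
    """Colony height at which the active-model growth rate peaks.

    h* = L * arcsech(sqrt(beta/alpha)); always exceeds L for the
    decay-to-growth ratios seen in practice (h* = L at beta/alpha ~ 0.42).
    Requires 0 < beta < alpha: without decay the rate saturates instead of
    peaking, and with beta >= alpha it decreases from the start.
    """
    if not (params.beta > 0):
        raise ValueError("hstar requires beta > 0 (no interior maximum otherwise)")
    if not (params.beta < params.alpha):
        raise ValueError("hstar requires beta < alpha (arcsech argument must be < 1)")
    return params.L * arcsech(math.sqrt(params.beta / params.alpha))


def steady_state_height(params: GrowthParams, model: str = "active") -> float:
    """Plateau height where growth balances decay.

    The interface model gives alpha*L/beta exactly; the active model's
    root of alpha L tanh(h/L) = beta h lies just below it (tanh < 1) and is
    bracketed in (h*, alpha L / beta].
    """
    from scipy.optimize import brentq

    if model not in ("active", "interface"):
        raise ValueError(f"unknown model {model!r}")
    if not (params.beta > 0):
        raise ValueError("steady state requires beta > 0 (unbounded growth otherwise)")
    if not (params.beta < params.alpha):
        raise ValueError("steady state requires beta < alpha")
    h_interface = params.alpha * params.L / params.beta
    if model == "interface":
        return h_interface
    lo = hstar(params)
    f = lambda h: dhdt_active(h, params)
    # dhdt is positive at h* and non-positive at the interface plateau; in
    # floats tanh can saturate to exactly 1 there, leaving f a rounding-level
    # positive, so widen the bracket until the sign genuinely flips
    hi = h_interface
    for _ in range(60):
        if f(hi) <= 0:
            break
        hi *= 1.0 + 1e-9
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def peclet(alpha: float, h0: float, D_R: float) -> NondimScales:
    """Nondimensional scales of resource transport in a young colony.

    Pe = alpha h0^2 / D_R compares the diffusion time across the initial
    height with the advection (growth) time 1/alpha; measured values put it
    near 1e-4, which justifies the quasi-static nutrient profile.
    """
    if not (alpha > 0 and h0 > 0 and D_R > 0):
        raise ValueError("alpha, h0 and D_R must all be > 0")
    T_adv = 1.0 / alpha
    T_diff = h0 * h0 / D_R
    pe = T_diff / T_adv
    return NondimScales(T_adv=T_adv, T_diff=T_diff, Pe=pe, alpha_prime=pe)
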