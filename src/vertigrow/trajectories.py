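"""Height-over-time curves for the active-fluid and interface models.

The active model's ODE dh/dt = alpha L tanh(h/L) - beta h has no elementary
closed-form solution, so trajectories are produced by adaptive high-order
integration (DOP853, rtol 1e-10).  The piecewise interface model does admit
an exact piecewise-exponential solution, implemented in
:func:`interface_closed_form`; the numeric path integrates it with event
detection at the kink h = L so the adaptive stepper never straddles the
discontinuity in dh/dt's derivative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .model_core import GrowthParams, dhdt_active, dhdt_interface

__all__ = ["HeightTrajectory", "integrate_height", "interface_closed_form"]

_MODEL_TAGS = ("active", "interface", "data")


@dataclass(frozen=True)
class HeightTrajectory:
    """Time series of colony height, the central observable.

    ``times`` in hours (strictly increasing), ``heights`` in micrometres
    (strictly positive), ``model_tag`` one of ``active``, ``interface`` or
    ``data``.
    """

    times: np.ndarray
    heights: np.ndarray
    model_tag: str = "data"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        h = np.asarray(self.heights, dtype=float)
        if t.ndim != 1 or t.shape != h.shape or t.size < 2:
            raise ValueError("times and heights must be equal-length 1-D, size >= 2")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(h <= 0):
            raise ValueError("heights must be strictly positive")
        if self.model_tag not in _MODEL_TAGS:
            raise ValueError(f"model_tag must be one of {_MODEL_TAGS}")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "heights", h)

    def __len__(self) -> int:
        return self.times.size


def integrate_height(
    params: GrowthParams,
    h0: float,
    times,
    model: str = "active",
    *,
    rtol: float = 1e-10,
) -> HeightTrajectory:
    """Integrate a growth law from ``h0`` over the given time grid.

    ``times[0]`` is the initial time and ``heights[0] == h0`` by
    construction; the dynamics are autonomous, so integration happens on
    the shifted grid t - times[0].
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing, length >= 2")
    if not (h0 > 0):
        raise ValueError(f"h0 must be > 0, got {h0}")
    if model not in ("active", "interface"):
        raise ValueError(f"unknown model {model!r}")

    span = t - t[0]

    if model == "active":
        sol = solve_ivp(
            lambda _, y: [dhdt_active(max(y[0], 0.0), params)],
            (0.0, span[-1]),
            [h0],
            t_eval=span,
            method="DOP853",
            rtol=rtol,
            atol=1e-12 * max(h0, params.alpha * params.L / max(params.beta, 1e-12)),
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"integration failed: {sol.message}")
        heights = sol.y[0]
    else:
        heights = _integrate_interface(params, h0, span, rtol)

    heights = np.asarray(heights, dtype=float)
    heights[0] = h0
    return HeightTrajectory(times=t, heights=heights, model_tag=model)


def _integrate_interface(params, h0, span, rtol):
    """Numeric interface-model trajectory with kink events at h = L."""

    def rhs(_, y):
        return [dhdt_interface(max(y[0], 0.0), params)]

    def kink(_, y):
        return y[0] - params.L

    kink.terminal = True
    kink.direction = 0

    heights = np.empty_like(span)
    idx = 0
    t_now, h_now = 0.0, h0
    # restart the integrator at each branch crossing; at most two segments
    # can occur (growth up through L, or decay down through L), but the loop
    # is generic.
    for _ in range(8):
        events = [kink] if not math.isclose(h_now, params.L, rel_tol=1e-12) else []
        mask = span >= t_now - 1e-12
        t_eval = span[mask]
        sol = solve_ivp(
            rhs,
            (t_now, span[-1]),
            [h_now],
            t_eval=t_eval if t_eval.size else None,
            events=events or None,
            method="DOP853",
            rtol=rtol,
            atol=1e-12 * max(h0, params.L),
        )
        if not sol.success:  # pragma: no cover - defensive
            raise RuntimeError(f"integration failed: {sol.message}")
        n_got = sol.t.size
        heights[idx : idx + n_got] = sol.y[0]
        idx += n_got
        if sol.status == 1 and sol.t_events[0].size:  # hit the kink
            t_now = float(sol.t_events[0][0])
            h_now = params.L * (1.0 + 1e-15)  # nudge off the event surface
            continue
        break
    if idx < span.size:  # pragma: no cover - defensive
        raise RuntimeError("interface integration did not cover the time grid")
    return heights


def interface_closed_form(params: GrowthParams, h0: float, t):
    """Exact piecewise-exponential interface-model solution h(t).

    Below L the law is linear, h = h0 exp((alpha-beta) t); once the
    trajectory crosses L at t_c = ln(L/h0)/(alpha-beta) the second branch
    relaxes exponentially toward the plateau alpha L / beta:
    h = aL/b + (L - aL/b) exp(-beta (t - t_c)).  Crossings in either
    direction are handled; a colony started below L with alpha == beta sits
    on a constant branch forever (flagged via the returned value simply
    staying at h0).
    """
    if not (h0 > 0):
        raise ValueError(f"h0 must be > 0, got {h0}")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    a, b, L = params.alpha, params.beta, params.L

    def branch1(t0, h_at_t0, tt):
        return h_at_t0 * np.exp((a - b) * (tt - t0))

    def branch2(t0, h_at_t0, tt):
        if b == 0:
            return h_at_t0 + a * L * (tt - t0)
        plateau = a * L / b
        return plateau + (h_at_t0 - plateau) * np.exp(-b * (tt - t0))

    out = np.empty_like(t)
    if h0 < L:
        if a <= b:
            # decaying or constant first branch: never reaches L
            out[:] = branch1(0.0, h0, t)
        else:
            t_c = math.log(L / h0) / (a - b)
            below = t <= t_c
            out[below] = branch1(0.0, h0, t[below])
            out[~below] = branch2(t_c, L, t[~below])
    else:
        plateau = a * L / b if b > 0 else math.inf
        if b > 0 and plateau < L < h0:
            # decay through the kink into the first branch (requires b > a)
            t_c = -math.log((L - plateau) / (h0 - plateau)) / b
            above = t <= t_c
            out[above] = branch2(0.0, h0, t[above])
            out[~above] = branch1(t_c, L, t[~above])
        else:
            out[:] = branch2(0.0, h0, t)
    return out[0].item() if scalar else out
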