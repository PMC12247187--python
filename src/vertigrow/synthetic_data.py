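"""Seeded synthetic height-over-time panels emulating interferometric data.

Single-colony vertical height traces start near one cell length (~1 um),
rise near-exponentially while the colony is shorter than the nutrient
penetration depth L, and saturate toward the plateau alpha L / beta over
tens of hours.  The generator integrates the chosen growth law for a
noiseless backbone and overlays multiplicative Gaussian noise (optical
height error plausibly scales with height) plus a small additive floor
(instrument noise).  Parameter panels are drawn uniformly from the narrow
region of rate space that laboratory strains occupy: alpha in [0.4, 1.5]/h,
beta/alpha in [0.03, 0.12], L in [5, 30] um.

Every trajectory is reproducible from a single integer seed; panels spawn
per-strain child seeds from the panel seed, so strain k of a panel is
stable under changes to n_strains >= k.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .model_core import GrowthParams
from .trajectories import HeightTrajectory, integrate_height

__all__ = ["SyntheticSpec", "generate_trajectory", "generate_panel", "save_panel"]

_H_TRUNCATE = 0.01  # um; positivity floor for noisy observations


@dataclass(frozen=True)
class SyntheticSpec:
    """Sampling design, parameter ranges and noise model for a panel.

    Defaults describe the measured regime: 40 h of growth sampled every
    0.5 h from an initial height of one cell length, with 1% relative noise
    and a 0.1 um additive floor.
    """

    n_strains: int = 9
    alpha_range: tuple[float, float] = (0.4, 1.5)
    beta_over_alpha_range: tuple[float, float] = (0.03, 0.12)
    L_range: tuple[float, float] = (5.0, 30.0)
    h0: float = 1.0
    duration: float = 40.0
    sampling_interval: float = 0.5
    noise_sd_rel: float = 0.01
    noise_sd_abs: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strains < 1:
            raise ValueError("n_strains must be >= 1")
        for name in ("alpha_range", "beta_over_alpha_range", "L_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        ra = self.beta_over_alpha_range
        if not (ra[1] < 1.0):
            raise ValueError("beta_over_alpha_range must lie inside (0, 1)")
        if not (self.h0 > 0 and self.duration > 0 and self.sampling_interval > 0):
            raise ValueError("h0, duration and sampling_interval must be > 0")
        if self.sampling_interval >= self.duration:
            raise ValueError("sampling_interval must be shorter than duration")
        if self.noise_sd_rel < 0 or self.noise_sd_abs < 0:
            raise ValueError("noise levels must be >= 0")

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration / self.sampling_interval)) + 1
        return np.arange(n) * self.sampling_interval


def generate_trajectory(
    params: GrowthParams,
    spec: SyntheticSpec,
    model: str = "active",
    seed: int | None = None,
) -> HeightTrajectory:
    """One noisy height trace for the given rates.

    The observation model is h_obs = h(1 + e_rel) + e_abs with independent
    zero-mean Gaussians per time point, truncated below at 0.01 um so
    observations stay positive.  Zero noise returns the backbone exactly.
    """
    if seed is None:
        seed = spec.seed
    backbone = integrate_height(params, spec.h0, spec.times, model=model)
    rng = np.random.default_rng(seed)
    h = backbone.heights
    obs = h.copy()
    if spec.noise_sd_rel > 0:
        obs = obs * (1.0 + rng.normal(0.0, spec.noise_sd_rel, h.size))
    if spec.noise_sd_abs > 0:
        obs = obs + rng.normal(0.0, spec.noise_sd_abs, h.size)
    obs = np.maximum(obs, _H_TRUNCATE)
    return HeightTrajectory(times=spec.times, heights=obs, model_tag="data")


def generate_panel(
    spec: SyntheticSpec, model: str = "active"
) -> list[tuple[GrowthParams, HeightTrajectory]]:
    """A panel of strains with parameters drawn uniformly within ranges.

    beta is derived from a uniform beta/alpha draw, keeping every strain in
    the net-growth regime.  The generating parameters are returned with
    each trajectory so downstream recovery can be scored.
    """
    root = np.random.default_rng(spec.seed)
    panel = []
    for _ in range(spec.n_strains):
        alpha = root.uniform(*spec.alpha_range)
        ratio = root.uniform(*spec.beta_over_alpha_range)
        L = root.uniform(*spec.L_range)
        child_seed = int(root.integers(0, 2**31 - 1))
        params = GrowthParams(alpha=alpha, beta=ratio * alpha, L=L)
        panel.append((params, generate_trajectory(params, spec, model, child_seed)))
    return panel


def save_panel(
    panel: list[tuple[GrowthParams, HeightTrajectory]],
    outdir: str | Path,
    spec: SyntheticSpec | None = None,
) -> Path:
    """Write one CSV per strain plus a manifest of generating parameters.

    Returns the manifest path.  Strain files are ``strain_00.csv`` etc.
    with columns time_h, height_um.
    """
    import pandas as pd

    from .cli_io import write_trajectory

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (params, traj) in enumerate(panel):
        name = f"strain_{k:02d}.csv"
        write_trajectory(traj, outdir / name)
        rows.append(
            {
                "strain": name,
                "alpha_per_h": params.alpha,
                "beta_per_h": params.beta,
                "L_um": params.L,
                "seed": spec.seed if spec is not None else None,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
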