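"""Synthetic growth curves, Brownian tracks and lattice fixtures.

Everything here carries its ground truth alongside the data and is
bit-reproducible from a seed, emulating the structure of an in-vitro
confluency experiment: six seeding densities, eight replicates sampled
every 15 min for 120 h with the first 3.5 h discarded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .meanfield import PhenomParams, euler_solve
from .fitting import GrowthCurveSet
from .trackstats import Track, TrackSet

__all__ = [
    "SynthSpec",
    "n0_from_cells_per_well",
    "synth_growth_curves",
    "synth_tracks",
    "synth_occupancy",
    "DEFAULT_CELLS_PER_WELL",
]

#: Seeding ladder used by the emulated experimental design (cells/well).
DEFAULT_CELLS_PER_WELL = (125, 250, 500, 1000, 2000, 4000)

#: Linear cells/well -> normalized density map: 4000 cells/well corresponds
#: to n0 = 0.08 by default (the conversion itself is a free choice).
DEFAULT_FULL_WELL_CELLS = 50_000.0


def n0_from_cells_per_well(cells: float, full_well_cells: float = DEFAULT_FULL_WELL_CELLS) -> float:
    if full_well_cells <= 0:
        raise ValueError("full_well_cells must be > 0")
    return cells / full_well_cells


@dataclass(frozen=True)
class SynthSpec:
    """Design of a synthetic growth-curve experiment (rates per hour)."""

    theta: tuple[float, float, float] = (0.08, 0.25, 0.07)  # (A, B, mu) in 1/h
    initial_densities: tuple[float, ...] = tuple(
        n0_from_cells_per_well(c) for c in DEFAULT_CELLS_PER_WELL
    )
    replicates: int = 8
    duration_h: float = 120.0
    sample_interval_h: float = 0.25
    discard_h: float = 3.5
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.duration_h <= self.discard_h:
            raise ValueError("duration must exceed the discard window")
        if self.sample_interval_h <= 0:
            raise ValueError("sample_interval_h must be > 0")
        for n0 in self.initial_densities:
            if not 0.0 <= n0 <= 1.0:
                raise ValueError("initial densities must lie in [0, 1]")

    @property
    def params(self) -> PhenomParams:
        A, B, mu = self.theta
        return PhenomParams(A=A, B=B, mu=mu, time_unit="hours")


def synth_growth_curves(spec: SynthSpec) -> tuple[GrowthCurveSet, dict]:
    """Noisy replicate-averaged growth curves plus their ground truth.

    Per seeding density: ``replicates`` copies of the Euler trajectory with
    i.i.d. additive Gaussian noise (clipped to [0, 1]) are averaged; points
    in the first ``discard_h`` hours are then dropped.
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.params
    n_samples = int(math.floor(spec.duration_h / spec.sample_interval_h + 1e-9))
    t_grid = np.arange(n_samples + 1) * spec.sample_interval_h
    curves = {}
    for n0 in spec.initial_densities:
        t_euler, n_euler = euler_solve(p, n0, spec.duration_h, dt=spec.sample_interval_h)
        clean = np.interp(t_grid, t_euler, n_euler)
        reps = clean[None, :] + rng.normal(0.0, spec.noise_sd, size=(spec.replicates, t_grid.size))
        reps = np.clip(reps, 0.0, 1.0)
        avg = reps.mean(axis=0)
        keep = t_grid >= spec.discard_h
        curves[f"n0={n0:g}"] = (t_grid[keep], np.clip(avg[keep], 0.0, 1.0))
    truth = {
        "theta": tuple(spec.theta),
        "initial_densities": tuple(spec.initial_densities),
        "noise_sd": spec.noise_sd,
        "replicates": spec.replicates,
        "seed": spec.seed,
    }
    return GrowthCurveSet(curves), truth


def synth_tracks(
    D: float,
    n_tracks: int,
    frame_interval: float,
    duration: float,
    seed: int = 0,
    label: Optional[str] = None,
) -> TrackSet:
    """2-D Brownian tracks: per-axis Gaussian increments of variance 2*D*dt.

    Times in seconds, positions in cm, all tracks starting at the origin.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    if frame_interval <= 0 or duration < frame_interval:
        raise ValueError("need duration >= frame_interval > 0")
    rng = np.random.default_rng(seed)
    n_steps = int(math.floor(duration / frame_interval + 1e-9))
    t = np.arange(n_steps + 1) * frame_interval
    sd = math.sqrt(2.0 * D * frame_interval)
    tracks = []
    for i in range(n_tracks):
        steps = rng.normal(0.0, sd, size=(n_steps, 2)) if sd > 0 else np.zeros((n_steps, 2))
        pos = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
        tracks.append(Track(track_id=f"track{i}", t=t, x=pos[:, 0], y=pos[:, 1], label=label))
    return TrackSet(tracks=tracks, frame_interval=frame_interval)


def synth_occupancy(
    N: int,
    pattern: str = "uniform_random",
    n0: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Binary N x N occupancy fixtures: uniform_random, centered block, or single site."""
    if not 0.0 <= n0 <= 1.0:
        raise ValueError("n0 must lie in [0, 1]")
    occ = np.zeros((N, N), dtype=np.int8)
    if pattern == "uniform_random":
        n_cells = int(round(n0 * N * N))
        if n_cells:
            rng = np.random.default_rng(seed)
            flat = rng.choice(N * N, size=n_cells, replace=False)
            occ.ravel()[flat] = 1
    elif pattern == "block":
        side = int(math.ceil(math.sqrt(n0 * N * N)))
        side = min(side, N)
        lo = (N - side) // 2
        occ[lo : lo + side, lo : lo + side] = 1
    elif pattern == "single":
        occ[N // 2, N // 2] = 1
    else:
        raise ValueError("pattern must be one of: uniform_random, block, single")
    return occ
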