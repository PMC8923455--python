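"""Stochastic individual-based lattice model with autocrine division benefit.

Cells occupy an N x N square lattice (exclusion: one cell per site).  Each
cell divides at rate alpha*(1 + g) where g is the growth-factor
concentration at its own site, dies at rate mu and migrates at rate nu to a
uniformly drawn von Neumann neighbor (failing if the target is occupied or
off-lattice).  Daughters are dispersed either uniformly over the whole
lattice ("long") or to a von Neumann neighbor ("short"); an occupied or
off-lattice target makes the division fail.  The field is advanced in
operator-split fashion between cell steps (see :mod:`._kernels`).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from typing import Optional

import numpy as np

from . import _kernels
from .gf_field import GFField

__all__ = [
    "LatticeState",
    "IBParams",
    "SimResult",
    "initialize_lattice",
    "division_target",
    "simulate",
    "nu_from_diffusion",
]

DISPERSAL_MODES = ("long", "short")

# von Neumann step offsets
_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))


@dataclass
class LatticeState:
    """Cell configuration: binary occupancy grid plus simulation clock."""

    occupancy: np.ndarray  # int8 N x N
    time: float = 0.0

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 2 or occ.shape[0] != occ.shape[1]:
            raise ValueError("occupancy must be a square 2-D grid")
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        self.occupancy = occ.astype(np.int8)

    @property
    def N(self) -> int:
        return self.occupancy.shape[0]

    @property
    def n_cells(self) -> int:
        return int(self.occupancy.sum())

    @property
    def density(self) -> float:
        return self.n_cells / self.occupancy.size


@dataclass(frozen=True)
class IBParams:
    """All rates in 1/s; lengths in cm.  ``dispersal`` is 'long' or 'short'."""

    alpha: float = 1e-5
    mu: float = 0.0
    nu: float = 0.0
    dispersal: str = "long"
    D: float = 5e-9
    rho: float = 1e-2
    delta: float = 1e-3
    N: int = 100
    L: float = 0.2
    seed: int = 0
    prob_cap: float = 0.02  # max per-cell event probability per scheduler step

    def __post_init__(self) -> None:
        if self.dispersal not in DISPERSAL_MODES:
            raise ValueError(f"dispersal must be one of {DISPERSAL_MODES}")
        for name in ("alpha", "mu", "nu", "D", "rho", "delta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.N <= 0 or self.L <= 0:
            raise ValueError("N and L must be > 0")
        if not 0.0 < self.prob_cap <= 0.05:
            raise ValueError("prob_cap must lie in (0, 0.05]")

    @property
    def spacing(self) -> float:
        return self.L / self.N


@dataclass
class SimResult:
    times: np.ndarray       # seconds
    density: np.ndarray     # normalized cell density n(t) in [0, 1]
    final_state: LatticeState
    final_field: GFField
    params: IBParams = dataclass_field(repr=False, default=None)


def initialize_lattice(N: int, n0: float, seed: int) -> LatticeState:
    """Place round(n0 * N^2) cells uniformly at random without replacement."""
    if not 0.0 <= n0 <= 1.0:
        raise ValueError("n0 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cells = int(round(n0 * N * N))
    occ = np.zeros(N * N, dtype=np.int8)
    if n_cells > 0:
        occ[rng.choice(N * N, size=n_cells, replace=False)] = 1
    return LatticeState(occupancy=occ.reshape(N, N))


def division_target(
    state: LatticeState,
    site: tuple[int, int],
    mode: str,
    rng: np.random.Generator,
) -> Optional[tuple[int, int]]:
    """Draw a placement site for the daughter of the cell at ``site``.

    Long mode draws uniformly over all N^2 sites; short mode draws one of
    the four von Neumann directions (off-lattice counts as a failure, so
    each direction keeps probability 1/4).  Returns None when the attempt
    fails because the drawn site is occupied or outside the lattice.
    """
    if mode not in DISPERSAL_MODES:
        raise ValueError(f"mode must be one of {DISPERSAL_MODES}")
    x, y = site
    N = state.N
    if state.occupancy[x, y] != 1:
        raise ValueError(f"source site {site} is not occupied")
    if mode == "long":
        tx = int(rng.integers(0, N))
        ty = int(rng.integers(0, N))
    else:
        dx, dy = _OFFSETS[int(rng.integers(0, 4))]
        tx, ty = x + dx, y + dy
        if not (0 <= tx < N and 0 <= ty < N):
            return None
    if state.occupancy[tx, ty] == 1:
        return None
    return (tx, ty)


def nu_from_diffusion(D_c: float, d: float) -> float:
    """Migration rate nu = 4*D_c/d^2 matching a lattice walker's MSD = 4*D_c*t."""
    if D_c < 0:
        raise ValueError("D_c must be >= 0")
    if d <= 0:
        raise ValueError("site size d must be > 0")
    return 4.0 * D_c / (d * d)


def simulate(
    params: IBParams,
    T: float,
    record_every: float,
    initial_state: Optional[LatticeState] = None,
    n0: Optional[float] = None,
) -> SimResult:
    """Run the coupled cell/growth-factor simulation for ``T`` seconds.

    Either pass an explicit ``initial_state`` or an initial density ``n0``
    (cells then placed uniformly at random using ``params.seed``).  Density
    is recorded every ``record_every`` seconds; the run is reproducible
    from ``params.seed``.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if record_every <= 0:
        raise ValueError("record_every must be > 0")
    if initial_state is None:
        if n0 is None:
            raise ValueError("provide initial_state or n0")
        initial_state = initialize_lattice(params.N, n0, params.seed)
    if initial_state.N != params.N:
        raise ValueError("initial_state size does not match params.N")

    occ = initial_state.occupancy.copy()
    g = np.zeros((params.N, params.N), dtype=np.float64)
    mode = _kernels.LONG if params.dispersal == "long" else _kernels.SHORT
    times, dens = _kernels.run_sim(
        occ,
        g,
        params.alpha,
        params.mu,
        params.nu,
        params.rho,
        params.delta,
        params.D,
        params.spacing,
        mode,
        float(T),
        float(record_every),
        np.uint32(params.seed & 0xFFFFFFFF),
        params.prob_cap,
    )
    final_state = LatticeState(occupancy=occ, time=float(times[-1]))
    final_field = GFField(
        values=g, spacing=params.spacing, D=params.D, rho=params.rho, delta=params.delta
    )
    return SimResult(
        times=times, density=dens, final_state=final_state, final_field=final_field,
        params=params,
    )


def simulate_ensemble(
    params: IBParams,
    T: float,
    record_every: float,
    n0: float,
    replicates: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble of replicate runs; returns (times, densities[replicate, time]).

    Replicate ``r`` uses seed ``params.seed + r`` for both the initial
    placement and the dynamics.
    """
    if replicates <= 0:
        raise ValueError("replicates must be > 0")
    from dataclasses import replace

    trajs = []
    times = None
    for r in range(replicates):
        p_r = replace(params, seed=params.seed + r)
        res = simulate(p_r, T, record_every, n0=n0)
        trajs.append(res.density)
        times = res.times
    return times, np.vstack(trajs)
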