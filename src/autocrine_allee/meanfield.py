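"""Mean-field ODE for lattice populations with an autocrine division benefit.

The population density ``n`` (normalized to the number of lattice sites)
obeys::

    dn/dt = f(n) = Gamma(n) * n * (1 - n) - mu * n

with a density-dependent division rate ``Gamma(n) = A + B*n``.  For the
mechanistic lattice model the coefficients are

    A = alpha + alpha*rho*K/N
    B = alpha*rho/delta - alpha*rho*K/N
    K = 1/(2*delta) + L/(4*sqrt(delta*D))

so that ``Gamma(n) = alpha + n*alpha*rho/delta + (alpha*rho*K/N)*(1-n)``:
a baseline rate, the mean-field contribution of the secreted factor, and a
local-concentration benefit that scales with 1/N = d/L.

Classification: the extinction state n=0 is stable iff f'(0) = A - mu < 0,
i.e. mu >= A gives a strong Allee effect with an extinction threshold n_c
(the unstable interior equilibrium); mu < A with B > A gives a weak Allee
effect (per-capita growth increasing at low density but positive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MechanisticParams",
    "PhenomParams",
    "compute_K",
    "reduce_params",
    "growth_rate",
    "critical_death_rate",
    "classify_allee",
    "critical_density",
    "fixed_points",
    "euler_solve",
    "BASELINE",
]

SECONDS_PER_HOUR = 3600.0

#: Allowed time units for phenomenological parameters.
_TIME_UNITS = ("seconds", "hours")


def compute_K(delta: float, D: float, L: float) -> float:
    """Spatial-interaction timescale K = 1/(2*delta) + L/(4*sqrt(delta*D)).

    Carries units of time, so that rho*K is dimensionless in Gamma(n).

    Parameters
    ----------
    delta : growth-factor decay rate (1/s).
    D : growth-factor diffusion coefficient (cm^2/s).
    L : linear domain size (cm).
    """
    if delta <= 0 or D <= 0 or L <= 0:
        raise ValueError("compute_K requires delta > 0, D > 0, L > 0")
    return 1.0 / (2.0 * delta) + L / (4.0 * math.sqrt(delta * D))


@dataclass(frozen=True)
class MechanisticParams:
    """Mechanistic lattice/growth-factor parameters (rates in 1/s, lengths in cm)."""

    alpha: float = 1e-5
    rho: float = 1e-2
    delta: float = 1e-3
    D: float = 5e-9
    L: float = 0.2
    N: int = 100
    mu: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha", "rho", "delta", "D", "L"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.N <= 0:
            raise ValueError("N must be a positive integer")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    @property
    def d(self) -> float:
        """Lattice site diameter d = L/N (cm)."""
        return self.L / self.N

    @property
    def K(self) -> float:
        return compute_K(self.delta, self.D, self.L)


@dataclass(frozen=True)
class PhenomParams:
    """Reduced growth-law parameters: Gamma(n) = A + B*n, death rate mu.

    ``time_unit`` records whether the rates are per second (mechanistic
    reductions) or per hour (growth-curve fits); conversions are explicit.
    """

    A: float
    B: float
    mu: float
    time_unit: str = "seconds"

    def __post_init__(self) -> None:
        if self.time_unit not in _TIME_UNITS:
            raise ValueError(f"time_unit must be one of {_TIME_UNITS}")
        if self.A < 0:
            raise ValueError("A must be >= 0")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.B < -self.A:
            raise ValueError("B >= -A required so Gamma(n) >= 0 on [0, 1]")

    def to_unit(self, unit: str) -> "PhenomParams":
        if unit not in _TIME_UNITS:
            raise ValueError(f"time_unit must be one of {_TIME_UNITS}")
        if unit == self.time_unit:
            return self
        factor = SECONDS_PER_HOUR if unit == "hours" else 1.0 / SECONDS_PER_HOUR
        return PhenomParams(self.A * factor, self.B * factor, self.mu * factor, unit)


#: Baseline mechanistic parameter set (mu varied per experiment).
BASELINE = MechanisticParams()


def reduce_params(mech: MechanisticParams) -> PhenomParams:
    """Mean-field reduction of the mechanistic parameters to (A, B, mu)."""
    K = mech.K
    local = mech.alpha * mech.rho * K / mech.N
    A = mech.alpha + local
    B = mech.alpha * mech.rho / mech.delta - local
    return PhenomParams(A=A, B=B, mu=mech.mu, time_unit="seconds")


def _f(n: float, A: float, B: float, mu: float) -> float:
    return (A + B * n) * n * (1.0 - n) - mu * n


def _fprime(n: float, A: float, B: float, mu: float) -> float:
    # d/dn [(A + B n) n (1-n) - mu n] = A + 2(B-A) n - 3 B n^2 - mu
    return A - mu + 2.0 * (B - A) * n - 3.0 * B * n * n


def growth_rate(n: float, p: PhenomParams) -> float:
    """Population growth rate f(n) = (A + B*n)*n*(1-n) - mu*n for n in [0, 1]."""
    if not 0.0 <= n <= 1.0:
        raise ValueError(f"density n={n} outside [0, 1]")
    return _f(n, p.A, p.B, p.mu)


def critical_death_rate(p: PhenomParams) -> float:
    """Death rate above which the extinction state is stable: mu_c = Gamma(0) = A."""
    return p.A


def classify_allee(p: PhenomParams) -> str:
    """Classify the growth law as 'strong', 'weak' or 'none'.

    Strong: mu >= A (extinction state stable; ties counted as strong).
    Weak: per-capita rate (A + B*n)*(1-n) - mu increasing at n=0, i.e. B > A.
    """
    if p.mu >= p.A:
        return "strong"
    if p.B > p.A:
        return "weak"
    return "none"


def _interior_roots(p: PhenomParams) -> list[float]:
    """Real roots of (A + B*n)*(1 - n) = mu, ascending."""
    A, B, mu = p.A, p.B, p.mu
    if B == 0.0:
        if A == 0.0:
            return []
        return [(A - mu) / A]
    disc = (A - B) ** 2 - 4.0 * B * (mu - A)
    if disc < 0.0:
        return []
    sq = math.sqrt(disc)
    r1 = (-(A - B) - sq) / (2.0 * B)
    r2 = (-(A - B) + sq) / (2.0 * B)
    return sorted([r1, r2])


def critical_density(p: PhenomParams) -> Optional[float]:
    """Extinction threshold n_c for a strong Allee effect, else None.

    n_c is the smaller root of B*n^2 + (A-B)*n + (mu-A) = 0 when it lies in
    (0, 1) with f'(n_c) > 0.  Returns 0.0 at the marginal case mu == A.
    """
    if classify_allee(p) != "strong":
        return None
    if p.mu == p.A:
        return 0.0
    roots = [r for r in _interior_roots(p) if 0.0 < r < 1.0]
    for r in roots:
        if _fprime(r, p.A, p.B, p.mu) > 0.0:
            return r
    return None


def fixed_points(p: PhenomParams) -> list[tuple[float, str]]:
    """All equilibria of f on [0, 1] with their linear stability.

    Returns ``(n_star, label)`` pairs sorted by density; label is
    'stable' (f'(n*) < 0), 'unstable' (f'(n*) > 0) or 'marginal'.
    """
    pts = [0.0]
    for r in _interior_roots(p):
        if 0.0 < r <= 1.0:
            pts.append(r)
    out = []
    for n_star in sorted(set(pts)):
        slope = _fprime(n_star, p.A, p.B, p.mu)
        if slope < 0.0:
            label = "stable"
        elif slope > 0.0:
            label = "unstable"
        else:
            label = "marginal"
        out.append((n_star, label))
    return out


def euler_solve(
    p: PhenomParams,
    n0: float,
    T: float,
    dt: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-Euler integration of dn/dt = f(n), clipped to [0, 1].

    Times are in the unit of ``p``; the default step is 0.25 h for hourly
    parameters and its equivalent (900 s) for per-second parameters.

    Returns ``(times, densities)`` including t=0.
    """
    if not 0.0 <= n0 <= 1.0:
        raise ValueError("n0 must lie in [0, 1]")
    if T < 0:
        raise ValueError("T must be >= 0")
    if dt is None:
        dt = 0.25 if p.time_unit == "hours" else 0.25 * SECONDS_PER_HOUR
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_steps = int(math.ceil(T / dt - 1e-12)) if T > 0 else 0
    times = np.empty(n_steps + 1)
    dens = np.empty(n_steps + 1)
    times[0] = 0.0
    dens[0] = n0
    n = n0
    A, B, mu = p.A, p.B, p.mu
    for k in range(1, n_steps + 1):
        n = n + dt * _f(n, A, B, mu)
        n = min(max(n, 0.0), 1.0)
        times[k] = k * dt
        dens[k] = n
    return times, dens
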