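"""Least-squares fitting of the Allee growth law to multi-density curves.

The error function sums, over curves m with k_m retained points each,

    E(theta) = sum_m (1/k_m) sum_i (n(t_i; theta) - N_m(t_i))^2

where n(.; theta) is the forward-Euler solution of
dn/dt = (A + B*n)*n*(1-n) - mu*n started from each curve's first retained
data point.  The nested logistic model fixes B = 0.  Model comparison uses
AIC = 2k + n*log(E_min); note E_min here is the error E itself (the model
error above), not a root-mean-square quantity, and n counts all retained
points across curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import minimize
from scipy.stats import qmc

from .meanfield import PhenomParams, classify_allee, critical_density

__all__ = [
    "GrowthCurveSet",
    "FitResult",
    "objective",
    "fit_model",
    "aic",
    "model_selection",
]

DEFAULT_DT_HOURS = 0.25

#: Default search boxes (per hour), wide enough for typical confluency fits.
DEFAULT_BOUNDS_ALLEE = ((1e-4, 4.0), (-0.5, 8.0), (0.0, 4.0))   # A, B, mu
DEFAULT_BOUNDS_LOGISTIC = ((1e-4, 4.0), (0.0, 4.0))             # A, mu


@dataclass
class GrowthCurveSet:
    """Replicate-averaged normalized growth curves on per-curve time grids.

    ``curves`` maps a curve label (e.g. the seeding density) to a
    ``(times_h, density)`` pair with densities in [0, 1] and strictly
    increasing times in hours.
    """

    curves: dict[str, tuple[np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("GrowthCurveSet requires at least one curve")
        clean = {}
        for label, (t, y) in self.curves.items():
            t = np.asarray(t, dtype=float)
            y = np.asarray(y, dtype=float)
            if t.ndim != 1 or t.shape != y.shape or t.size < 1:
                raise ValueError(f"curve {label!r}: times/densities must be equal-length 1-D")
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"curve {label!r}: times must be strictly increasing")
            if np.any(y < 0) or np.any(y > 1):
                raise ValueError(f"curve {label!r}: densities must lie in [0, 1]")
            clean[str(label)] = (t, y)
        self.curves = clean

    @property
    def n_points(self) -> int:
        return sum(t.size for t, _ in self.curves.values())

    def discard_before(self, t_min_hours: float) -> "GrowthCurveSet":
        """Drop points earlier than ``t_min_hours`` (seeding-effect window)."""
        out = {}
        for label, (t, y) in self.curves.items():
            keep = t >= t_min_hours
            if keep.sum() == 0:
                raise ValueError(f"curve {label!r} has no points at t >= {t_min_hours} h")
            out[label] = (t[keep], y[keep])
        return GrowthCurveSet(out)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "GrowthCurveSet":
        """Build from long-format columns curve_id, time_h, density
        (an optional ``replicate`` column is averaged out per time point)."""
        required = {"curve_id", "time_h", "density"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"growth-curve table is missing columns: {sorted(missing)}")
        if "replicate" in df.columns:
            df = df.groupby(["curve_id", "time_h"], as_index=False)["density"].mean()
        curves = {}
        for label, sub in df.groupby("curve_id"):
            sub = sub.sort_values("time_h")
            curves[str(label)] = (
                sub["time_h"].to_numpy(float),
                np.clip(sub["density"].to_numpy(float), 0.0, 1.0),
            )
        return cls(curves)

    @classmethod
    def read_csv(cls, path) -> "GrowthCurveSet":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label, (t, y) in self.curves.items():
            rows.append(pd.DataFrame({"curve_id": label, "time_h": t, "density": y}))
        return pd.concat(rows, ignore_index=True)


@njit(cache=True)
def _curve_sse(A, B, mu, t, y, dt):
    """Sum of squared residuals of the Euler model against one curve.

    The model starts from (t[0], y[0]); values at observation times are
    linearly interpolated from the Euler grid.
    """
    n = y[0]
    tc = t[0]
    sse = 0.0
    i = 1
    k = t.shape[0]
    while i < k:
        fn = (A + B * n) * n * (1.0 - n) - mu * n
        nn = n + dt * fn
        if nn < 0.0:
            nn = 0.0
        elif nn > 1.0:
            nn = 1.0
        tn = tc + dt
        while i < k and t[i] <= tn + 1e-9:
            w = (t[i] - tc) / dt
            m = n + w * (nn - n)
            r = m - y[i]
            sse += r * r
            i += 1
        n = nn
        tc = tn
    return sse


def _pack(curves: GrowthCurveSet):
    ts = [t for t, _ in curves.curves.values()]
    ys = [y for _, y in curves.curves.values()]
    return ts, ys


def objective(
    theta: Sequence[float],
    curves: GrowthCurveSet,
    dt_hours: float = DEFAULT_DT_HOURS,
) -> float:
    """E(theta) for theta = (A, B, mu) in 1/h against ``curves``."""
    A, B, mu = (float(v) for v in theta)
    ts, ys = _pack(curves)
    total = 0.0
    for t, y in zip(ts, ys):
        total += _curve_sse(A, B, mu, t, y, dt_hours) / t.size
    return total


@dataclass
class FitResult:
    model: str                      # "allee" or "logistic"
    params: PhenomParams            # per-hour rates; B == 0 for logistic
    e_min: float
    n_points: int
    k_params: int
    aic: Optional[float]            # None when e_min == 0 (perfect fit)
    perfect_fit: bool = False
    n_starts: int = 0
    start_errors: list = field(default_factory=list, repr=False)


def aic(k_params: int, n_points: int, e_min: float) -> float:
    """Akaike information criterion 2k + n*log(E_min)."""
    if n_points <= 0:
        raise ValueError("n_points must be > 0")
    if e_min <= 0:
        raise ValueError(
            "E_min must be > 0 (a perfect fit has undefined AIC; report a perfect-fit flag)"
        )
    return 2.0 * k_params + n_points * math.log(e_min)


def fit_model(
    curves: GrowthCurveSet,
    model: str = "allee",
    n_starts: int = 16,
    seed: int = 0,
    dt_hours: float = DEFAULT_DT_HOURS,
    bounds: Optional[tuple] = None,
) -> FitResult:
    """Multistart Nelder-Mead minimization of the curve error.

    Starts are a Latin-hypercube sample of the bounded box; constraints
    A >= 0, mu >= 0, B >= -A are enforced by penalty.  Ties are broken by
    lowest error, then lowest A.  Deterministic given ``seed``.
    """
    if model not in ("allee", "logistic"):
        raise ValueError("model must be 'allee' or 'logistic'")
    ts, ys = _pack(curves)
    n_points = curves.n_points
    if bounds is None:
        bounds = DEFAULT_BOUNDS_ALLEE if model == "allee" else DEFAULT_BOUNDS_LOGISTIC
    bounds = np.asarray(bounds, dtype=float)
    ndim = bounds.shape[0]
    expected = 3 if model == "allee" else 2
    if ndim != expected:
        raise ValueError(f"{model} fit needs {expected} parameter bounds, got {ndim}")

    def unpack(x):
        if model == "allee":
            return float(x[0]), float(x[1]), float(x[2])
        return float(x[0]), 0.0, float(x[1])

    def penalized(x):
        A, B, mu = unpack(x)
        viol = max(0.0, -A) + max(0.0, -mu) + max(0.0, -(B + A))
        if viol > 0.0:
            return 1e6 * (1.0 + viol)
        total = 0.0
        for t, y in zip(ts, ys):
            total += _curve_sse(A, B, mu, t, y, dt_hours) / t.size
        return total

    sampler = qmc.LatinHypercube(d=ndim, seed=seed)
    starts = qmc.scale(sampler.random(n=n_starts), bounds[:, 0], bounds[:, 1])

    best = None
    errors = []
    for x0 in starts:
        res = minimize(
            penalized,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-14, "maxiter": 4000},
        )
        errors.append(float(res.fun))
        cand = (float(res.fun), unpack(res.x))
        if best is None or cand[0] < best[0] - 1e-15 or (
            abs(cand[0] - best[0]) <= 1e-15 and cand[1][0] < best[1][0]
        ):
            best = cand
    if best is None or not np.isfinite(best[0]) or best[0] >= 1e6:
        raise RuntimeError(
            f"{model} fit failed to converge from any of {n_starts} starts; "
            f"best objective values: {sorted(errors)[:3]}"
        )
    e_min, (A, B, mu) = best
    params = PhenomParams(A=A, B=B, mu=mu, time_unit="hours")
    perfect = e_min <= 0.0
    return FitResult(
        model=model,
        params=params,
        e_min=e_min,
        n_points=n_points,
        k_params=expected,
        aic=None if perfect else aic(expected, n_points, e_min),
        perfect_fit=perfect,
        n_starts=n_starts,
        start_errors=errors,
    )


def model_selection(
    curves: GrowthCurveSet,
    seed: int = 0,
    n_starts: int = 16,
    dt_hours: float = DEFAULT_DT_HOURS,
) -> dict:
    """Fit both models, compare AICs and classify the winning growth law."""
    fit_allee = fit_model(curves, "allee", n_starts=n_starts, seed=seed, dt_hours=dt_hours)
    fit_log = fit_model(curves, "logistic", n_starts=n_starts, seed=seed, dt_hours=dt_hours)
    if fit_allee.aic is not None and fit_log.aic is not None:
        delta = fit_allee.aic - fit_log.aic
        selected = "allee" if fit_allee.aic < fit_log.aic else "logistic"
    else:
        # perfect fits have undefined AIC; prefer the simpler model on a tie
        delta = None
        selected = "allee" if (fit_allee.perfect_fit and not fit_log.perfect_fit) else "logistic"
    winner = fit_allee if selected == "allee" else fit_log
    classification = classify_allee(winner.params)
    n_c = critical_density(winner.params) if classification == "strong" else None
    return {
        "allee": fit_allee,
        "logistic": fit_log,
        "aic_allee": fit_allee.aic,
        "aic_logistic": fit_log.aic,
        "delta_aic": delta,
        "selected": selected,
        "classification": classification,
        "n_c": n_c,
    }
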