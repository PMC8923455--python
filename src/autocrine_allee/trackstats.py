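"""Mean-squared-displacement analysis of cell tracks.

Tracks are centred at the origin and shifted to t = 0, the MSD at each
frame time is the average squared distance from the origin over all tracks
observed at that time, points beyond a 10 h cutoff are discarded, and the
diffusion coefficient follows from a through-the-origin least-squares line
via MSD(t) = 4*D*t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackSet",
    "MSDResult",
    "normalize_tracks",
    "compute_msd",
    "estimate_diffusion",
    "average_diffusion",
]

DEFAULT_T_MAX_S = 10.0 * 3600.0

# tolerated deviation of a sample time from the frame grid, as a fraction
# of the frame interval
_SNAP_TOL = 0.1


@dataclass
class Track:
    track_id: str
    t: np.ndarray  # seconds
    x: np.ndarray  # cm
    y: np.ndarray  # cm
    label: Optional[str] = None  # e.g. well or cell line

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape) or self.t.ndim != 1:
            raise ValueError(f"track {self.track_id!r}: t, x, y must be equal-length 1-D")
        if self.t.size < 2:
            raise ValueError(f"track {self.track_id!r}: needs at least 2 time points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError(f"track {self.track_id!r}: times must be strictly increasing")


@dataclass
class TrackSet:
    tracks: list[Track]
    frame_interval: float  # seconds

    def __post_init__(self) -> None:
        if not self.tracks:
            raise ValueError("TrackSet requires at least one track")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, frame_interval: float) -> "TrackSet":
        """Long format: track_id, t_s, x_cm, y_cm (optional label column).

        Tracks with fewer than 2 frames are dropped (cells leaving the
        field of view); the dropped count is recorded on the result.
        """
        required = {"track_id", "t_s", "x_cm", "y_cm"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"track table is missing columns: {sorted(missing)}")
        tracks = []
        dropped = 0
        for tid, sub in df.groupby("track_id"):
            sub = sub.sort_values("t_s")
            if len(sub) < 2:
                dropped += 1
                continue
            label = str(sub["label"].iloc[0]) if "label" in sub.columns else None
            tracks.append(
                Track(
                    track_id=str(tid),
                    t=sub["t_s"].to_numpy(float),
                    x=sub["x_cm"].to_numpy(float),
                    y=sub["y_cm"].to_numpy(float),
                    label=label,
                )
            )
        if not tracks:
            raise ValueError("no usable tracks (all shorter than 2 frames)")
        ts = cls(tracks=tracks, frame_interval=frame_interval)
        ts.n_dropped = dropped
        return ts

    @classmethod
    def read_csv(cls, path, frame_interval: float) -> "TrackSet":
        return cls.from_dataframe(pd.read_csv(path), frame_interval)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            d = pd.DataFrame({"track_id": tr.track_id, "t_s": tr.t, "x_cm": tr.x, "y_cm": tr.y})
            if tr.label is not None:
                d["label"] = tr.label
            rows.append(d)
        return pd.concat(rows, ignore_index=True)


@dataclass
class MSDResult:
    times: np.ndarray   # seconds, frame-grid times <= t_max
    msd: np.ndarray     # cm^2
    counts: np.ndarray  # number of tracks contributing at each time


def normalize_tracks(raw: TrackSet) -> TrackSet:
    """Translate every track so it starts at (0, 0) at t = 0 (idempotent)."""
    out = [
        Track(
            track_id=tr.track_id,
            t=tr.t - tr.t[0],
            x=tr.x - tr.x[0],
            y=tr.y - tr.y[0],
            label=tr.label,
        )
        for tr in raw.tracks
    ]
    return TrackSet(tracks=out, frame_interval=raw.frame_interval)


def _snap_to_grid(t: np.ndarray, dt: float, track_id: str) -> np.ndarray:
    k = np.rint(t / dt)
    if np.any(np.abs(t - k * dt) > _SNAP_TOL * dt):
        worst = float(np.max(np.abs(t - k * dt)))
        raise ValueError(
            f"track {track_id!r}: sample times deviate from the {dt} s frame grid "
            f"by up to {worst} s (> {_SNAP_TOL:.0%} of the frame interval)"
        )
    return k.astype(np.int64)


def compute_msd(tracks: TrackSet, t_max: float = DEFAULT_T_MAX_S) -> MSDResult:
    """MSD(t_k) = mean over tracks observed at t_k of |x(t_k)|^2, t_k <= t_max."""
    dt = tracks.frame_interval
    k_max = int(np.floor(t_max / dt + 1e-9))
    sums = np.zeros(k_max + 1)
    counts = np.zeros(k_max + 1, dtype=np.int64)
    for tr in tracks.tracks:
        if abs(tr.t[0]) > _SNAP_TOL * dt or np.hypot(tr.x[0], tr.y[0]) != 0.0:
            raise ValueError(
                f"track {tr.track_id!r} is not normalized; call normalize_tracks first"
            )
        ks = _snap_to_grid(tr.t, dt, tr.track_id)
        keep = ks <= k_max
        r2 = tr.x[keep] ** 2 + tr.y[keep] ** 2
        np.add.at(sums, ks[keep], r2)
        np.add.at(counts, ks[keep], 1)
    observed = counts > 0
    if not observed.any():
        raise ValueError(f"no track covers any frame time <= {t_max} s")
    times = np.arange(k_max + 1)[observed] * dt
    msd = sums[observed] / counts[observed]
    return MSDResult(times=times, msd=msd, counts=counts[observed])


def estimate_diffusion(msd_series: MSDResult | tuple[np.ndarray, np.ndarray]) -> float:
    """Diffusion coefficient from the zero-intercept line MSD(t) = 4*D*t.

    The slope is the through-the-origin least-squares estimate
    sum(t*MSD)/sum(t^2); D = slope/4.
    """
    if isinstance(msd_series, MSDResult):
        t, m = msd_series.times, msd_series.msd
    else:
        t, m = (np.asarray(a, dtype=float) for a in msd_series)
    if t.size < 2:
        raise ValueError("need at least 2 MSD points")
    denom = float(np.sum(t * t))
    if denom == 0.0:
        raise ValueError("all MSD times are zero; slope is undefined")
    slope = float(np.sum(t * m)) / denom
    return slope / 4.0


def average_diffusion(per_group_Ds: Iterable[float]) -> float:
    """Arithmetic mean diffusion coefficient over densities/replicates/lines."""
    vals = np.asarray(list(per_group_Ds), dtype=float)
    if vals.size == 0:
        raise ValueError("average_diffusion requires at least one value")
    return float(vals.mean())
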