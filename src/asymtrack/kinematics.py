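"""Per-track translocation kinematics.

Implements the quantities used to characterise basal soma translocation of
retinal progenitors after division: maximum basal position, instantaneous
step velocities, time-averaged mean squared displacement (MSD) within a
window after mitosis, directionality ratio, and the integral-mean depth

    d_hat = I / T,   I = integral_0^T depth(t) dt,

i.e. the time average of the depth trajectory (the area below the
depth-vs-time curve divided by track duration).

All operations work on the recorded timestamps; nothing is resampled.  By
default displacements are measured along the apicobasal axis only
(depth-only, 1-D); ``use_planar=True`` switches to Euclidean displacement
on all available coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tracks import Track, ValidationError

__all__ = [
    "MsdCurve",
    "DirectionalityCurve",
    "KinematicsSummary",
    "max_basal_position",
    "instantaneous_velocity",
    "msd",
    "directionality_ratio",
    "integral_mean",
    "summarize_track",
    "summarize_tracks",
]

DEFAULT_MSD_WINDOW = 100.0  # minutes after mitosis


@dataclass
class MsdCurve:
    """Time-averaged MSD versus lag.

    ``lags`` are positive multiples of the base sampling interval (minutes),
    ``msd`` the mean squared displacement (µm²) over all overlapping ordered
    sample pairs at that lag, ``n_pairs`` the pair count entering each lag.
    ``window`` records the restriction t <= window applied before computing.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_pairs: np.ndarray
    window: float

    def slope(self) -> float:
        """Least-squares slope of MSD vs lag through the origin-free fit (µm²/min)."""
        if len(self.lags) < 2:
            return float("nan")
        return float(np.polyfit(self.lags, self.msd, 1)[0])


@dataclass
class DirectionalityCurve:
    """Net-over-path displacement ratio at each sample time > 0.

    The ratio is 1 for perfectly straight motion and decreases with
    backtracking; it lies in [0, 1] by the triangle inequality.
    """

    times: np.ndarray
    ratio: np.ndarray

    def final(self) -> float:
        return float(self.ratio[-1]) if len(self.ratio) else float("nan")


@dataclass
class KinematicsSummary:
    track_id: str
    max_basal: float
    t_max_basal: float
    mean_inst_velocity: float
    integral_mean: float
    integral_area: float
    duration: float
    msd: MsdCurve
    directionality: DirectionalityCurve
    censored: bool = False
    fate: str = "UNKNOWN"
    pair_id: str | None = None
    embryo_id: str | None = None


def max_basal_position(track: Track) -> tuple[float, float]:
    """Maximum depth attained and the earliest time it is attained."""
    i = int(np.argmax(track.depth))  # argmax returns the first maximum
    return float(track.depth[i]), float(track.t[i])


def instantaneous_velocity(
    track: Track, use_planar: bool = False, time_weighted: bool = False
) -> tuple[np.ndarray, float]:
    """Per-step speeds |displacement|/dt and their average (µm/min).

    The average is unweighted over steps (the sampling is uniform in
    practice); ``time_weighted=True`` weights each step by its dt instead,
    which equals path length / duration.
    """
    pos = track.positions(use_planar)
    dt = np.diff(track.t)
    if np.any(dt <= 0):
        raise ValidationError(f"track {track.track_id}: non-positive time step")
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    v = step / dt
    if time_weighted:
        mean = float(np.sum(step) / np.sum(dt))
    else:
        mean = float(np.mean(v))
    return v, mean


def _base_interval(t: np.ndarray) -> float:
    return float(np.median(np.diff(t)))


def msd(
    track: Track,
    window: float = DEFAULT_MSD_WINDOW,
    use_planar: bool = False,
    min_pairs: int = 2,
) -> MsdCurve:
    """Time-averaged MSD over overlapping sample pairs within ``window``.

    Samples are restricted to t <= window (the first ``window`` minutes
    after mitosis).  Lags are multiples of the median sampling interval;
    every ordered pair (t_i, t_j), t_j > t_i, whose separation matches a
    lag multiple contributes its squared displacement.  Lags supported by
    fewer than ``min_pairs`` pairs are dropped to keep the tail of the
    curve from resting on single pairs.
    """
    keep = track.t <= window + 1e-9
    t = track.t[keep]
    if len(t) < 2:
        raise ValidationError(
            f"track {track.track_id}: fewer than 2 samples within the {window}-min window"
        )
    pos = track.positions(use_planar)[keep]
    base = _base_interval(t)
    n = len(t)
    # all ordered pairs; n is small (a 100-min window at 5-min cadence is 21 points)
    i, j = np.triu_indices(n, k=1)
    tau = t[j] - t[i]
    k = np.rint(tau / base).astype(int)
    on_grid = np.abs(tau - k * base) <= 1e-6 * base + 1e-12
    sq = np.sum((pos[j] - pos[i]) ** 2, axis=1)
    lags, msds, counts = [], [], []
    for kk in np.unique(k[on_grid]):
        if kk < 1:
            continue
        sel = on_grid & (k == kk)
        if np.count_nonzero(sel) < min_pairs:
            continue
        lags.append(kk * base)
        msds.append(float(np.mean(sq[sel])))
        counts.append(int(np.count_nonzero(sel)))
    return MsdCurve(
        lags=np.asarray(lags, dtype=float),
        msd=np.asarray(msds, dtype=float),
        n_pairs=np.asarray(counts, dtype=int),
        window=float(window),
    )


def directionality_ratio(track: Track, use_planar: bool = False) -> DirectionalityCurve:
    """Net displacement over cumulative path length at each time point.

    At a time point with zero accumulated path length the cell has not
    moved, and the ratio is defined as 1.
    """
    pos = track.positions(use_planar)
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    path = np.cumsum(step)
    net = np.linalg.norm(pos[1:] - pos[0], axis=1)
    ratio = np.ones_like(path)
    moving = path > 0
    ratio[moving] = net[moving] / path[moving]
    return DirectionalityCurve(times=track.t[1:].copy(), ratio=ratio)


def integral_mean(track: Track) -> tuple[float, float, float]:
    """Integral-mean depth of a trajectory: (d_hat, I, T).

    I is the area below the depth(t) curve by trapezoidal quadrature over
    the recorded timestamps (exact for the piecewise-linear trajectories
    that point tracking produces), T the track duration, d_hat = I/T.
    """
    if track.n_samples < 2:
        raise ValidationError(f"track {track.track_id}: integral mean needs >= 2 samples")
    T = track.duration
    if T <= 0:
        raise ValidationError(f"track {track.track_id}: non-positive duration")
    I = float(np.trapezoid(track.depth, track.t))
    return I / T, I, T


def summarize_track(
    track: Track, window: float = DEFAULT_MSD_WINDOW, use_planar: bool = False
) -> KinematicsSummary:
    """All per-track kinematics in one record (same coordinate convention throughout)."""
    try:
        mb, t_mb = max_basal_position(track)
        _, mean_v = instantaneous_velocity(track, use_planar=use_planar)
        d_hat, area, duration = integral_mean(track)
        curve = msd(track, window=window, use_planar=use_planar)
        direc = directionality_ratio(track, use_planar=use_planar)
    except ValidationError:
        raise
    except Exception as exc:  # pragma: no cover - defensive context wrapping
        raise ValidationError(f"track {track.track_id}: {exc}") from exc
    return KinematicsSummary(
        track_id=track.track_id,
        max_basal=mb,
        t_max_basal=t_mb,
        mean_inst_velocity=mean_v,
        integral_mean=d_hat,
        integral_area=area,
        duration=duration,
        msd=curve,
        directionality=direc,
        censored=track.censored,
        fate=track.fate.value,
        pair_id=track.pair_id,
        embryo_id=track.embryo_id,
    )


def summarize_tracks(
    tracks: list[Track], window: float = DEFAULT_MSD_WINDOW, use_planar: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Batch kinematics: (scalar summary, long MSD curves, long directionality curves)."""
    summaries = [summarize_track(tr, window=window, use_planar=use_planar) for tr in tracks]
    scalar = pd.DataFrame(
        {
            "track_id": [s.track_id for s in summaries],
            "embryo_id": [s.embryo_id for s in summaries],
            "pair_id": [s.pair_id for s in summaries],
            "fate": [s.fate for s in summaries],
            "max_basal_um": [s.max_basal for s in summaries],
            "t_max_basal_min": [s.t_max_basal for s in summaries],
            "mean_inst_velocity_um_per_min": [s.mean_inst_velocity for s in summaries],
            "integral_mean_um": [s.integral_mean for s in summaries],
            "integral_area_um_min": [s.integral_area for s in summaries],
            "duration_min": [s.duration for s in summaries],
            "final_directionality": [s.directionality.final() for s in summaries],
            "censored": [s.censored for s in summaries],
        }
    )
    msd_rows = []
    dir_rows = []
    for s in summaries:
        for lag, m, npairs in zip(s.msd.lags, s.msd.msd, s.msd.n_pairs):
            msd_rows.append(
                {"track_id": s.track_id, "fate": s.fate, "lag_min": lag, "msd_um2": m, "n_pairs": npairs}
            )
        for t, r in zip(s.directionality.times, s.directionality.ratio):
            dir_rows.append({"track_id": s.track_id, "fate": s.fate, "time_min": t, "ratio": r})
    msd_long = pd.DataFrame(msd_rows, columns=["track_id", "fate", "lag_min", "msd_um2", "n_pairs"])
    dir_long = pd.DataFrame(dir_rows, columns=["track_id", "fate", "time_min", "ratio"])
    return scalar, msd_long, dir_long
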