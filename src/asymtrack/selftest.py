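"""Built-in oracle/property battery.

Each check recomputes a quantity two independent ways — the pipeline
implementation versus a closed form, a brute-force oracle or a known
simulation truth — under a fixed internal seed, so a fresh install can be
verified from the command line without the test suite.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from . import asymmetry, kinematics, spatial, synthetic
from .io_tracks import Fate, Track, tracks_to_frame
from .stats import wilson_interval

__all__ = ["run_selftest", "random_piecewise_linear_track"]

SELFTEST_SEED = 20201103


def random_piecewise_linear_track(
    rng: np.random.Generator, n_max: int = 30, depth_max: float = 60.0, track_id: str = "pl"
) -> Track:
    """A random piecewise-linear depth trajectory on a jittered time grid."""
    n = int(rng.integers(3, n_max + 1))
    t = np.concatenate([[0.0], np.cumsum(rng.uniform(1.0, 8.0, size=n - 1))])
    depth = rng.uniform(0.0, depth_max, size=n)
    return Track(
        track_id=track_id, embryo_id="E1", pair_id=None, fate=Fate.UNKNOWN, t=t, depth=depth
    )


def riemann_integral_mean(track: Track, n_sub: int = 10_000) -> float:
    """Midpoint Riemann-sum oracle for the integral-mean depth."""
    t0, t1 = track.t[0], track.t[-1]
    h = (t1 - t0) / n_sub
    mids = t0 + (np.arange(n_sub) + 0.5) * h
    return float(np.sum(np.interp(mids, track.t, track.depth)) * h / (t1 - t0))


def _check_quadrature(rng, n_tracks=200) -> tuple[bool, str]:
    worst = 0.0
    for _ in range(n_tracks):
        tr = random_piecewise_linear_track(rng)
        d_hat, _, _ = kinematics.integral_mean(tr)
        oracle = riemann_integral_mean(tr)
        rel = abs(d_hat - oracle) / max(abs(oracle), 1e-12)
        worst = max(worst, rel)
    return worst < 1e-6, f"max relative error {worst:.2e} over {n_tracks} tracks"


def _check_ballistic(rng) -> tuple[bool, str]:
    v = 1.0
    t = np.arange(0, 105, 5.0)
    tr = Track("ball", "E1", None, Fate.UNKNOWN, t=t, depth=v * t)
    curve = kinematics.msd(tr, window=100.0)
    ok = np.allclose(curve.msd, (v * curve.lags) ** 2, rtol=1e-12)
    direc = kinematics.directionality_ratio(tr)
    ok &= bool(np.allclose(direc.ratio, 1.0))
    flat = Track("flat", "E1", None, Fate.UNKNOWN, t=t, depth=np.full_like(t, 7.0))
    ok &= bool(np.allclose(kinematics.msd(flat, window=100.0).msd, 0.0))
    return bool(ok), "MSD(tau)=v^2 tau^2, ratio=1 on ballistic; MSD=0 stationary"


def _check_normalization(rng) -> tuple[bool, str]:
    spots = synthetic.simulate_spots(6, 80, 60.0, rng=rng)
    table = spatial.spot_ratios(spots, n_rois=3)
    sums = table.groupby(["slice_id", "marker"])["ratio"].sum()
    ok = bool(np.allclose(sums, 1.0))
    return ok, "per-slice spot ratios sum to 1"


def _check_fate_recovery(rng, n_cohorts=20, n_pairs=100) -> tuple[bool, str]:
    fate = synthetic.FateModel(p_sym_neuro=0.08)
    hits = 0
    for _ in range(n_cohorts):
        classes = synthetic.draw_division_classes(fate, n_pairs, rng)
        k = int(np.sum(classes == "ASYMMETRIC"))
        lo, hi = wilson_interval(k, n_pairs)
        hits += lo <= fate.p_asym <= hi
    ok = hits >= int(0.85 * n_cohorts)
    return ok, f"true asymmetric fraction inside Wilson CI in {hits}/{n_cohorts} cohorts"


def _check_conservation(rng) -> tuple[bool, str]:
    cfg = synthetic.preset("control", seed=int(rng.integers(2**31)), n_pairs=50)
    cohort = synthetic.simulate_cohort(cfg)
    from .io_tracks import pair_sisters

    pairs = pair_sisters(cohort.tracks).pairs
    ok = True
    for p in pairs:
        summ = asymmetry.endosome_partition(p)
        ok &= summ.count_a + summ.count_b == summ.total
    thickness = cfg.motion_pos.tissue_thickness
    for tr in cohort.tracks:
        ok &= bool(np.all((tr.depth >= 0) & (tr.depth <= thickness)))
    return bool(ok), "endosome counts conserved; depths inside the tissue"


def _check_determinism(rng) -> tuple[bool, str]:
    seed = int(rng.integers(2**31))
    cfg = synthetic.preset("control", seed=seed, n_pairs=10)
    a = tracks_to_frame(synthetic.simulate_cohort(cfg).tracks).to_csv(index=False)
    b = tracks_to_frame(synthetic.simulate_cohort(cfg).tracks).to_csv(index=False)
    return a == b, "same config + seed gives byte-identical track tables"


CHECKS = [
    ("quadrature_oracle", _check_quadrature),
    ("ballistic_closed_form", _check_ballistic),
    ("ratio_normalization", _check_normalization),
    ("fate_parameter_recovery", _check_fate_recovery),
    ("conservation_and_bounds", _check_conservation),
    ("seed_determinism", _check_determinism),
]


def run_selftest(seed: int = SELFTEST_SEED) -> pd.DataFrame:
    """Run the battery and return a pass/fail table (one row per property)."""
    rows = []
    for name, fn in CHECKS:
        rng = np.random.default_rng([seed, zlib.crc32(name.encode())])
        try:
            ok, detail = fn(rng)
        except Exception as exc:  # a crash is a failure, not an error state
            ok, detail = False, f"raised {type(exc).__name__}: {exc}"
        rows.append({"check": name, "passed": bool(ok), "detail": detail})
    return pd.DataFrame(rows)
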