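"""Apicobasal spot-distribution quantification.

Punctate immunostaining signal (e.g. the Notch receptor or its Delta
ligand) is summarised per optical slice by splitting the apicobasal axis
into ``n_rois`` equal-length regions of interest (three by default:
apical, central, basal), counting spots per ROI, and normalising each
count by the slice's total so that the per-slice ratios sum to 1.  ROI
ratio distributions are then compared across slices with Welch's t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tracks import SpotRecord, ValidationError
from .stats import TestResult, welch_ttest

__all__ = [
    "RoiPartition",
    "DEFAULT_ROI_LABELS",
    "roi_index",
    "assign_rois",
    "spot_ratios",
    "compare_roi_groups",
]

DEFAULT_ROI_LABELS = ("APICAL", "CENTRAL", "BASAL")


@dataclass(frozen=True)
class RoiPartition:
    """Equal-length partition of a slice's apicobasal axis into ROIs."""

    n_rois: int = 3

    def labels(self) -> tuple[str, ...]:
        if self.n_rois == 3:
            return DEFAULT_ROI_LABELS
        return tuple(f"ROI_{k}" for k in range(self.n_rois))

    def boundaries(self, axis_length: float) -> np.ndarray:
        return np.linspace(0.0, axis_length, self.n_rois + 1)


def roi_index(positions: np.ndarray, axis_length: float, n_rois: int) -> np.ndarray:
    """ROI index (0 = apical-most) for each axis position.

    Intervals are half-open [k·L/n, (k+1)·L/n) with the basal-most
    interval closed, so a spot exactly at the basal boundary belongs to
    the last ROI and assignment is deterministic.
    """
    if n_rois < 2:
        raise ValidationError("roi_index: need at least 2 ROIs")
    pos = np.asarray(positions, dtype=float)
    idx = np.floor(pos * n_rois / axis_length).astype(int)
    return np.clip(idx, 0, n_rois - 1)


def assign_rois(spots: list[SpotRecord], n_rois: int = 3) -> pd.DataFrame:
    """Per-spot ROI assignment; each slice uses its own axis length."""
    part = RoiPartition(n_rois)
    labels = part.labels()
    rows = []
    for s in spots:
        k = int(roi_index(np.array([s.axis_position]), s.axis_length, n_rois)[0])
        rows.append(
            {
                "slice_id": s.slice_id,
                "region": s.region,
                "marker": s.marker,
                "axis_position_um": s.axis_position,
                "axis_length_um": s.axis_length,
                "roi_index": k,
                "roi_label": labels[k],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "slice_id",
            "region",
            "marker",
            "axis_position_um",
            "axis_length_um",
            "roi_index",
            "roi_label",
        ],
    )


def spot_ratios(
    spots: list[SpotRecord], n_rois: int = 3, per_embryo: bool = False
) -> pd.DataFrame:
    """Per-(slice, marker) ROI counts and total-normalised ratios.

    Every (slice, marker, ROI) combination is emitted, including zero
    counts, so the ratios of one slice always sum to 1 when the slice has
    any spots.  A slice with zero spots for a marker is emitted with NaN
    ratios and flagged ``empty``.  With ``per_embryo`` the ``region``
    column is used as the grouping unit instead of the slice (aggregating
    slices of the same region).
    """
    part = RoiPartition(n_rois)
    labels = part.labels()
    assigned = assign_rois(spots, n_rois)
    unit = "region" if per_embryo else "slice_id"
    units = sorted(assigned[unit].unique()) if len(assigned) else []
    rows = []
    for u in units:
        sub_u = assigned[assigned[unit] == u]
        for marker in sorted(sub_u["marker"].unique()):
            sub = sub_u[sub_u["marker"] == marker]
            counts = np.bincount(sub["roi_index"].to_numpy(), minlength=n_rois)
            total = int(counts.sum())
            for k in range(n_rois):
                rows.append(
                    {
                        unit: u,
                        "marker": marker,
                        "roi_label": labels[k],
                        "count": int(counts[k]),
                        "ratio": counts[k] / total if total > 0 else float("nan"),
                        "empty": total == 0,
                    }
                )
    return pd.DataFrame(rows, columns=[unit, "marker", "roi_label", "count", "ratio", "empty"])


def compare_roi_groups(
    table: pd.DataFrame, pairings: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Welch t-tests between ROI ratio distributions across slices.

    ``table`` is a :func:`spot_ratios` output.  For each (roi_a, roi_b)
    pairing and each marker, the per-slice ratios of the two ROIs are
    compared with an unpaired two-sided t-test with Welch's correction.
    Pairings where either group has fewer than 2 slices are skipped with a
    note.
    """
    if pairings is None:
        pairings = [("CENTRAL", "APICAL"), ("BASAL", "CENTRAL"), ("BASAL", "APICAL")]
    rows = []
    for marker in sorted(table["marker"].unique()):
        sub = table[(table["marker"] == marker) & (~table["empty"])]
        by_roi = {
            roi: grp["ratio"].to_numpy(dtype=float)
            for roi, grp in sub.groupby("roi_label")
        }
        for roi_a, roi_b in pairings:
            a = by_roi.get(roi_a, np.empty(0))
            b = by_roi.get(roi_b, np.empty(0))
            row = {
                "marker": marker,
                "roi_a": roi_a,
                "roi_b": roi_b,
                "n_a": len(a),
                "n_b": len(b),
                "mean_a": float(np.mean(a)) if len(a) else float("nan"),
                "mean_b": float(np.mean(b)) if len(b) else float("nan"),
                "sd_a": float(np.std(a, ddof=1)) if len(a) > 1 else float("nan"),
                "sd_b": float(np.std(b, ddof=1)) if len(b) > 1 else float("nan"),
            }
            if len(a) < 2 or len(b) < 2:
                row.update(t=float("nan"), df=float("nan"), p=float("nan"),
                           note="skipped: <2 slices in a group")
            else:
                res: TestResult = welch_ttest(a, b)
                row.update(t=res.statistic, df=res.df, p=res.p_value, note="")
            rows.append(row)
    return pd.DataFrame(rows)
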