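"""Reading, writing and validation of track, spot and pair tables.

The package works on point-tracked soma trajectories of neuroepithelial
progenitor cells.  All depths are measured along the apicobasal axis with
the apical surface at 0 µm and depth increasing basal-ward; time is in
minutes with t = 0 at the mitosis of the mother cell.  Tables are plain
CSV (comma separator, one header row, UTF-8, ``.`` decimal) so they can be
exported from any spreadsheet-based tracking workflow.

Tracks CSV columns
    track_id, embryo_id, pair_id, fate, time_min, depth_um
    [x_um, y_um, basal_process, endosome_count, end_event, division_time_min]

Spots CSV columns
    slice_id, marker, axis_position_um, axis_length_um [, region]
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AxisConvention",
    "Fate",
    "EndEvent",
    "Track",
    "SisterPair",
    "SpotRecord",
    "PairingResult",
    "FormatError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "tracks_to_frame",
    "read_spots",
    "write_spots",
    "spots_to_frame",
    "pair_sisters",
]

TRACK_COLUMNS = ["track_id", "embryo_id", "pair_id", "fate", "time_min", "depth_um"]
OPTIONAL_TRACK_COLUMNS = [
    "x_um",
    "y_um",
    "basal_process",
    "endosome_count",
    "end_event",
    "division_time_min",
]
SPOT_COLUMNS = ["slice_id", "marker", "axis_position_um", "axis_length_um"]


class FormatError(ValueError):
    """A table is structurally malformed (e.g. a required column is missing)."""


class ValidationError(ValueError):
    """A table parses but violates a domain invariant."""


class Fate(str, enum.Enum):
    """Neurogenic-commitment label of a daughter cell.

    ``ATH5_POS`` marks onset of the proneural reporter (neurogenic
    progenitor); ``ATH5_NEG`` marks a sister that stays in another lineage.
    """

    ATH5_POS = "ATH5_POS"
    ATH5_NEG = "ATH5_NEG"
    UNKNOWN = "UNKNOWN"


class EndEvent(str, enum.Enum):
    ROUNDING_ONSET = "ROUNDING_ONSET"
    CENSORED = "CENSORED"


@dataclass(frozen=True)
class AxisConvention:
    """Global apicobasal axis and time conventions.

    Depth 0 µm is the apical surface and depth increases toward the basal
    lamina; with this sign choice the most basal position a soma reaches is
    simply ``max(depth)``.  ``tissue_thickness`` (µm), when given, bounds
    every admissible depth.
    """

    apical_origin: bool = True
    basal_sign: int = 1
    tissue_thickness: float | None = None
    depth_units: str = "um"
    time_units: str = "min"

    def check_depths(self, depth: np.ndarray, context: str = "") -> None:
        if np.any(depth < 0):
            raise ValidationError(f"negative depth in {context or 'track'}")
        if self.tissue_thickness is not None and np.any(depth > self.tissue_thickness):
            raise ValidationError(
                f"depth exceeds tissue thickness {self.tissue_thickness} in {context or 'track'}"
            )


@dataclass
class Track:
    """One cell's soma trajectory from mother-cell mitosis to rounding.

    ``t`` starts at 0 (mitosis of the mother defines the time origin) and is
    strictly increasing; ``depth`` is the apicobasal position in µm.  Planar
    image coordinates ``x``/``y`` are optional — tracking is often done in
    maximum projections, so some datasets carry them and some do not.
    """

    track_id: str
    embryo_id: str
    pair_id: str | None
    fate: Fate
    t: np.ndarray
    depth: np.ndarray
    x: np.ndarray | None = None
    y: np.ndarray | None = None
    end_event: EndEvent = EndEvent.ROUNDING_ONSET
    basal_process: bool | None = None
    endosome_count: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        if self.x is not None:
            self.x = np.asarray(self.x, dtype=float)
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=float)
        self.validate()

    def validate(self, convention: AxisConvention | None = None) -> None:
        tid = self.track_id
        if self.t.ndim != 1 or self.t.shape != self.depth.shape:
            raise ValidationError(f"track {tid}: time and depth must be 1-D and equal length")
        if len(self.t) < 2:
            raise ValidationError(f"track {tid}: needs at least 2 samples")
        if not np.isclose(self.t[0], 0.0):
            raise ValidationError(f"track {tid}: first sample must be at t=0 (got {self.t[0]})")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValidationError(f"track {tid}: timestamps must be strictly increasing")
        for arr, name in ((self.x, "x"), (self.y, "y")):
            if arr is not None and arr.shape != self.t.shape:
                raise ValidationError(f"track {tid}: {name} length mismatch")
        conv = convention or AxisConvention()
        conv.check_depths(self.depth, context=f"track {tid}")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    @property
    def censored(self) -> bool:
        return self.end_event is EndEvent.CENSORED

    def positions(self, use_planar: bool = False) -> np.ndarray:
        """Coordinate matrix (n_samples, d) used by the kinematic operations.

        Depth-only (d=1) by default; with ``use_planar`` the available
        planar coordinates are appended.
        """
        cols = [self.depth]
        if use_planar:
            cols += [c for c in (self.x, self.y) if c is not None]
        return np.column_stack(cols)


@dataclass
class SisterPair:
    """The two daughters of one mitosis plus their inheritance annotations."""

    pair_id: str
    daughter_a: Track
    daughter_b: Track

    def __post_init__(self) -> None:
        a, b = self.daughter_a, self.daughter_b
        if a.pair_id != self.pair_id or b.pair_id != self.pair_id:
            raise ValidationError(f"pair {self.pair_id}: daughters carry a different pair_id")
        if a.embryo_id != b.embryo_id:
            raise ValidationError(f"pair {self.pair_id}: daughters come from different embryos")
        for d in (a, b):
            if d.endosome_count is not None and (
                d.endosome_count < 0 or d.endosome_count != int(d.endosome_count)
            ):
                raise ValidationError(
                    f"pair {self.pair_id}: endosome counts must be integers >= 0"
                )

    @property
    def embryo_id(self) -> str:
        return self.daughter_a.embryo_id

    @property
    def fates(self) -> tuple[Fate, Fate]:
        return (self.daughter_a.fate, self.daughter_b.fate)

    @property
    def endosome_counts(self) -> tuple[int, int] | None:
        ca, cb = self.daughter_a.endosome_count, self.daughter_b.endosome_count
        if ca is None or cb is None:
            return None
        return int(ca), int(cb)

    @property
    def basal_process_owner(self) -> str:
        """'A', 'B' or 'UNKNOWN' — which daughter inherited the basal process."""
        fa, fb = self.daughter_a.basal_process, self.daughter_b.basal_process
        if fa and not fb:
            return "A"
        if fb and not fa:
            return "B"
        return "UNKNOWN"


@dataclass(frozen=True)
class SpotRecord:
    """One punctate-signal detection along the apicobasal axis of one slice."""

    slice_id: str
    marker: str
    axis_position: float
    axis_length: float
    region: str = "UNSPECIFIED"

    def __post_init__(self) -> None:
        if self.axis_length <= 0:
            raise ValidationError(f"slice {self.slice_id}: axis_length must be > 0")
        if not (0.0 <= self.axis_position <= self.axis_length):
            raise ValidationError(
                f"slice {self.slice_id}: axis_position {self.axis_position} outside "
                f"[0, {self.axis_length}]"
            )


@dataclass
class PairingResult:
    pairs: list[SisterPair]
    excluded: dict[str, int] = field(default_factory=dict)
    """pair_id -> number of tracks found, for every pair_id that did not have exactly two."""


# ---------------------------------------------------------------------------
# tracks


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} table is missing column(s): {', '.join(missing)}")


def _opt_scalar(group: pd.DataFrame, col: str):
    if col not in group.columns:
        return None
    vals = group[col].dropna().unique()
    if len(vals) == 0:
        return None
    if len(vals) > 1:
        raise ValidationError(f"column {col} is not constant within a track")
    return vals[0]


def read_tracks(path, convention: AxisConvention | None = None) -> list[Track]:
    """Read a tracks CSV into validated :class:`Track` objects.

    Rows are grouped by ``track_id`` and sorted by time.  If the file stores
    absolute time and carries a per-track ``division_time_min`` column, times
    are re-based so that each track starts at 0.
    """
    conv = convention or AxisConvention()
    df = pd.read_csv(
        path,
        dtype={"track_id": str, "embryo_id": str, "pair_id": str},
        float_precision="round_trip",
    )
    _require_columns(df, TRACK_COLUMNS, "tracks")
    tracks: list[Track] = []
    for track_id, group in df.groupby("track_id", sort=True):
        group = group.sort_values("time_min", kind="stable")
        t = group["time_min"].to_numpy(dtype=float)
        if len(np.unique(t)) != len(t):
            raise ValidationError(f"track {track_id}: duplicate timestamps")
        div_t = _opt_scalar(group, "division_time_min")
        if div_t is not None:
            t = t - float(div_t)
        elif len(t) and t[0] != 0.0:
            # absolute-time file without an explicit division time: the first
            # sample is the division frame by construction
            t = t - t[0]
        depth = group["depth_um"].to_numpy(dtype=float)
        x = group["x_um"].to_numpy(dtype=float) if "x_um" in group.columns else None
        y = group["y_um"].to_numpy(dtype=float) if "y_um" in group.columns else None
        if x is not None and np.all(np.isnan(x)):
            x = None
        if y is not None and np.all(np.isnan(y)):
            y = None
        pair_id = _opt_scalar(group, "pair_id")
        fate_raw = _opt_scalar(group, "fate")
        try:
            fate = Fate(fate_raw) if fate_raw is not None else Fate.UNKNOWN
        except ValueError as exc:
            raise ValidationError(f"track {track_id}: unknown fate {fate_raw!r}") from exc
        end_raw = _opt_scalar(group, "end_event")
        end_event = EndEvent(end_raw) if end_raw is not None else EndEvent.ROUNDING_ONSET
        bp = _opt_scalar(group, "basal_process")
        endo = _opt_scalar(group, "endosome_count")
        track = Track(
            track_id=str(track_id),
            embryo_id=str(_opt_scalar(group, "embryo_id")),
            pair_id=None if pair_id is None else str(pair_id),
            fate=fate,
            t=t,
            depth=depth,
            x=x,
            y=y,
            end_event=end_event,
            basal_process=None if bp is None else bool(int(bp)),
            endosome_count=None if endo is None else int(endo),
        )
        track.validate(conv)
        tracks.append(track)
    return tracks


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format DataFrame in the tracks CSV dialect (one row per sample)."""
    rows = []
    for tr in tracks:
        for i in range(tr.n_samples):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "embryo_id": tr.embryo_id,
                    "pair_id": tr.pair_id if tr.pair_id is not None else "",
                    "fate": tr.fate.value,
                    "time_min": tr.t[i],
                    "depth_um": tr.depth[i],
                    "x_um": tr.x[i] if tr.x is not None else np.nan,
                    "y_um": tr.y[i] if tr.y is not None else np.nan,
                    "basal_process": (
                        np.nan if tr.basal_process is None else int(tr.basal_process)
                    ),
                    "endosome_count": (
                        np.nan if tr.endosome_count is None else tr.endosome_count
                    ),
                    "end_event": tr.end_event.value,
                }
            )
    return pd.DataFrame(
        rows, columns=TRACK_COLUMNS[:4] + ["time_min", "depth_um"] + OPTIONAL_TRACK_COLUMNS[:5]
    )


def write_tracks(tracks: list[Track], path) -> None:
    # %.17g round-trips float64 exactly, so write->read->write is the identity
    tracks_to_frame(tracks).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# spots


def read_spots(path) -> list[SpotRecord]:
    df = pd.read_csv(
        path, dtype={"slice_id": str, "marker": str}, float_precision="round_trip"
    )
    _require_columns(df, SPOT_COLUMNS, "spots")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SpotRecord(
                slice_id=str(row.slice_id),
                marker=str(row.marker),
                axis_position=float(row.axis_position_um),
                axis_length=float(row.axis_length_um),
                region=str(getattr(row, "region", "UNSPECIFIED") or "UNSPECIFIED"),
            )
        )
    return records


def spots_to_frame(spots: list[SpotRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "slice_id": [s.slice_id for s in spots],
            "region": [s.region for s in spots],
            "marker": [s.marker for s in spots],
            "axis_position_um": [s.axis_position for s in spots],
            "axis_length_um": [s.axis_length for s in spots],
        }
    )


def write_spots(spots: list[SpotRecord], path) -> None:
    spots_to_frame(spots).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# pairing


def pair_sisters(tracks: list[Track]) -> PairingResult:
    """Group tracks into sister pairs by ``pair_id``.

    Every pair_id carried by exactly two tracks yields one
    :class:`SisterPair`; any pair_id with a different multiplicity is
    reported in ``excluded`` and skipped.  Tracks without a pair_id are
    ignored.  The result is independent of input order: daughters are
    ordered by track_id and pairs by pair_id.
    """
    by_pair: dict[str, list[Track]] = {}
    for tr in tracks:
        if tr.pair_id:
            by_pair.setdefault(tr.pair_id, []).append(tr)
    pairs: list[SisterPair] = []
    excluded: dict[str, int] = {}
    for pid in sorted(by_pair):
        members = sorted(by_pair[pid], key=lambda tr: tr.track_id)
        if len(members) == 2:
            pairs.append(SisterPair(pair_id=pid, daughter_a=members[0], daughter_b=members[1]))
        else:
            excluded[pid] = len(members)
    return PairingResult(pairs=pairs, excluded=excluded)
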