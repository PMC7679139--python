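"""Seeded generator of synthetic lineages, trajectories, endosome partitions
and spot fields.

The generator emulates the statistical structure of tracked sister-cell
cohorts in the embryonic zebrafish retina so that every stage of the
pipeline can be exercised without imaging data:

* soma trajectories sampled every 5 min from mother-cell mitosis, moving
  along an apicobasal axis bounded by the apical surface (0 µm) and the
  basal side of the neuroepithelium;
* sister pairs whose division class (asymmetric / symmetric neurogenic /
  symmetric proliferative) is drawn from a fate model with named presets
  for the control, Notch-inhibited and Sara-depleted conditions;
* largely all-or-none partition of Notch-carrying signalling endosomes,
  with the endosome-rich daughter forced to the non-neurogenic fate in
  asymmetric divisions;
* punctate spot fields along a bounded axis, uniform or linearly graded.

Motion is a discrete-time persistent (autoregressive) random walk with
reflecting boundaries — a minimal family whose three parameters (drift,
step noise, persistence) span both observed regimes: diffusive
interkinetic nuclear migration and directed basal translocation.

All randomness flows from a single integer seed through independent named
substreams, so identical config + seed gives byte-identical output tables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .io_tracks import EndEvent, Fate, SpotRecord, Track, ValidationError

__all__ = [
    "MotionKind",
    "MotionModel",
    "FateModel",
    "SimulationConfig",
    "CohortTables",
    "preset",
    "PRESET_NAMES",
    "simulate_depths",
    "simulate_track",
    "draw_division_classes",
    "simulate_cohort",
    "sample_axis_positions",
    "simulate_spots",
]


class MotionKind(str, enum.Enum):
    IKNM_RANDOM = "IKNM_RANDOM"
    DIRECTED_BASAL = "DIRECTED_BASAL"


@dataclass(frozen=True)
class MotionModel:
    """Persistent random walk along the apicobasal axis.

    drift            mean basal-ward velocity, µm/min
    step_sd          diffusive step scale, µm per sqrt(minute); with zero
                     persistence the depth increment over dt has standard
                     deviation step_sd * sqrt(dt)
    persistence      AR(1) velocity memory in [0, 1); 0 is memoryless
    tissue_thickness reflecting boundary, µm (apical boundary is 0)
    """

    kind: MotionKind = MotionKind.IKNM_RANDOM
    drift: float = 0.0
    step_sd: float = 0.3
    persistence: float = 0.0
    tissue_thickness: float = 85.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.persistence < 1.0):
            raise ValidationError("persistence must be in [0, 1)")
        if self.step_sd < 0 or self.tissue_thickness <= 0:
            raise ValidationError("step_sd must be >= 0 and tissue_thickness > 0")


@dataclass(frozen=True)
class FateModel:
    """Division-class and endosome-inheritance model.

    p_sym_neuro        probability of a symmetric neurogenic division
                       (two Ath5+ daughters); 0.08 in the control condition,
                       0.48 under Notch inhibition
    p_sym_prolif       probability of a symmetric proliferative division
                       (two Ath5− daughters); the remainder is asymmetric
    endosome_total_pmf probabilities of 0..k endosomes in the mother,
                       concentrated on 1–3
    p_all_to_one       probability that one daughter inherits every endosome
    p_bp_to_pos        probability that the Ath5+ daughter of an asymmetric
                       division inherits the basal process
    """

    p_sym_neuro: float = 0.08
    p_sym_prolif: float = 0.0
    endosome_total_pmf: tuple[float, ...] = (0.05, 0.35, 0.35, 0.20, 0.05)
    p_all_to_one: float = 0.8
    p_bp_to_pos: float = 0.6

    def __post_init__(self) -> None:
        if self.p_sym_neuro + self.p_sym_prolif > 1.0 + 1e-12:
            raise ValidationError("p_sym_neuro + p_sym_prolif must be <= 1")
        pmf = np.asarray(self.endosome_total_pmf, dtype=float)
        if np.any(pmf < 0) or not np.isclose(pmf.sum(), 1.0):
            raise ValidationError("endosome_total_pmf must be a probability vector")

    @property
    def p_asym(self) -> float:
        return 1.0 - self.p_sym_neuro - self.p_sym_prolif


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one synthetic cohort (parameters + seed)."""

    n_pairs: int = 35
    n_embryos: int = 9
    sampling_interval: float = 5.0  # minutes, the imaging cadence
    track_duration: float = 150.0  # minutes from mitosis to daughter rounding
    start_depth: float = 5.0  # µm; mitosis happens at the apical surface
    motion_pos: MotionModel = field(
        default_factory=lambda: MotionModel(
            kind=MotionKind.DIRECTED_BASAL, drift=0.08, step_sd=0.22, persistence=0.6
        )
    )
    motion_neg: MotionModel = field(
        default_factory=lambda: MotionModel(
            kind=MotionKind.IKNM_RANDOM, drift=0.02, step_sd=0.30, persistence=0.1
        )
    )
    bp_drift_bonus: float = 0.05  # µm/min added to the basal-process inheritor
    fate: FateModel = field(default_factory=FateModel)
    spot_model: str = "UNIFORM"  # UNIFORM | LINEAR_GRADIENT
    spot_gradient_slope: float = 0.0
    n_slices: int = 9  # 3 optical slices in each of 3 retinal regions
    spots_per_slice: float = 100.0  # Poisson mean
    spot_axis_length: float = 60.0  # µm, apicobasal extent of a slice
    spot_markers: tuple[str, ...] = ("Notch1b", "DeltaC")
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["motion_pos"]["kind"] = self.motion_pos.kind.value
        data["motion_neg"]["kind"] = self.motion_neg.kind.value
        data["fate"]["endosome_total_pmf"] = list(self.fate.endosome_total_pmf)
        data["spot_markers"] = list(self.spot_markers)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("motion_pos", "motion_neg"):
            if key in data:
                sub = dict(data[key])
                sub["kind"] = MotionKind(sub.get("kind", "IKNM_RANDOM"))
                data[key] = MotionModel(**sub)
        if "fate" in data:
            sub = dict(data["fate"])
            if "endosome_total_pmf" in sub:
                sub["endosome_total_pmf"] = tuple(sub["endosome_total_pmf"])
            data["fate"] = FateModel(**sub)
        if "spot_markers" in data:
            data["spot_markers"] = tuple(data["spot_markers"])
        return cls(**data)


PRESET_NAMES = ("control", "notch_inhibited", "sara_depleted")


def preset(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Named study conditions.

    control          8% symmetric neurogenic divisions, the rest asymmetric
    notch_inhibited  48% symmetric neurogenic divisions
    sara_depleted    excess symmetric proliferative divisions (two Ath5−
                     daughters); the published account is qualitative, so the
                     preset uses 30% as a documented choice
    """
    base = SimulationConfig(seed=seed)
    if name == "control":
        cfg = base
    elif name == "notch_inhibited":
        cfg = replace(base, fate=replace(base.fate, p_sym_neuro=0.48))
    elif name == "sara_depleted":
        cfg = replace(base, fate=replace(base.fate, p_sym_prolif=0.30))
    else:
        raise ValidationError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# motion


def simulate_depths(
    model: MotionModel,
    n_tracks: int,
    duration: float,
    dt: float,
    start_depth: float,
    rng: np.random.Generator,
    drift_offset: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Depth matrix (n_tracks, n_steps+1) of reflected persistent random walks.

    The velocity follows v_{k+1} = p v_k + (1 - p) (drift + offset) + noise
    and the depth is reflected at 0 and at the tissue thickness (the
    velocity flips sign on reflection).  ``drift_offset`` can be a
    per-track array (e.g. the basal-process drift bonus).
    """
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if not (0.0 <= start_depth <= model.tissue_thickness):
        raise ValidationError("start_depth outside the tissue")
    n_steps = int(round(duration / dt))
    drift = model.drift + np.broadcast_to(np.asarray(drift_offset, dtype=float), (n_tracks,))
    depth = np.empty((n_tracks, n_steps + 1))
    depth[:, 0] = start_depth
    v = np.zeros(n_tracks)
    p = model.persistence
    noise_sd = model.step_sd / np.sqrt(dt)
    thickness = model.tissue_thickness
    for k in range(n_steps):
        eps = rng.normal(0.0, noise_sd, size=n_tracks) if noise_sd > 0 else 0.0
        v = p * v + (1.0 - p) * drift + eps
        d = depth[:, k] + v * dt
        # reflect at both boundaries (increments are small; loop rarely repeats)
        for _ in range(8):
            below = d < 0
            above = d > thickness
            if not (below.any() or above.any()):
                break
            d = np.where(below, -d, d)
            d = np.where(above, 2 * thickness - d, d)
            v = np.where(below | above, -v, v)
        depth[:, k + 1] = np.clip(d, 0.0, thickness)
    return depth


def simulate_track(
    model: MotionModel,
    duration: float,
    dt: float,
    start_depth: float,
    rng: np.random.Generator,
    track_id: str = "sim",
    embryo_id: str = "E1",
    pair_id: str | None = None,
    fate: Fate = Fate.UNKNOWN,
) -> Track:
    """One simulated soma trajectory as a validated :class:`Track`."""
    depth = simulate_depths(model, 1, duration, dt, start_depth, rng)[0]
    t = np.arange(len(depth)) * dt
    return Track(
        track_id=track_id,
        embryo_id=embryo_id,
        pair_id=pair_id,
        fate=fate,
        t=t,
        depth=depth,
        end_event=EndEvent.ROUNDING_ONSET,
    )


# ---------------------------------------------------------------------------
# fates and cohorts


def draw_division_classes(fate: FateModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Array of 'ASYMMETRIC' / 'SYMMETRIC_NEUROGENIC' / 'SYMMETRIC_PROLIFERATIVE'."""
    u = rng.random(n)
    classes = np.full(n, "ASYMMETRIC", dtype=object)
    classes[u < fate.p_sym_neuro] = "SYMMETRIC_NEUROGENIC"
    classes[(u >= fate.p_sym_neuro) & (u < fate.p_sym_neuro + fate.p_sym_prolif)] = (
        "SYMMETRIC_PROLIFERATIVE"
    )
    return classes


@dataclass
class CohortTables:
    """Simulated cohort: tracks, one row per pair, and a spot table."""

    tracks: list[Track]
    pairs: "object"  # pandas DataFrame; typed loosely to keep import light
    spots: list[SpotRecord]
    config: SimulationConfig


def simulate_cohort(config: SimulationConfig) -> CohortTables:
    """Simulate a full cohort of sister pairs plus a spot field.

    Per pair: the division class is drawn from the fate model; fates are
    assigned to the two daughters in random order; the basal process goes
    to the Ath5+ daughter with probability ``p_bp_to_pos`` in asymmetric
    divisions (coin flip otherwise) and its inheritor receives a drift
    bonus; motion models follow fate (Ath5+ directed, Ath5− diffusive);
    the mother's endosomes are partitioned all-to-one with probability
    ``p_all_to_one`` (the rich daughter forced Ath5− in asymmetric
    divisions), otherwise by a fair binomial split.
    """
    import pandas as pd

    ss = np.random.SeedSequence(config.seed)
    fate_rng, motion_rng, endo_rng, spot_rng = (
        np.random.Generator(np.random.PCG64(child)) for child in ss.spawn(4)
    )
    n = config.n_pairs
    classes = draw_division_classes(config.fate, n, fate_rng)
    swap = fate_rng.random(n) < 0.5  # random daughter order
    bp_coin = fate_rng.random(n)
    fates_a = np.empty(n, dtype=object)
    fates_b = np.empty(n, dtype=object)
    bp_owner = np.empty(n, dtype=object)  # 'A' or 'B'
    for i, cls in enumerate(classes):
        if cls == "ASYMMETRIC":
            pos_first = not swap[i]
            fa, fb = (Fate.ATH5_POS, Fate.ATH5_NEG) if pos_first else (Fate.ATH5_NEG, Fate.ATH5_POS)
            bp_to_pos = bp_coin[i] < config.fate.p_bp_to_pos
            owner_is_a = (pos_first and bp_to_pos) or (not pos_first and not bp_to_pos)
        else:
            f = Fate.ATH5_POS if cls == "SYMMETRIC_NEUROGENIC" else Fate.ATH5_NEG
            fa = fb = f
            owner_is_a = bp_coin[i] < 0.5
        fates_a[i], fates_b[i] = fa, fb
        bp_owner[i] = "A" if owner_is_a else "B"

    # endosome totals and partition
    totals = endo_rng.choice(
        len(config.fate.endosome_total_pmf), size=n, p=config.fate.endosome_total_pmf
    )
    all_to_one = endo_rng.random(n) < config.fate.p_all_to_one
    rich_coin = endo_rng.random(n) < 0.5
    split = endo_rng.binomial(totals, 0.5)
    count_a = np.empty(n, dtype=int)
    count_b = np.empty(n, dtype=int)
    for i in range(n):
        if all_to_one[i]:
            if classes[i] == "ASYMMETRIC":
                rich_is_a = fates_a[i] is Fate.ATH5_NEG
            else:
                rich_is_a = rich_coin[i]
            count_a[i] = totals[i] if rich_is_a else 0
            count_b[i] = 0 if rich_is_a else totals[i]
        else:
            count_a[i] = split[i]
            count_b[i] = totals[i] - split[i]

    # motion: batch all tracks per fate so the generator scales to large cohorts
    fate_flat = np.concatenate([fates_a, fates_b])  # track j = pair j%n, daughter j//n
    fate_names = np.array([f.value for f in fate_flat])
    bonus = np.zeros(2 * n)
    for i in range(n):
        owner_idx = i if bp_owner[i] == "A" else n + i
        bonus[owner_idx] = config.bp_drift_bonus
    depths = np.empty((2 * n, int(round(config.track_duration / config.sampling_interval)) + 1))
    for fate_val, model in ((Fate.ATH5_POS, config.motion_pos), (Fate.ATH5_NEG, config.motion_neg)):
        idx = np.flatnonzero(fate_names == fate_val.value)
        if len(idx):
            depths[idx] = simulate_depths(
                model,
                len(idx),
                config.track_duration,
                config.sampling_interval,
                config.start_depth,
                motion_rng,
                drift_offset=bonus[idx],
            )
    t = np.arange(depths.shape[1]) * config.sampling_interval

    digits = max(4, len(str(n)))
    tracks: list[Track] = []
    pair_rows = []
    for i in range(n):
        pid = f"p{i + 1:0{digits}d}"
        embryo = f"E{i % config.n_embryos + 1}"
        for daughter, j in (("a", i), ("b", n + i)):
            tracks.append(
                Track(
                    track_id=f"{pid}{daughter}",
                    embryo_id=embryo,
                    pair_id=pid,
                    fate=fate_flat[j],
                    t=t.copy(),
                    depth=depths[j],
                    end_event=EndEvent.ROUNDING_ONSET,
                    basal_process=(bp_owner[i] == daughter.upper()),
                    endosome_count=int(count_a[i] if daughter == "a" else count_b[i]),
                )
            )
        pair_rows.append(
            {
                "pair_id": pid,
                "embryo_id": embryo,
                "division_class": classes[i],
                "fate_a": fates_a[i].value,
                "fate_b": fates_b[i].value,
                "endosome_count_a": int(count_a[i]),
                "endosome_count_b": int(count_b[i]),
                "basal_process_owner": bp_owner[i],
            }
        )
    pairs = pd.DataFrame(pair_rows)

    spots = simulate_spots(
        n_slices=config.n_slices,
        spots_per_slice=config.spots_per_slice,
        axis_length=config.spot_axis_length,
        model=config.spot_model,
        slope=config.spot_gradient_slope,
        markers=config.spot_markers,
        rng=spot_rng,
    )
    return CohortTables(tracks=tracks, pairs=pairs, spots=spots, config=config)


# ---------------------------------------------------------------------------
# spots


def sample_axis_positions(
    n: int, axis_length: float, model: str, slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Spot positions on [0, L]: uniform, or density proportional to
    1 + slope * x/L (slope > -1) sampled by inverting the CDF."""
    if model == "UNIFORM":
        return rng.uniform(0.0, axis_length, size=n)
    if model == "LINEAR_GRADIENT":
        if slope <= -1:
            raise ValidationError("gradient slope must be > -1")
        u = rng.random(n)
        if slope == 0:
            return u * axis_length
        # CDF(x) = (x/L + (s/2)(x/L)^2) / (1 + s/2); solve the quadratic for x/L
        s = slope
        z = (-1.0 + np.sqrt(1.0 + 2.0 * s * (1.0 + s / 2.0) * u)) / s
        return z * axis_length
    raise ValidationError(f"unknown spot model {model!r}")


REGIONS = ("NASAL", "CENTRAL", "TEMPORAL")


def simulate_spots(
    n_slices: int,
    spots_per_slice: float,
    axis_length: float,
    model: str = "UNIFORM",
    slope: float = 0.0,
    markers: tuple[str, ...] = ("Notch1b",),
    rng: np.random.Generator | None = None,
) -> list[SpotRecord]:
    """Spot table for ``n_slices`` optical slices per marker.

    Spot counts per slice are Poisson(``spots_per_slice``); slices cycle
    through the nasal/central/temporal regions.  A slice that draws zero
    spots is simply absent from the record list (downstream ratio code
    flags empty slices explicitly when given the slice inventory).
    """
    if axis_length <= 0:
        raise ValidationError("axis_length must be > 0")
    rng = rng or np.random.default_rng(0)
    records: list[SpotRecord] = []
    for marker in markers:
        for s in range(n_slices):
            slice_id = f"{marker}_s{s + 1:03d}"
            region = REGIONS[s % len(REGIONS)]
            count = rng.poisson(spots_per_slice)
            for pos in sample_axis_positions(count, axis_length, model, slope, rng):
                records.append(
                    SpotRecord(
                        slice_id=slice_id,
                        marker=marker,
                        axis_position=float(pos),
                        axis_length=axis_length,
                        region=region,
                    )
                )
    return records
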