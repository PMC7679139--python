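"""Division-symmetry classification and sister-cell asymmetry quantification.

A progenitor division is classified by the neurogenic-commitment labels of
its two daughters: asymmetric (one Ath5+ and one Ath5− daughter),
symmetric neurogenic (two Ath5+), or symmetric proliferative (two Ath5−).
Fate labels are inputs — the package never infers fate from kinematics;
the asymmetry analysis exists precisely to compare the two independently.

The endosome-partition summary quantifies how the Notch-carrying signalling
endosomes of the mother are split between the daughters.  The partition
ratio is operationalised as the minority fraction min(a, b)/(a + b) in
[0, 0.5]; 0 means one daughter inherited everything (all-or-none
partition).  Raw counts are always carried alongside.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tracks import Fate, SisterPair, ValidationError
from .kinematics import max_basal_position
from .stats import wilson_interval

__all__ = [
    "DivisionClass",
    "DivisionCall",
    "SisterComparison",
    "PartitionSummary",
    "classify_division",
    "division_proportions",
    "compare_sisters",
    "stratified_difference",
    "endosome_partition",
    "basal_process_concordance",
]


class DivisionClass(str, enum.Enum):
    ASYMMETRIC = "ASYMMETRIC"
    SYMMETRIC_NEUROGENIC = "SYMMETRIC_NEUROGENIC"
    SYMMETRIC_PROLIFERATIVE = "SYMMETRIC_PROLIFERATIVE"
    INDETERMINATE = "INDETERMINATE"


DETERMINATE_CLASSES = (
    DivisionClass.ASYMMETRIC,
    DivisionClass.SYMMETRIC_NEUROGENIC,
    DivisionClass.SYMMETRIC_PROLIFERATIVE,
)


@dataclass(frozen=True)
class DivisionCall:
    pair_id: str
    call: DivisionClass
    ath5_pos_count: int
    embryo_id: str | None = None


@dataclass(frozen=True)
class SisterComparison:
    """Max-basal-position comparison between the two daughters of one pair."""

    pair_id: str
    max_basal_a: float
    max_basal_b: float
    abs_difference: float
    more_basal_fate: str  # ATH5_POS | ATH5_NEG | TIE | UNKNOWN
    basal_process_to_more_basal: bool | None
    embryo_id: str | None = None


@dataclass(frozen=True)
class PartitionSummary:
    pair_id: str
    total: int
    count_a: int
    count_b: int
    minority_fraction: float  # NaN when total == 0
    all_to_one: bool


def classify_division(pair: SisterPair) -> DivisionCall:
    """Pure function of the two fate labels; any UNKNOWN fate is indeterminate."""
    fa, fb = pair.fates
    if Fate.UNKNOWN in (fa, fb):
        call = DivisionClass.INDETERMINATE
    else:
        n_pos = (fa is Fate.ATH5_POS) + (fb is Fate.ATH5_POS)
        call = {
            1: DivisionClass.ASYMMETRIC,
            2: DivisionClass.SYMMETRIC_NEUROGENIC,
            0: DivisionClass.SYMMETRIC_PROLIFERATIVE,
        }[n_pos]
    n_pos = (fa is Fate.ATH5_POS) + (fb is Fate.ATH5_POS)
    return DivisionCall(
        pair_id=pair.pair_id, call=call, ath5_pos_count=n_pos, embryo_id=pair.embryo_id
    )


def division_proportions(calls: list[DivisionCall], alpha: float = 0.05) -> pd.DataFrame:
    """Fractions of each determinate division class with Wilson intervals.

    Fractions are computed among determinate calls only; indeterminate
    calls are counted but excluded from the denominator.  The Wilson score
    interval is used because division cohorts are small (tens of
    divisions), where the Wald interval misbehaves.
    """
    determinate = [c for c in calls if c.call is not DivisionClass.INDETERMINATE]
    if not determinate:
        raise ValidationError("division_proportions: no determinate division calls")
    n = len(determinate)
    n_embryos = len({c.embryo_id for c in determinate if c.embryo_id is not None})
    rows = []
    for cls in DETERMINATE_CLASSES:
        k = sum(c.call is cls for c in determinate)
        lo, hi = wilson_interval(k, n, alpha=alpha)
        rows.append(
            {
                "call": cls.value,
                "count": k,
                "n": n,
                "fraction": k / n,
                "ci_low": lo,
                "ci_high": hi,
                "n_embryos": n_embryos,
                "n_indeterminate": len(calls) - n,
            }
        )
    return pd.DataFrame(rows)


def compare_sisters(pair: SisterPair) -> SisterComparison:
    """Compare the maximum basal positions of the two daughters.

    Exact equality of the maxima is reported as a TIE rather than broken
    arbitrarily: at 1 µm axial sampling, exact ties are meaningful
    degeneracies.
    """
    mba, _ = max_basal_position(pair.daughter_a)
    mbb, _ = max_basal_position(pair.daughter_b)
    fa, fb = pair.fates
    if mba == mbb:
        more = "TIE"
        winner = None
    elif mba > mbb:
        more = fa.value if fa is not Fate.UNKNOWN else "UNKNOWN"
        winner = "A"
    else:
        more = fb.value if fb is not Fate.UNKNOWN else "UNKNOWN"
        winner = "B"
    owner = pair.basal_process_owner
    bp_to_more = None
    if owner != "UNKNOWN" and winner is not None:
        bp_to_more = owner == winner
    return SisterComparison(
        pair_id=pair.pair_id,
        max_basal_a=mba,
        max_basal_b=mbb,
        abs_difference=abs(mba - mbb),
        more_basal_fate=more,
        basal_process_to_more_basal=bp_to_more,
        embryo_id=pair.embryo_id,
    )


def stratified_difference(comparisons: list[SisterComparison]) -> pd.DataFrame:
    """Mean ± sd of the sister max-basal difference, stratified by which
    fate was most basal.

    Sample standard deviation uses the n−1 denominator; a one-element
    stratum reports its value with sd = NaN; empty strata are absent from
    the table.
    """
    strata: dict[str, list[float]] = {}
    for c in comparisons:
        strata.setdefault(c.more_basal_fate, []).append(c.abs_difference)
    rows = []
    for name in sorted(strata):
        vals = np.asarray(strata[name], dtype=float)
        rows.append(
            {
                "more_basal_fate": name,
                "n": len(vals),
                "mean_um": float(np.mean(vals)),
                "sd_um": float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    return pd.DataFrame(rows, columns=["more_basal_fate", "n", "mean_um", "sd_um"])


def endosome_partition(pair: SisterPair) -> PartitionSummary:
    counts = pair.endosome_counts
    if counts is None:
        raise ValidationError(f"pair {pair.pair_id}: endosome counts missing")
    a, b = counts
    total = a + b
    minority = min(a, b) / total if total > 0 else float("nan")
    return PartitionSummary(
        pair_id=pair.pair_id,
        total=total,
        count_a=a,
        count_b=b,
        minority_fraction=minority,
        all_to_one=(total > 0 and min(a, b) == 0),
    )


def basal_process_concordance(
    pairs: list[SisterPair], comparisons: list[SisterComparison] | None = None
) -> pd.DataFrame:
    """Fractions of pairs where the basal-process-inheriting daughter (i) was
    the more basally translocating sister, and (ii) was the Ath5+ daughter.

    Pairs with unknown process ownership (or, for (i), tied maxima) are
    excluded from the respective denominator; exclusion counts are
    reported.
    """
    if comparisons is None:
        comparisons = [compare_sisters(p) for p in pairs]
    comp_by_id = {c.pair_id: c for c in comparisons}
    n_unknown = 0
    trans_k = trans_n = fate_k = fate_n = 0
    for p in pairs:
        owner = p.basal_process_owner
        if owner == "UNKNOWN":
            n_unknown += 1
            continue
        c = comp_by_id.get(p.pair_id)
        if c is not None and c.basal_process_to_more_basal is not None:
            trans_n += 1
            trans_k += int(c.basal_process_to_more_basal)
        owner_fate = p.daughter_a.fate if owner == "A" else p.daughter_b.fate
        if owner_fate is not Fate.UNKNOWN:
            fate_n += 1
            fate_k += int(owner_fate is Fate.ATH5_POS)
    rows = []
    for name, k, n in (
        ("process_inheritor_more_basal", trans_k, trans_n),
        ("process_inheritor_ath5_pos", fate_k, fate_n),
    ):
        rows.append(
            {
                "event": name,
                "count": k,
                "n": n,
                "fraction": k / n if n else float("nan"),
                "n_excluded_unknown": n_unknown,
            }
        )
    return pd.DataFrame(rows)
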