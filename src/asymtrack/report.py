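"""Report assembly: runs the analysis stages over a cohort and writes the
CSV surfaces, a markdown report, diagnostic plots and a run manifest.

Every number printed in the markdown report is read back from a CSV cell
written in the same run; the manifest records input/output digests so a
rerun with identical inputs, config and seed is verifiably identical
(timestamp aside).
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict
from datetime import datetime, timezone

import numpy as np
import pandas as pd

from . import __version__, asymmetry, kinematics, spatial
from .io_tracks import Fate, PairingResult, SpotRecord, Track, pair_sisters
from .stats import mann_whitney, paired_ttest

__all__ = ["analyze_cohort", "write_manifest", "file_digest"]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir,
    inputs: dict[str, str],
    outputs: list[str],
    seed: int | None = None,
    config_digest: str | None = None,
) -> dict:
    manifest = {
        "artifact": "asymtrack",
        "version": __version__,
        "seed": seed,
        "config_digest": config_digest,
        "inputs": {name: file_digest(path) for name, path in inputs.items()},
        "outputs": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    for name in outputs:
        path = os.path.join(out_dir, name)
        entry = {"sha256": file_digest(path)}
        if name.endswith(".csv"):
            with open(path) as fh:
                entry["rows"] = sum(1 for _ in fh) - 1
        manifest["outputs"][name] = entry
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _filter_neurogenic(pairs):
    """The backtracked-cohort conditioning: keep pairs with >= 1 Ath5+ daughter."""
    return [p for p in pairs if Fate.ATH5_POS in p.fates]


def analyze_cohort(
    tracks: list[Track],
    spots: list[SpotRecord] | None = None,
    out_dir: str = ".",
    window: float = kinematics.DEFAULT_MSD_WINDOW,
    n_rois: int = 3,
    condition_filter: str | None = None,
    make_plots: bool = True,
    inputs: dict[str, str] | None = None,
    seed: int | None = None,
    config_digest: str | None = None,
) -> dict:
    """Run the full analysis over a cohort and write all report files.

    Returns a dict of the in-memory result tables.  ``condition_filter``
    may be ``"neurogenic"`` to restrict pair-level analyses to divisions
    with at least one Ath5+ daughter (the conditioning a backtracking
    screen imposes); track-level kinematics always cover all tracks.
    """
    os.makedirs(out_dir, exist_ok=True)
    outputs: list[str] = []
    results: dict = {}

    def emit(df: pd.DataFrame, name: str) -> None:
        df.to_csv(os.path.join(out_dir, name), index=False)
        outputs.append(name)
        results[name[:-4]] = df

    # ---- kinematics over every track
    scalar, msd_long, dir_long = kinematics.summarize_tracks(tracks, window=window)
    emit(scalar, "kinematics_summary.csv")
    emit(msd_long, "msd_curves.csv")
    emit(dir_long, "directionality_curves.csv")

    # ---- pairing and pair-level analyses
    pairing: PairingResult = pair_sisters(tracks)
    pairs = pairing.pairs
    if condition_filter == "neurogenic":
        pairs = _filter_neurogenic(pairs)
    elif condition_filter not in (None, "", "none"):
        raise ValueError(f"unknown condition filter {condition_filter!r}")

    calls = [asymmetry.classify_division(p) for p in pairs]
    if any(c.call is not asymmetry.DivisionClass.INDETERMINATE for c in calls):
        emit(asymmetry.division_proportions(calls), "division_proportions.csv")
    emit(
        pd.DataFrame(
            {
                "pair_id": [c.pair_id for c in calls],
                "call": [c.call.value for c in calls],
                "ath5_pos_count": [c.ath5_pos_count for c in calls],
            }
        ),
        "division_calls.csv",
    )

    comparisons = [asymmetry.compare_sisters(p) for p in pairs]
    comp_df = pd.DataFrame([asdict(c) for c in comparisons])
    # paired t-test on sister maxima ordered by fate (Ath5+ vs Ath5-) so the
    # signed difference is meaningful; Mann-Whitney as the
    # distribution-free companion
    pos_max, neg_max = [], []
    for p in pairs:
        fa, fb = p.fates
        if {fa, fb} == {Fate.ATH5_POS, Fate.ATH5_NEG}:
            a = kinematics.max_basal_position(p.daughter_a)[0]
            b = kinematics.max_basal_position(p.daughter_b)[0]
            pos_max.append(a if fa is Fate.ATH5_POS else b)
            neg_max.append(b if fa is Fate.ATH5_POS else a)
    if len(pos_max) >= 2:
        pt = paired_ttest(pos_max, neg_max)
        mw = mann_whitney(pos_max, neg_max)
        tests = pd.DataFrame([asdict(pt), asdict(mw)])
        emit(tests, "sister_tests.csv")
    emit(comp_df, "sister_comparisons.csv")
    emit(asymmetry.stratified_difference(comparisons), "stratified_differences.csv")

    with_endo = [p for p in pairs if p.endosome_counts is not None]
    if with_endo:
        parts = [asymmetry.endosome_partition(p) for p in with_endo]
        emit(pd.DataFrame([asdict(p) for p in parts]), "endosome_partitions.csv")
    emit(asymmetry.basal_process_concordance(pairs, comparisons), "basal_process_concordance.csv")
    if pairing.excluded:
        emit(
            pd.DataFrame(
                {"pair_id": list(pairing.excluded), "n_tracks": list(pairing.excluded.values())}
            ),
            "pairing_exclusions.csv",
        )

    # ---- spot distribution (optional)
    if spots:
        ratio_table = spatial.spot_ratios(spots, n_rois=n_rois)
        emit(ratio_table, "spot_ratios.csv")
        emit(spatial.compare_roi_groups(ratio_table), "spot_roi_tests.csv")

    if make_plots:
        _plots(tracks, results, out_dir, outputs)

    _write_markdown(results, out_dir, outputs, window=window)
    write_manifest(out_dir, inputs or {}, outputs, seed=seed, config_digest=config_digest)
    return results


def _plots(tracks, results, out_dir, outputs) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"ATH5_POS": "tab:green", "ATH5_NEG": "tab:gray", "UNKNOWN": "tab:blue"}
    for tr in tracks:
        ax.plot(tr.t, tr.depth, color=colors.get(tr.fate.value, "k"), alpha=0.4, lw=0.8)
    ax.set_xlabel("time after mitosis (min)")
    ax.set_ylabel("depth from apical surface (µm)")
    ax.set_title("soma trajectories (green: Ath5+, grey: Ath5−)")
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "trajectories.png"), dpi=120)
    plt.close(fig)
    outputs.append("trajectories.png")

    parts = results.get("endosome_partitions")
    if parts is not None and len(parts):
        fig, ax = plt.subplots(figsize=(4, 3))
        vals = parts["minority_fraction"].dropna()
        ax.hist(vals, bins=np.linspace(0, 0.5, 6), edgecolor="k")
        ax.set_xlabel("endosome minority fraction min/total")
        ax.set_ylabel("pairs")
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "endosome_ratio_hist.png"), dpi=120)
        plt.close(fig)
        outputs.append("endosome_ratio_hist.png")


def _fmt(x, nd=3):
    return "NA" if x is None or (isinstance(x, float) and np.isnan(x)) else f"{x:.{nd}g}"


def _write_markdown(results, out_dir, outputs, window) -> None:
    lines = ["# asymtrack analysis report", ""]
    props = results.get("division_proportions")
    if props is not None:
        lines.append("## Division symmetry")
        for _, row in props.iterrows():
            lines.append(
                f"- {row['call']}: {row['count']}/{row['n']} = {100 * row['fraction']:.1f}% "
                f"(Wilson 95% CI {100 * row['ci_low']:.1f}–{100 * row['ci_high']:.1f}%)"
            )
        lines.append("")
    comp = results.get("sister_comparisons")
    if comp is not None and len(comp):
        d = comp["abs_difference"]
        lines.append("## Sister max-basal positions")
        lines.append(
            f"- mean sister difference {d.mean():.2f} ± {d.std(ddof=1):.2f} µm (n = {len(d)})"
        )
        frac_pos = float((comp["more_basal_fate"] == "ATH5_POS").mean())
        lines.append(f"- Ath5+ daughter more basal in {100 * frac_pos:.0f}% of pairs")
        tests = results.get("sister_tests")
        if tests is not None:
            for row in tests.itertuples(index=False):
                lines.append(
                    f"- {row.test} (Ath5+ vs Ath5− max basal, n = {row.n_a} asymmetric pairs): "
                    f"statistic {_fmt(row.statistic)}, p = {_fmt(row.p_value)}"
                )
        lines.append("")
    strat = results.get("stratified_differences")
    if strat is not None and len(strat):
        lines.append("## Sister difference by most-basal fate")
        for row in strat.itertuples(index=False):
            lines.append(
                f"- {row.more_basal_fate}: {row.mean_um:.2f} ± {_fmt(row.sd_um)} µm (n = {row.n})"
            )
        lines.append("")
    kin = results.get("kinematics_summary")
    if kin is not None and len(kin):
        lines.append(f"## Kinematics (MSD window {window:g} min)")
        for fate, grp in kin.groupby("fate"):
            lines.append(
                f"- {fate}: mean velocity {grp['mean_inst_velocity_um_per_min'].mean():.3f} µm/min, "
                f"integral-mean depth {grp['integral_mean_um'].mean():.1f} µm (n = {len(grp)})"
            )
        lines.append("")
    parts = results.get("endosome_partitions")
    if parts is not None and len(parts):
        lines.append("## Endosome partition")
        lines.append(
            f"- all-to-one inheritance in {int(parts['all_to_one'].sum())}/{len(parts)} pairs"
        )
        lines.append("")
    conc = results.get("basal_process_concordance")
    if conc is not None and len(conc):
        lines.append("## Basal process inheritance")
        for _, row in conc.iterrows():
            lines.append(
                f"- {row['event']}: {row['count']}/{row['n']} ({_fmt(100 * row['fraction'])}%)"
            )
        lines.append("")
    roi = results.get("spot_roi_tests")
    if roi is not None and len(roi):
        lines.append("## Spot distribution along the apicobasal axis")
        for row in roi.itertuples(index=False):
            lines.append(
                f"- {row.marker} {row.roi_a} vs {row.roi_b}: "
                f"means {_fmt(row.mean_a)} vs {_fmt(row.mean_b)}, Welch p = {_fmt(row.p)}"
            )
        lines.append("")
    path = os.path.join(out_dir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    outputs.append("report.md")
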