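# asymtrack

Sister-cell translocation kinematics and division-asymmetry analysis for
tracked neuroepithelial lineages.

## The problem

In pseudostratified neuroepithelia such as the embryonic zebrafish retina,
progenitor cells divide at the apical surface and their two daughters then
translocate their somas along the apicobasal axis. Whether a division is
*asymmetric* (one daughter switches on a proneural factor such as Ath5/atoh7
and commits to neurogenesis while its sister stays in another lineage) or
*symmetric* is a central question for how tissues balance proliferation and
differentiation. Testing hypotheses about this — does basal translocation
depth predict fate? are Notch-carrying Sara endosomes partitioned
all-or-none between sisters? are Notch pathway components graded along the
axis? — requires quantitative analysis of backtracked sister-cell
trajectories, inheritance annotations and punctate-staining positions.

`asymtrack` is a toolkit for exactly that analysis. It consumes plain CSV
track/spot/endosome tables (e.g. exported from MTrackJ-style manual
tracking), computes per-track kinematics and pair-level asymmetry
statistics, and ships a fully seeded synthetic-cohort generator so the
entire pipeline is runnable and testable without any imaging data.

## What it computes

For a soma trajectory `depth(t)` sampled from the mother's mitosis (t = 0,
depth measured from the apical surface, in µm):

- **Maximum basal position** — max depth attained, and when;
- **Instantaneous velocity** — per-step |Δposition|/Δt and its mean;
- **MSD** — time-averaged mean squared displacement over overlapping pairs,
  restricted to a window after mitosis (default 100 min):
  MSD(τ) = ⟨(d(t+τ) − d(t))²⟩, ∝ τ for diffusive and ∝ τ² for directed motion;
- **Directionality ratio** — net displacement over path length at each time,
  1 for perfectly straight motion;
- **Integral-mean depth** — d̂ = I/T with I = ∫₀ᵀ depth(t) dt (trapezoidal,
  on the recorded timestamps), the time-averaged depth of the trajectory.

At the pair and cohort level:

- division classification (asymmetric / symmetric neurogenic / symmetric
  proliferative) from daughter fate labels, with class proportions and
  Wilson 95% intervals;
- sister max-basal comparisons (paired t-test, Mann-Whitney), differences
  stratified by which fate was most basal;
- endosome-partition summaries (minority fraction min/total ∈ [0, 0.5],
  all-to-one flag, counts conserved by construction);
- basal-process inheritance concordance with translocation and fate;
- apicobasal spot-distribution ratios in equal-length ROIs (apical /
  central / basal thirds by default), per-slice normalised, compared with
  Welch's t-test.

## Worked example

```bash
asymtrack simulate --preset control --seed 5 --n-pairs 30 --out sim/
asymtrack analyze --tracks sim/tracks.csv --spots sim/spots.csv --out results/
```

`results/report.md` from this exact run reads (excerpt):

```
## Division symmetry
- ASYMMETRIC: 26/30 = 86.7% (Wilson 95% CI 70.3–94.7%)
- SYMMETRIC_NEUROGENIC: 4/30 = 13.3% (Wilson 95% CI 5.3–29.7%)
- SYMMETRIC_PROLIFERATIVE: 0/30 = 0.0% (Wilson 95% CI 0.0–11.4%)

## Sister max-basal positions
- mean sister difference 11.73 ± 7.17 µm (n = 30)
- Ath5+ daughter more basal in 90% of pairs
- paired_t (Ath5+ vs Ath5− max basal, n = 26 asymmetric pairs): statistic 6.28, p = 1.43e-06
```

meaning: in this 30-pair synthetic control cohort, 26 divisions produced
one Ath5+ and one Ath5− daughter (the generator draws 92% asymmetric on
average; a 30-pair cohort scatters around that); sister somas differed by
~12 µm in their deepest basal position on average, and the neurogenic
daughter was the deeper one far more often than not — the qualitative
structure the generator is calibrated to. Alongside the report you get CSVs for every
table (kinematics per track, MSD and directionality curves in long format,
division proportions, endosome partitions, spot-ratio Welch tests),
trajectory/histogram plots, and a `manifest.json` with input/output
digests: identical inputs + seed reproduce identical outputs byte for
byte.

The same analyses are available as a library (`asymtrack.kinematics`,
`.asymmetry`, `.spatial`, `.synthetic`, `.report`) for use on real track
tables; the CSV dialects are documented in `asymtrack/io_tracks.py`.

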