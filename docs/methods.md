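# Methods

This note documents the models, estimators, parameter choices and known
limitations of `asymtrack`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted from memory.

## Conventions

Depth is measured along the apicobasal axis from the apical surface
(0 µm), increasing basal-ward, so the "maximum basal position" of a track
is simply its maximum depth. Time is in minutes with t = 0 at the mitosis
of the mother cell; tracks end at the daughters' rounding onset, or are
flagged `CENSORED` when tracking stopped early (censored tracks are
analysed, not rejected — the flag travels into every summary). Sampling
is nominally every 5 min (the imaging cadence the tables come from), but
nothing assumes uniformity: all integrators and velocity estimates use
the recorded timestamps. Depths are required to be ≥ 0 at ingest; the
time-average d̂ = I/T is therefore taken over a non-negative integrand,
which resolves the ambiguity of how sub-apical excursions would be
handled (they cannot occur by construction).

## Kinematic estimators

**Integral-mean depth.** I = ∫ depth(t) dt is computed by trapezoidal
quadrature on the recorded timestamps, which is exact for the
piecewise-linear trajectories that point tracking produces; d̂ = I/T.
The acceptance suite checks agreement with a 10⁴-subdivision midpoint
Riemann sum to 1e-6 relative error on 1,000 random piecewise-linear
tracks. Refining the sampling of a piecewise-linear track does not change
d̂, and min depth ≤ d̂ ≤ max depth always.

**MSD.** The estimator is the time-averaged MSD over overlapping ordered
sample pairs — the de-facto convention of trajectory-analysis tools —
restricted to the first `window` minutes after mitosis (default 100).
Lags are multiples of the median sampling interval; a lag supported by
fewer than 2 pairs is dropped (a 100-min window at 5-min cadence has 21
points, so single-pair tail lags would otherwise dominate the curve).
`n_pairs` is reported per lag to keep the estimator auditable.
Displacement is depth-only (1-D) by default, because the apicobasal axis
is the axis the analysis reasons about; `use_planar=True` switches to
Euclidean displacement on the available projected coordinates. Closed
forms used as oracles: MSD(τ) = v²τ² for ballistic tracks, MSD ≡ 0 for
stationary ones, and slope σ²/Δt for an unbiased walk with per-step sd σ
(recovered within 15% by a 200-walk ensemble in the acceptance suite).

**Directionality ratio.** Net displacement from the start divided by
cumulative path length at each sample time; in [0, 1] by the triangle
inequality, 1 until the path first backtracks, and defined as 1 while the
path length is still zero. Invariant to rigid translation.

**Instantaneous velocity.** Per-step |Δposition|/Δt, averaged unweighted
over steps (steps are equal-duration in practice); a time-weighted mean
(= path length / duration) is available behind a flag for irregular
sampling.

## Asymmetry analyses

Division classification is a pure function of the two daughters' fate
labels; any unknown fate makes the call indeterminate. Proportions are
reported with Wilson 95% intervals (cohorts are tens of divisions; Wald
intervals misbehave there). Exact ties in sister maxima are reported as
`TIE` rather than broken arbitrarily, since at ~1 µm axial resolution an
exact tie is a meaningful degeneracy. The endosome "partition ratio" is
operationalised as the minority fraction min(a,b)/(a+b) ∈ [0, 0.5] — the
raw counts are always emitted alongside so any alternative definition can
be recomputed. The backtracking conditioning of a neurogenic screen
(cohorts containing only divisions with ≥ 1 committed daughter) is an
explicit filter flag (`condition_filter="neurogenic"`), not a baked-in
assumption, because synthetic cohorts are generated unconditioned and the
symmetric-proliferative class is needed for the Sara-depleted condition.

Statistical tests follow their standard definitions (scipy/statsmodels):
paired t for fate-ordered sister maxima, Welch's unequal-variance t for
ROI ratio comparisons, Mann-Whitney with the exact null for group sizes
≤ 20 and the tie-corrected normal approximation above that. No
multiple-testing correction is applied anywhere; raw p-values are
reported with their n's.

## Spot-distribution analysis

Each optical slice's apicobasal axis is split into `n_rois` equal-length
intervals (3 by default: apical / central / basal), half-open basal-ward
with the last interval closed so boundary spots are assigned
deterministically. Counts are normalised by the slice's total so ratios
sum to 1 per (slice, marker); empty slices are flagged rather than
silently dropped. Working on equal axis-length thirds of extracted spot
positions is equivalent, for ratio purposes, to equal-area image ROIs
spanning the same thirds. Welch comparisons are run per-slice by default;
aggregation to region level is a flag. Comparisons of *different* ROIs of
the same slices are negatively correlated by the normalisation (a
multinomial constraint), which the unpaired Welch test does not model —
the same caveat applies to the analysis the test mirrors; the type-I
calibration in the acceptance suite therefore uses the same ROI across
two independently generated slice groups, where independence holds and
the empirical rejection rate at α = 0.05 lands inside [0.04, 0.06] over
10,000 datasets.

## Synthetic cohort generator

Motion is a discrete-time persistent random walk on the velocity:
v(k+1) = p·v(k) + (1−p)·(drift) + ε, depth reflected at 0 and at the
tissue thickness (velocity flips sign on reflection). With persistence
p = 0 the depth increment over dt has sd `step_sd`·√dt, so `step_sd` is
in µm/√min. This three-parameter family spans both observed regimes:
diffusive interkinetic nuclear migration and directed basal
translocation. No published motion model exists for these cells; this is
the minimal family with interpretable parameters.

Default study conditions (one cohort = 35 pairs from 9 embryos unless
overridden):

| parameter | value | rationale |
|---|---|---|
| sampling interval | 5 min | imaging cadence of the source data |
| track duration | 150 min | division-to-rounding intervals at desk scale; the MSD window (100 min) must fit inside |
| tissue thickness | 85 µm | mid-range of the 70–100 µm retinal neuroepithelium |
| start depth | 5 µm | mitosis at the apical surface, soma radius offset |
| Ath5+ motion | drift 0.08 µm/min, step sd 0.22, persistence 0.6 | directed translocation |
| Ath5− motion | drift 0.02 µm/min, step sd 0.30, persistence 0.1 | near-diffusive IKNM |
| basal-process drift bonus | 0.05 µm/min | process inheritance facilitates translocation independently of fate |
| p(sym. neurogenic) | 0.08 control / 0.48 notch_inhibited | reported division-pattern frequencies |
| p(sym. proliferative) | 0 control / 0.30 sara_depleted | the depleted condition is described only qualitatively; 0.30 is this package's documented choice |
| endosome totals | pmf (.05, .35, .35, .20, .05) on 0–4 | mothers mainly carry 1–3 endosomes |
| p(all-to-one) | 0.8 | all-or-none partition dominates |
| p(process → Ath5+) | 0.6 | process inheritance only weakly predicts fate |

The motion parameters were calibrated once, jointly, against the printed
cohort statistics — a mean sister max-basal difference of ≈10 µm and the
neurogenic daughter deeper in ≈78% of asymmetric pairs — and then frozen.
At these defaults a large cohort gives a sister difference of 10.5 ± 7.2 µm
and Ath5+ deeper in 79.5% of asymmetric pairs, with clearly separated
velocity and MSD by fate. In asymmetric divisions the endosome-rich
daughter of an all-to-one partition is forced to the Ath5− fate — the
working model in which retained signalling endosomes keep Notch active
and the cell proliferative, read as a deterministic partition rule rather
than a signalling simulation. Randomness flows from one integer seed
through independent named substreams (fates, motion, endosomes, spots),
so identical config + seed yields byte-identical tables; CSVs are written
with 17-significant-digit floats and read with round-trip parsing so
write→read→write is the identity.

What the generator does *not* emulate: cell-cycle structure and mitotic
rounding shape changes, apical crowding and tissue mechanics, lateral
inhibition dynamics, measurement noise of manual tracking, per-embryo
random effects (embryo labels are assigned round-robin), and the plateau
of basal translocation near the final position (drift is constant until
reflection). Passing tests therefore demonstrate that the *estimators*
are correct and the pipeline recovers known generating parameters — not
that real retinal cohorts satisfy the generator's assumptions.

## Numerical and design notes

- ROI boundary rule: [lo, hi) with the basal-most interval closed.
- Velocity AR(1) noise is Gaussian; reflection preserves |v|.
- MSD lags match the grid to 1e-6 relative tolerance, so lightly jittered
  timestamps still bin correctly; heavily nonuniform tracks simply yield
  fewer on-grid pairs (reported via `n_pairs`).
- Zero-spot slices, zero-endosome mothers (minority fraction undefined),
  single-member strata (sd undefined) and sub-2-slice Welch groups are
  reported as flagged/NaN rather than raised, because they are legitimate
  small-cohort outcomes.
- Problem sizes in the test and acceptance batteries (e.g. 200-walk MSD
  ensembles, 200×100 coverage cohorts, 100×100-pair discrimination
  cohorts, 10,000 type-I datasets) were chosen so each check resolves its
  stated tolerance with comfortable Monte-Carlo margin at desk scale.

## Known limitations

- Wilson-interval coverage oscillates with (n, p) as for any discrete
  proportion interval; near p ≈ 0.5 and n = 100 the exact coverage of the
  nominal 95% interval is 94.3%, slightly below nominal. A battery that
  demands ≥ 95% empirical coverage there will fail for most seeds — this
  is a property of the interval, not of the estimator pipeline, and it is
  deliberately left visible rather than papered over.
- Fate labels are inputs. The package never infers fate from kinematics;
  the asymmetry module exists to *compare* the two, and a user supplying
  kinematics-derived fates would make those comparisons circular.
- The paired sister test orders daughters by fate and is therefore only
  defined for asymmetric pairs; symmetric pairs contribute to unordered
  summaries only.
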