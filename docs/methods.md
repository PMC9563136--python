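# Methods

This note documents the models, conventions and numerical choices behind
`planqa`: what the synthetic cohort emulates, how each evaluation quantity
is defined, and where the design was genuinely open.

## 1. Evaluation conventions

**DVH indices.** All indices use full-voxel counting on the raw voxel
doses — no partial volumes, no interpolation, no binned-curve readback.
With in-structure doses sorted descending as `s[0] >= s[1] >= ...`,
`Dx = s[k-1]` for `k = ceil(x/100 · N)`: the minimum dose received by the
hottest x% of the structure.  `Vx` counts voxels at or above the threshold
(inclusive `>=`, so tie behaviour is deterministic).  Cumulative DVH
curves are built on a 10 cGy grid by default and extend one bin beyond the
maximum dose so they always end at volume fraction 0; they are for
display — indices never come from the binned curve, avoiding binning bias.
Treatment-planning systems differ in these conventions and rarely document
them; ours is declared rather than inferred, and it admits an exact
sort/count oracle that the test suite exercises on thousands of random
grids.

**Conformity.** `CI = (TV_RI/TV) · (TV_RI/V_RI)` (Paddick form), where TV
is the target volume, V_RI the reference-isodose volume and TV_RI their
intersection, all in voxels.  The reference isodose defaults to 95% of the
prescription (4750 cGy at 5000 cGy).  The phrase "the 95% prescription
isodose" is genuinely ambiguous — it can mean the 4750 cGy surface or the
5000 cGy surface that must cover 95% of the PTV — so the reference
fraction is a parameter (`reference_fraction`, default 0.95, set 1.0 for
the other reading); the default is documented, not silently resolved.
V_RI is counted inside the body contour only: in the phantom model dose
outside the patient is non-physical.  An empty reference isodose yields
CI = 0 with an `undefined` flag rather than an exception.

**Homogeneity.** `HI = (D2 − D98)/D_prescription`; 0 is perfectly
homogeneous, and `D2 < D98` is rejected as an ordering error.

**PQM scoring.** Each of the nine shipped metrics has a value window
`[lower, upper]` mapped onto `[0, 10]` points: at-or-beyond the favourable
edge scores 10, at-or-beyond the unfavourable edge scores 0, linear in
between, clamped outside.  Linear interpolation is the standard reading of
a scored "value range" and is what the midpoint test pins down (score 5.0
at the window midpoint).  Orientation is an explicit field — CI is the
single higher-is-better metric — rather than being inferred from metric
names, so a misconfigured spec fails loudly.  Scores and totals are
reported to 2 decimals.  A plan missing any of the nine metrics is listed
as unscored and excluded from cohort totals.

**Goal checks.** The prescription goal passes when PTV D95 ≥ its limit;
every other goal is an upper bound and passes only when the achieved value
is strictly below the limit — printed goals are "<" constraints, so ties
at the limit fail.  One knife-edge consequence: a hybrid plan evaluated
against its *own* personalised goals often ties the limit exactly (the
personalised limit is the predicted index, and outside the PTV the
simulated dose equals the prediction deterministically), and the tie
counts as a fail.  Self-goal pass rates therefore understate attainment;
the cohort conclusions rest on the metric and PQM comparisons instead.

## 2. The synthetic cohort

There is no public cohort of rectal VMAT plans to evaluate against, so the
package generates one.  The phantom is schematic by design: it reproduces
the *relational* anatomy that drives the evaluation (a posteriorly placed
elongated PTV, a bladder that may overlap it, lateral femoral heads, small
bowel superior-anterior, all inside an elliptical body) without claiming
anatomical realism.

**Geometry.** Default grid 80³ voxels at 2.5 mm isotropic, axes (z, y, x),
doses in cGy throughout (conversion only at report time).  Structures are
voxelized ellipsoids with mild per-patient jitter in size and position.
The bladder's anterior gap to the PTV is drawn per patient so the
bladder–PTV overlap fraction spans roughly 0–0.2 of the PTV across seeds —
including high-overlap anatomies for which a population-level bladder goal
is infeasible, the case that motivates goal personalisation.  The CTV is
the PTV eroded by one voxel shell; the small bowel is clipped away from
the PTV.  Containment invariants (everything inside the body, CTV inside
PTV, femoral heads clear of the PTV) are validated on construction and
property-tested over 50 seeds.

**Dose model.** Inside the PTV:
`dose = Rx · cs · (1 + hotspot) + N(0, sd · Rx)`, with the coverage scale
`cs` auto-calibrated per plan so PTV D95 lands on the prescription (inner
tolerance 0.1%, contract ±1%; bounded iteration with a calibration error
beyond 50 steps).  Because the hotspot term is uniform, calibration
absorbs it into `cs`; it is kept as a model parameter for uncalibrated
fields and the degenerate noise-free case, but in a calibrated plan the
in-PTV distribution is set by the noise sd alone — which is exactly what
drives D2, D98 and HI.  Outside the PTV:
`dose = Rx · exp(−d/falloff) · sparing`, where `d` is the distance to the
PTV, `falloff` is a per-strategy length, and `sparing ∈ (0, 1]` multiplies
voxels inside each OAR (minimum factor where OARs overlap; overlap voxels
*inside* the PTV get the full target dose).  The falloff anchors at the
prescription level — the calibrated D95 surface — so conformity is
controlled by the falloff length alone, decoupled from PTV noise.

**Distance maps.** Margin expansion (`expand_mask`) uses the plain
voxel-center distance transform, matching its exhaustive Euclidean-ball
oracle exactly.  The dose falloff instead uses the signed voxel-center
distance smoothed with a 1-voxel Gaussian: on a 2.5 mm grid the plain
transform puts every PTV-adjacent voxel at exactly 2.5 mm, which quantizes
the 95% isodose shell to whole voxel layers and pins CI to three discrete
values; the smoothed map restores a continuously valued isodose surface
(and a CI that varies smoothly and monotonically with the falloff length)
at the cost of a slightly diffused boundary.  The falloff lengths below
are therefore *effective* lengths on this smoothed, coarse-grid phantom,
not clinical gradient measurements.

**Prediction surrogate.** The achievable-dose predictor is the same
parametric model run noise-free — a deliberate stand-in for a trained
dose-prediction model.  Its role in the workflow is only to supply
patient-specific dose-volume indices for goal replacement, and for that
the surrogate is exact by construction.  Consequently the pipeline cannot
probe prediction *error*; conclusions about the hybrid strategy hold for a
well-calibrated predictor.

**Strategy presets.** Seven presets stand in for the seven plans per
patient.  They were calibrated once, before the acceptance tests existed,
against the qualitative orderings the study design implies, and frozen:

| strategy        | noise sd | falloff (mm) | sparing bladder / femur / bowel |
|-----------------|---------:|-------------:|--------------------------------:|
| manual          | 0.016    | 41           | 0.88 / 0.85 / 0.88 |
| script_easy     | 0.024    | 41           | 0.95 / 0.95 / 0.95 |
| script_moderate | 0.014    | 45           | 0.85 / 0.76 / 0.85 |
| script_hard     | 0.035    | 73           | 0.40 / 0.28 / 0.45 |
| hybrid_easy     | 0.023    | 39           | 0.72 / 0.78 / 0.75 |
| hybrid_moderate | 0.0135   | 43           | 0.66 / 0.68 / 0.70 |
| hybrid_hard     | 0.0145   | 54           | 0.56 / 0.52 / 0.62 |

The pattern encodes the stated world: script planning tracks its goal
template (weak OAR sparing at the easy setting, aggressive OAR sparing at
the hard setting bought with a noisy, inhomogeneous PTV and a long
falloff, i.e. poor D2/HI/CI); hybrid planning is personalised and
therefore stable across settings, with moderate-to-good sparing and tight
PTV statistics; manual planning sits mid-pack.  One known divergence: in
a real cohort a hard script template can out-*score* hybrid because six of
the nine PQM metrics reward OAR sparing and a bimodal patient mix hides
the unacceptable PTVs in the mean; the uniform-noise phantom has no such
mix, so here `script_hard` totals below `hybrid_hard`.  The qualitative
headline this package tests — hybrid better at easy/moderate settings and
more robust in CI across settings — does not depend on that tail
behaviour.

**Seeding.** All randomness flows from one master seed through
`numpy.random.SeedSequence([master_seed, patient, stream])`, so cohorts
are bit-reproducible and extensible (patient *i* is identical regardless
of cohort size), and every plan's noise stream is independent.

## 3. Goal personalisation

`update_goals` replaces each OAR-role goal's limit with the same index
evaluated on the predicted dose — unconditionally by default (`replace`),
because personalisation must be able to *loosen* an infeasible goal (the
high-overlap bladder case), with `tighten_only` available as the
conservative alternative.  Target and auxiliary goals pass through
untouched, and the operation preserves goal count, order, kinds and roles,
and is idempotent for a fixed prediction.  A max-dose OAR goal is replaced
by the predicted true maximum (not a near-max percentile).  Margin
expansions ("PTV + 5 mm") are isotropic 3-D Euclidean dilations.  The two
auxiliary ring goals (max 4200 cGy on body ∖ (PTV ⊕ 5 mm), max 3000 cGy on
body ∖ (PTV ⊕ 15 mm)) and the five additional OAR goals (small bowel
V45Gy < 5%, V15Gy < 30%; femoral heads V10Gy < 75%; bladder Dmax
< 5250 cGy) ship as ready-made lists.  The script-based optimizer that
would *consume* the updated goals is a commercial TPS component and is out
of scope; downstream, updated goals are evaluated against the simulated
hybrid plans.

## 4. Statistical protocol

Per metric and strategy pair, differences are paired by patient.
Shapiro–Wilk on the differences (alpha 0.05) selects a paired t-test
(normal) or the Wilcoxon signed-rank test; the choice is per metric, and
either test can be forced.  Wilcoxon uses the exact null for n ≤ 25
without rank ties and the normal approximation with continuity correction
otherwise; zero differences are dropped (Wilcoxon's convention).  All
tests are two-sided at alpha 0.05 with no multiple-testing correction —
per-metric reporting.  All-zero difference vectors are reported as
`degenerate` with p = 1 rather than fed to either test.  The robustness
summary records, per metric and method family, the three setting means and
their spread (max − min), flagging the smaller-spread family.

## 5. What a green test establishes — and what it does not

The synthetic cohort demonstrates that the *pipeline* — indices, scoring,
goal machinery, statistics — behaves correctly and that the qualitative
comparison logic reproduces the expected directions when the strategy
behaviour matches the stated pattern.  It does not validate the clinical
magnitudes: phantom OAR doses, CI values and PQM totals live in realistic
ranges but are products of the shipped presets, not measurements.  Real
DICOM RT-DOSE/RT-STRUCT import is out of scope in this build (no DICOM
library in the supported environment); the documented array containers
(`DoseGrid`, `StructureSet`) are the input surface, and a thin import
layer mapping resampled DICOM onto them would slot in without touching
any evaluation code.

## 6. Known limitations

- Full-voxel DVHs differ from TPS DVHs that interpolate or use partial
  volumes; absolute Dx values on coarse grids carry voxel-size bias.
- The exponential falloff is isotropic and monotone; real plans have
  anisotropic gradients, entrance doses and cold spots the phantom cannot
  produce.
- The predictor surrogate is exact; prediction error and its effect on
  personalised goals are unmodelled.
- The hard-setting script preset under-scores relative to a real bimodal
  cohort (see above).
- Goal ties at personalised limits fail by the strict "<" convention
  (see §1).
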