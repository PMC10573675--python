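# Methods

## The measurement model

Renal stones on non-contrast CT are dense objects (typically 400–1800 HU)
against soft tissue and urine near 0–80 HU. `lithovol` implements the
interactive volumetry procedure used in clinical stone assessment: the
operator selects an inclusive Hounsfield *density window* `[hu_low, hu_high]`
that visually fits the stone; every voxel inside the window is stone
candidate; candidates are grouped into connected components; each component's
volume is its voxel count times the physical voxel volume `sx·sy·sz` (mm³).
The window is the method's **single operator-chosen control**, and everything
in the agreement layer is about how much results vary when that choice is
repeated by the same or different observers.

Design choices the underlying procedure leaves open, resolved here:

- **Threshold interval closed on both ends.** Matches the "density range
  that fits the stone" semantics and makes window monotonicity exact: for
  `W1 ⊆ W2`, volume(W1) ≤ volume(W2), voxel by voxel.
- **Default connectivity 26** (faces+edges+corners), so a stone whose
  oblique parts meet only diagonally stays one object; 6 and 18 are
  available everywhere and `label_components` guarantees
  count(26) ≤ count(18) ≤ count(6).
- **Default `min_voxels = 1`** — no silent noise filtering; filtered
  components are excluded from totals when a filter is requested.
- **Homogeneity flag**: a segment is *heterogeneous* when its internal HU
  range (max − min) exceeds 600 HU, the conventional cut-off for
  mixed-composition stones; threshold configurable.
- **Maximum diameter** is the exact largest pairwise distance between voxel
  centers in physical mm. For components above 10⁴ voxels a convex-hull
  prefilter is applied first (the farthest pair are hull vertices, so the
  result is unchanged). Bulk simulations may skip the diameter entirely
  (`compute_diameter=False`, reported NaN).
- **Display windows** (e.g. the wide "bone window" recommended for reading
  stones) affect visualization only and never enter the voxel sum.
- Stone *complexity* (staghorn vs plain) and *location* are anatomical case
  metadata supplied by the user; they are not computable from a stone mask
  alone.

Reported volumes are full-precision floats; formatted reports round to
integer mm³.

### Geometric estimators

The classical closed-form estimators are provided for comparison: sphere
`4/3·π·r³` on the maximum diameter, scalene ellipsoid `π/6·l·w·h` on the
three axis diameters, cumulative diameter (plain sum), elliptical surface
area `d·w·π/4`, and Ackermann's formula `0.6·π·r²`. Ackermann's formula is
implemented exactly as conventionally printed; note it is dimensionally an
area, not a volume — treat it as the historical index it is.

### Lithotripsy duration

The duration model is structural: `duration = volume / ablation_rate`,
with the ablation rate (mm³/s) keyed by laser source (Ho:YAG, Ho:YAG with
pulse modulation, thulium fiber), fiber diameter, pulse energy × frequency
(their product is the average power), and stone composition. Published
ablation speeds vary widely with protocol, so **no calibration ships
enabled**: rates come from a user JSON table, lookup is exact, and a
missing key is an explicit error rather than a nearest match. The bundled
`example_rates.json` contains clearly illustrative round numbers for tests
and demos only. Whether real procedures add overhead beyond `volume/rate`
(basketing pauses, duty cycle) is deliberately out of scope of this model.

## Agreement statistics

All statistics are implemented from their defining formulas; SciPy supplies
only distribution functions (and serves as an independent oracle in tests).

- **Lin CCC**: `2·s_xy / (s_x² + s_y² + (m_x − m_y)²)` with population
  (1/n) moments. 95% CI by Fisher z-transform with Lin's large-sample
  variance. Two identical constant series give CCC 1; two unequal constant
  series give CCC 0 with a warning. Always `|CCC| ≤ |Pearson r|`.
- **Kendall W**: mid-ranks within each rater, `W = 12·S / (m²(n³−n) − m·T)`
  with the tie correction `T = Σ(t³−t)`; significance via
  `χ² = m(n−1)W`, df `n−1`. The fully tied 0/0 case is defined as W = 1
  with a warning.
- **CV**: per (case, observer), sample (n−1) SD of the replicates divided
  by their mean, ×100. Observer summaries report the arithmetic mean of
  per-case CVs (median also reported); subgroup comparisons use the
  **median** of per-case-per-observer CVs.
- **Bland–Altman**: bias = mean difference, limits of agreement
  bias ± 1.96·SD(diff) with sample SD, repeatability coefficient
  RC = 1.96·SD(diff) — RC/SD ≡ 1.96 by construction.
- **Paired t-test** two-sided, df n−1; zero-variance differences are an
  error, not p = NaN.
- **Mann–Whitney U** from mid-ranks; exact two-sided p by full enumeration
  of rank assignments when both groups have ≤ 8 observations and no ties,
  otherwise the normal approximation with tie and continuity correction.
- Tests are two-sided throughout; no significance level is hard-coded in
  library code.

`agreement_report` runs the whole battery on a long-format measurement
table. `aggregation="median"` collapses replicates to per-case medians
before the pairwise/overall statistics — the only mode available for the
bundled dataset, which publishes per-case medians rather than raw
replicates; `"raw"` pairs raw values by (case, replicate).
Intra-observer concordance is operationalized as Kendall W across the
replicate-wise rankings of the cases within one observer (an assumption;
there is no single standard definition). Subgroup analyses are skipped
with a warning when metadata or replicates are missing; everything else
still runs.

### The bundled dataset

`lithovol/data/table2b.csv` is a published inter-observer reliability
table: 50 renal-stone cases, three observers of increasing endourology
experience, five blinded repeat segmentations each, summarized as per-case
median volumes with quartiles. The transcription is verbatim with the
original cell text in a `raw` provenance column; known quirks (a decimal
comma; three cells whose quartile interval does not bracket the median)
are preserved and excluded only from quartile-dependent checks. On these
medians the package computes overall Kendall W = 0.992 and pairwise Lin
CCCs of 0.995 (junior–expert), 0.992 (junior–senior) and 0.989
(senior–expert) — near-perfect inter-observer agreement. Replicate-level
quantities (per-observer CV, intra-observer W, subgroup tests) cannot be
recomputed from published medians; the simulator covers that code path
with known ground truth instead.

## The phantom simulator

`simulate_phantom` renders what matters for threshold volumetry and
nothing more: a noisy soft-tissue background (default 40 ± 15 HU), stones
at 800–1500 HU (constraint: stone HU must exceed background by > 300 HU),
Gaussian blur as a partial-volume surrogate (default σ = 0.7 mm), global
acquisition noise (default 10 HU), optional core/shell HU heterogeneity
(outer 40% of the stone radius at a different HU), and three shape
families: spheres, rotated ellipsoids, and "staghorn-like" unions of a
pelvis ellipsoid with three calyceal branch ellipsoids at fixed template
angles. It does **not** model CT physics (beam hardening, reconstruction
kernels, dual energy), patient anatomy, or slice-dependent noise; passing
tests show the measurement and statistics layers are correct on stone-like
geometry, not that any particular scanner protocol is unbiased.

Ground truth is analytic (`π/6·l·w·h`) for spheres and ellipsoids and a
fine-grid voxelization oracle at 1/8 of the voxel spacing (computed slab
by slab) for staghorn unions; truth depends on geometry only, never on the
noise realization. For a blur- and noise-free digitized sphere of radius
r, the measured volume is within the surface-layer bound `4πr²·h` of truth
at spacing h, and the error decreases with h.

**Observer model.** Variability enters through exactly one knob, matching
the real method's single degree of freedom: the lower window bound is
drawn fresh per replicate as `Normal(hu_low_mean, hu_low_sd)` (defaults
300 ± 25 HU) with a fixed generous upper bound (4000 HU). Degenerate draws
(low > high) are redrawn with a warning, bounded retries. The default
jitter of 25 HU is a one-time illustrative calibration chosen so that
per-observer mean CVs on the default cohort roster land in the 4–6% range
reported for trained human observers — tuning for realism, not ground
truth. `default_study_phantoms` draws a cohort-like roster (≈30% complex
branched stones, ≈half heterogeneous, ≈half multiple, volumes spanning
tens to thousands of mm³) with per-case metadata for the subgroup
analyses.

End-to-end, the simulated pipeline recovers its own parameters: CCC → 1
and CV → 0 as jitter → 0; an injected systematic threshold offset between
observers appears as a Bland–Altman bias of the right sign; and branched
stones are less repeatable than volume-matched spheres under identical
jitter (higher surface-to-volume ratio puts more voxels in the
threshold-sensitive blurred shell), mirroring the finding that complex
stones reproduce worse.

## Problem sizes and numerical notes

Default test and acceptance runs use 48³ grids at 1 mm spacing (32³ for
convergence studies down to 0.25 mm), 50-case rosters and 750-measurement
studies; these sizes keep every result stable while the whole suite runs
in well under a minute. Determinism: every stochastic operation takes an
explicit seed (`numpy.random.default_rng`); identical seeds give
bit-identical phantoms and tables. Ties in component sorting are broken
by label; CSV round-trips preserve volumes at full float precision.

## Known limitations

- The lithotripsy module is a structural stand-in: it will not predict
  clinical durations without a user-supplied, properly measured rate
  calibration, and it ignores intra-operative overhead.
- The observer model jitters only the lower threshold; real observers also
  vary in cropping, seed placement and slice review, so simulated CVs are
  a lower-bound-style emulation, not a forecast.
- Staghorn truth is an oracle measurement (refined voxelization), exact to
  O(h³/8³) only.
- DICOM reading assumes a single regular axial series; multi-frame,
  gantry-tilted or variably spaced series are out of scope.
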