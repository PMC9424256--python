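# Methods

## Scope and data model

The package consumes first-level fMRI outputs only: per-subject statistical
maps (t or contrast) and per-run condition effect maps, all on one shared
volumetric grid (or per-hemisphere surface vertex vectors). Preprocessing,
normalization and GLM estimation are upstream responsibilities. Values are
stored as flat C-order vectors; "linear voxel index" — the deterministic
tie-break order everywhere — means position in that vector. World
coordinates come from the NIfTI affine with +x anatomically right; a voxel
is left-hemisphere iff its center's world x < 0, and voxels within 1e-6 mm
of the midplane belong to neither hemisphere (they are excluded from both
hemisphere summaries). Surface data are treated as two 1-D vectors
concatenated left-then-right; no mesh geometry is needed for any
computation here, so none is modelled.

## Analysis mask

Top-fraction selection needs a definite "across the brain" voxel set. The
default mask is the intersection of voxels that are finite and nonzero in
every subject map — reproducible from the data alone, with resampling
zero-pads dropping out automatically — and an explicit mask file can be
supplied instead. Atlas reproductions should always report which mask was
used, because k = round(f·|mask|) depends on it.

## Binarization and atlas

* k is computed by round-half-up of f·|mask|; exactly k voxels are always
  selected, with ties at the k-th order statistic broken by ascending
  linear voxel index. This keeps the conservation identity Σ_v A(v) = k
  exact and testable, and makes runs bit-reproducible.
* Selection pools both hemispheres (volumes and surfaces alike) so that
  hemispheric asymmetries in selection counts are preserved rather than
  normalized away.
* Fixed-p thresholding uses the one-sided positive-tail Student-t critical
  value (the localizer contrast is directional); empty selections are legal
  under this rule, unlike top-fraction.
* Atlas values are stored as counts/n, so value × n is integral to machine
  precision; the per-subject left-hemisphere selection fraction
  LH/(LH+RH) is recorded alongside (NaN, logged, if a subject selects no
  hemispheric voxels).
* Stability curves subsample subjects *without* replacement (a subsample of
  the full cohort equals it, giving the r = 1 anchor at n = N) and
  correlate each subsample atlas with the full atlas over the mask; the
  seed is a required argument.

## Split-half QC

Halves are averages of per-run contrast maps (language − control), odd
run numbers (1-based) versus even; no GLM refitting happens downstream of
first-level outputs. Per-parcel Pearson r is computed on the parcel's
voxels (optionally restricted to voxels positive in both halves); parcels
with fewer than two usable voxels or zero variance are omitted from the
session mean with a logged warning. Fisher z = atanh(r) is applied per
parcel and then averaged — the standard variance-stabilized aggregate —
with r clamped to ±(1 − 1e-7) first so that identical halves (which occur
in noise-free tests) give a large finite z rather than infinity. The
exclusion rule (negative session) is applied to the mean raw r; since
atanh is odd and monotone this is sign-equivalent to applying it to mean z.
Both mean r and mean z are emitted because published summaries do not
always state which aggregate they print. Sessions with a single run cannot
be split and are passed through flagged `needs_review` for visual
inspection rather than silently dropped. Session selection takes the
highest mean r per subject; ties go to the lexicographically earliest
session id and are logged.

## Neural markers

* The fROI statistic per cross-validation fold is the across-run one-sample
  t of the held-in runs when two or more are held in, else the single
  held-in run's contrast map. Fold fROIs are recomputed per fold and never
  reused; the fold estimate is the left-out run's mean language−control
  response over the fROI, and folds are averaged. Because the selection
  data and estimation data are disjoint, the estimator is unbiased — the
  property the null-simulation tests check.
* Effect sizes are in the units of the input effect maps. If inputs are
  scaled to % BOLD signal change, so are the effect sizes; the package does
  not perform percent-signal-change conversion (no universal formula exists
  across GLM conventions), and callers who need it should scale their maps
  upstream.
* Voxel counting thresholds parcel t-values at t_crit(p, dof), one-sided,
  default p = 0.001 uncorrected. Across-run t-maps have dof = runs − 1;
  with 2-run sessions (dof = 1) this criterion is essentially unattainable,
  which is a property of that statistic, not a bug — marker studies should
  either use sessions with more runs or supply the scanner-side GLM t-map,
  whose dof reflects the full time series. The bundled marker summaries use
  8-run simulated sessions for this reason.
* Hemisphere aggregates are unweighted means over that hemisphere's
  parcels, for each marker; both r- and z-scale split-half aggregates are
  available (z is the primary, being the variance-stabilized scale).
  Lateralization uses summed hemispheric voxel counts,
  (LH − RH)/(LH + RH), defined as 0 (with a warning) when both are zero.
* Quantile summaries use linear interpolation between order statistics
  (numpy's default, type 7); stated here because quantile comparisons
  across software depend on it.

## Zero-variance t conventions

Two deliberate conventions exist for 0/0 t-statistics. In ranking contexts
(fold statistics, simulated session t-maps) zero-variance voxels get
sign(mean)·∞ so that noise-free fixtures still rank and threshold sensibly.
In the inference-style `group_t_map` they become missing (NaN) and are
logged, keeping downstream correlations well-defined. Mixing the two would
silently corrupt one use case or the other.

## Synthetic cohorts

The generator emulates what the pipeline needs and nothing more: a
population amplitude landscape A(v) as a sum of 3-D Gaussian blobs (three
left-hemisphere foci in inferior-frontal / anterior-temporal /
posterior-temporal neighborhoods and their right homotopes), per-subject
isotropic normal jitter of blob centers, per-subject log-normal amplitude
scaling, and i.i.d. Gaussian noise per run. "Control" is a flat zero
baseline plus noise, so language − control has expectation equal to the
(scaled, jittered) landscape. Defaults, chosen once as a realistic study
condition: 200 subjects, 2 runs, jitter sd 6 mm, noise sd 0.25 (a quarter
of the unit peak amplitude), log-scale sd 0.25, right-hemisphere amplitude
multiplier 0.7 (a left-lateralized network), on a 12 mm version of the
standard MNI bounding-box grid (16×19×16 = 4,864 voxels) with blob sigmas
of 22–24 mm so that the suprathreshold landscape occupies roughly the 10%
selection fraction of the volume. Subject i is seeded from (master seed,
i), so cohorts are bitwise reproducible and any subject regenerates in
isolation.

The target selection-probability landscape q(v) has no closed form (it
involves order statistics of jittered, scaled, noisy fields), so it is
estimated by Monte-Carlo: run the generative model plus the actual
top-fraction selection many times and average memberships. Atlas recovery
is then judged against binomial 3σ bounds, 3·sqrt(q(1−q)/n), at ≥99% of
voxels.

What passing these tests shows — and does not. They establish that the
estimators are correct and calibrated under the generative model:
conservation, tie-break determinism, unbiasedness of cross-validated
effect sizes, monotone degradation of split-half stability with noise,
and convergence of atlas values to selection probabilities. They do not
certify behavior under spatially autocorrelated noise, imperfect
registration, hemodynamic confounds, or non-Gaussian artifacts, none of
which the generator models.

## Problem sizes

Tests and the acceptance script run on the 12 mm simulation grid with
cohorts of 40–500 subjects and Monte-Carlo sizes of 2,000–4,000 draws;
these sizes were chosen so the binomial error of the Monte-Carlo reference
is small relative to the bounds being checked while the whole suite stays
interactive-fast.

## Known limitations

* No DICOM ingestion, registration, smoothing, or first-level GLM.
* Percent-signal-change scaling is the caller's responsibility.
* Surface support covers pooled selection, atlases and correlations on
  vertex vectors; there is no mesh-aware smoothing or resampling.
* Whether per-subject selection should pool hemispheres or treat them
  separately is a genuine design fork; pooling is used everywhere here
  because it preserves lateralization, and per-hemisphere selection can be
  emulated by calling the binarizer with single-hemisphere masks.
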