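# Methods notes

## The paradigm and its model

One fMRI run is six minutes of BOLD at TR = 2 s (180 frames) while the
stimulator cycles Off/On in one-minute blocks, starting in Off, with an
8 s amplitude ramp at the start of every block.  Runs carry a bipolar
configuration label (which adjacent contact pair, which lead, 5–6 mA)
and two condition labels that are inputs, not computed quantities: the
*therapeutic* flag of the configuration and the *responder* status of
the subject.  The full default study is 5 subjects (3 responders), 23
runs, 6 of them therapeutic (two per responder) — the run structure the
statistics were designed around.

### Run-level GLM

Voxel time series are first scaled to a temporal mean of 100 (per
voxel, AFNI-style), so regression coefficients read directly in percent
signal.  The design has six columns: On and Off boxcars, each equal to
1 only during its block's *plateau* (the 8 s ramps are left unmodeled —
this is also what keeps On, Off, and the constant term jointly
identifiable), convolved with a canonical double-gamma HRF (peak 6 s,
undershoot 16 s, peak:undershoot 6, normalized to unit time-integral so
a sustained block plateaus at its amplitude); plus discrete orthogonal
polynomials of degree 0–3 over the run for drift.  Frames with
FD > 0.5 mm or standardized DVARS > 1.5 are removed by row deletion
(strict inequalities; frame 0 is defined as FD = DVARS = 0).  The fit
is OLS; the run's summary is the [On] − [Off] contrast volume.

An alternative "linear" ramp mode models the ramps as trapezoids.  Note
that with both conditions modeled, linear ramps make On + Off ≡ 1 and
the design degenerate next to the constant; the mode exists for
model-mismatch simulations of the generator, not for fitting.

### Group model

Per parcel (or voxel), run contrasts are modeled with a linear mixed
model: fixed effects intercept + therapeutic + responder, random
intercept per subject, REML.  Therapeutic and responder are partially
confounded by design (therapeutic runs occur only in responders); the
default formula keeps both and reports the therapeutic coefficient, and
a reduced therapeutic-only formula is available.  With 5 subjects the
random-intercept variance frequently estimates at the boundary; such
fits fall back to OLS with a logged warning, which is the correct
limiting model.  p-values use a t reference with residual degrees of
freedom rather than the normal approximation — with 23 runs this keeps
the null rejection rate at the nominal 5% (the z approximation runs
near 6.5%).

Cluster-extent correction is Monte-Carlo: Gaussian noise fields on the
analysis grid, smoothed to a configured FWHM (in voxels), standardized,
thresholded two-sided at the voxel p, maximum cluster size recorded per
iteration under the configured adjacency (NN = 1 faces, 2 +edges,
3 +corners), and the threshold is the ceiling of the (1 − α) quantile,
never below 1 voxel.  The resulting voxel count is specific to the
grid and smoothness supplied; only the procedure is portable across
datasets.

### Network permutation statistics

Parcel means of a contrast (unweighted over voxels, and parcels weighted
equally regardless of size) are averaged across each condition's runs
first, giving one parcel vector per condition.  Per network the
statistic is the mean over member parcels — negated ("suppression") for
the one-sided BOLD test, absolute for the two-sided condition
difference, raw for streamline counts (larger = more connected).
Surrogates permute the parcel-to-network assignment uniformly
(equivalently the parcel vector), preserving network sizes, sampling
with replacement from the permutation group with the identity not
excluded.  With b surrogates at or beyond the observed statistic,
p = max(b, 1)/n_perm — floored at the resolution 1/n_perm, which at
the default n_perm = 10,000 is 1.0 × 10⁻⁴ — and Bonferroni over the
seven networks caps at 1.

Tie handling: a surrogate counts toward p when it is **at or beyond**
the observed value.  Ties therefore never count in favor of
significance — a constant parcel vector yields p = 1 — while for
continuous data the rule is indistinguishable from a strict inequality.
The alternative floor convention (b+1)/(n_perm+1) differs from ours by
at most one resolution step.

The one-sided suppression test is deliberately *not* shift-invariant:
suppression is an absolute quantity, so adding a constant to the parcel
vector changes every network's observed suppression and its p.  The
two-sided difference test, operating on d = v_a − v_b, is shift-
invariant in each input.

### Stimulation field and connectivity

The VAT for a bipolar configuration is the union of two spheres at the
anode and cathode contact centers with radius r = k·√(amplitude in mA),
k = 1.8 mm by default.  This is a declared geometric surrogate with a
configurable radius law — not a volume-conductor solution — chosen so
the radius grows sublinearly with current and sits at 4–4.4 mm at
5–6 mA, the scale of published activation radii.  Every downstream
statistic is agnostic to the VAT's origin; an externally computed
binary mask (NIfTI) can be supplied instead (`MaskVAT`), in which case
polyline intersection uses 0.5 mm dense resampling rather than the
exact segment–sphere test.

A streamline survives filtering iff any vertex lies inside the VAT or
any segment intersects it (exact closest-point-on-segment test, so a
crossing between two outside vertices is caught).  Each surviving
streamline is assigned to the parcel at the endpoint farther from the
VAT centroid (its distal termination); a traversal mode that credits
every parcel touched is available as an option.  Fractions are over
all filtered streamlines including unassigned terminations by default;
a cortical-only denominator is a switch.

## The synthetic-data generator

The generator emulates exactly the statistical structure the analysis
assumes, not anatomy:

* **Atlas** — parcels grown by seeded face-neighbor region growing
  inside the grid (1-voxel background shell), randomly assigned to
  networks with fixed sizes (default 17/13/12/13/12/13/20, summing to
  100).  The permutation statistics depend only on labels, so no
  surface geometry is modeled.
* **BOLD** — in-brain voxels follow
  `100 + drift(t) + amplitude · x(t) + AR(1) noise`, with `x` the same
  HRF-convolved On waveform the GLM uses, mean-centered, and the drift
  built from the same zero-mean orthogonal polynomials.  Centering
  makes noiseless voxel means exactly 100, so mean-100 scaling is the
  identity and the GLM recovers injected amplitudes to machine
  precision — the key end-to-end oracle.  Defaults: noise SD 0.5%
  signal, AR(1) = 0.3, drift amplitudes (0.2, 0.1, 0.1)%, values in the
  range of well-denoised 3 T block-design data.  The default effect is
  −0.3% in the default-mode network during therapeutic runs and zero
  elsewhere (per-network effect sizes are free parameters of the
  generator; no published per-network amplitudes exist).  Model
  mismatch (trapezoid effect waveform vs. plateau-only regressors) is a
  config option, off by default.
* **Motion** — slow random-walk traces (step SD 0.02 mm) with
  occasional step spikes (probability 0.02/frame, 1 mm) that produce
  FD excursions; spikes perturb the motion traces only, not the BOLD
  intensities.
* **Streamlines** — per category draw (network weights plus an
  "elsewhere" bucket summing to 1), a streamline either starts inside
  the VAT and terminates at a random voxel of a random parcel of the
  drawn network, or avoids the VAT entirely (rejection sampling).
  Filtering + endpoint assignment therefore recovers the weights within
  binomial error.  The default tractogram size is 200,000 streamlines
  per subject, scalable down.

What the generator does **not** emulate: realistic anatomy or surface
geometry, EPI distortion, physiological noise, electrode artifact,
spatial autocorrelation of BOLD noise, or subject-level random effects
beyond what the run structure induces.  Passing tests demonstrate the
correctness and calibration of the *procedures* under the assumed
model, not performance on real patient data.

## Numerical choices

* Drift basis: discrete (Gram) orthogonal polynomials from a QR of the
  Vandermonde basis — exactly orthogonal on the frame grid, degree ≥ 1
  columns have exactly zero mean (continuous Legendre sampled on a grid
  would be orthogonal only approximately).
* Near-collinearity of the design is judged on steady-state frames
  (t ≥ HRF duration): each column's R² against the rest must stay below
  1 − 1e-8.  Identification must not rest on HRF-onset transients; a
  zero-ramp design, exactly degenerate at steady state, is rejected
  with the offending column names.
* DVARS standardization divides the raw RMS frame difference by the
  within-run median — robust, dimensionless, median ≈ 1 under
  stationary noise, making the 1.5 threshold meaningful.  A constant
  run (median 0) is defined as all-zero DVARS.
* Rotation-to-mm conversion uses a 50 mm sphere (Power convention),
  configurable.
* Mixed-model degeneracy: random-effect variance below 1e-8 × residual
  variance, a convergence failure, or a linear-algebra error triggers
  the OLS fallback; the per-parcel method used is reported in the
  output table.
* Permutation vectorization draws n_perm independent row permutations
  and reduces with a membership matrix; all tests are exactly
  reproducible from their seed.

## Problem sizes used in the test suite

Statistical suites run on scaled-down grids chosen so every check keeps
its power while the full suite stays interactive: 8³ grids with 14
parcels (seven 2-parcel networks) for GLM/LME recovery and type-I
calibration (50 and 200 replicate studies of the full 23-run design),
the default 24³/100-parcel atlas for permutation calibration (500 null
vectors) and the resolution-floor check (n_perm = 10,000), a 6-parcel
atlas wherever exhaustive enumeration over all 20 assignments serves as
the oracle, and 10,000-streamline tractograms for weight recovery.  All
statistics are invariant to grid size by construction.

## Known limitations

* The VAT is a radius-law surrogate; absolute connectivity fractions
  from it should not be interpreted physically.
* Mixed-model p-values rely on a t approximation with residual df, not
  Satterthwaite/Kenward-Roger corrections.
* The Monte-Carlo cluster null assumes stationary Gaussian smoothness;
  no autocorrelation-function estimation from residuals is performed.
* Voxel-wise mixed models loop in Python; they are intended for the
  modest grids of this paradigm, not whole-brain 2 mm data.
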