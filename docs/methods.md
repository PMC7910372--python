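# Methods

## Scope and model

The package quantifies reversible neuroreceptor binding from dynamic PET
without blood sampling, using a receptor-free reference region. The primary
outcome is the non-displaceable binding potential BP_ND (unitless, ratio of
specifically bound to non-displaceable tracer at equilibrium); secondary
outcomes are the relative delivery R1 = K1/K1′ and the efflux rates k2
(target), k2a = k2/(1+BP_ND) (apparent) and k2′ (reference), all in min⁻¹.
The application it is built around is striatal D1-receptor imaging with
[11C]SCH23390 in mice (striatum vs whole cerebellum), where BP_ND runs
roughly 7–12 in healthy striatum and drops by about a third in the
Q175DN heterozygote.

All fitters assume the reference region is adequately described by a
one-tissue compartment and that both regions share the plasma input. SRTM
additionally assumes the target behaves as one tissue; the multilinear and
graphical methods only require the integrated equations to have reached
their linear regime over the frames used.

## Numerical design

* **Time base.** Rates are min⁻¹ internally; file I/O carries frame times
  in seconds, converted at the boundary. The default schedule is the
  39-frame, 90-min protocol (12×10, 3×20, 3×30, 3×60, 3×150, 15×300 s).
* **Convolutions.** The reference TAC is resampled to a 1-s grid by linear
  interpolation from frame midpoints anchored at (0, 0). Convolution with
  e^(−kt) uses the exact piecewise-linear update evaluated as an IIR
  filter, so no accuracy is lost at any step size. Model predictions are
  frame-averaged (trapezoid on the fine grid, boundaries exactly on grid
  points) before residuals are formed — the same operator the generator
  uses, so generator and fitter are discretization-consistent.
* **SRTM basis grid.** 128 log-spaced k2a values in [0.01, 1.0] min⁻¹,
  followed by a bounded scalar minimization between the best point's
  neighbours (tolerance 1e-6 in log k2a), removing grid quantization. A
  boundary optimum is flagged; for receptor-free targets the convolution
  term has near-zero weight, making k2a unidentifiable (and the flag
  expected) while BP_ND ≈ 0 remains valid.
* **Cumulative integrals** (MRTM/MRTM2/Logan) use exact frame-duration
  quadrature: a TAC value is the average of the underlying curve over its
  frame, so cumulative sums of value×duration give the exact integral at
  frame ends, minus half a frame to reach the midpoint. This keeps the
  multilinear fits within 0.5% of truth despite 300-s late frames, which
  midpoint-trapezoid quadrature does not achieve.
* **MRTM coefficient mapping.** −γ2 is the apparent efflux k2a (the
  reciprocal of the graphical intercept magnitude), verified against
  noise-free ground truth; the target efflux follows as k2 = k2a(1+BP_ND).
* **%SE.** SRTM/SRTM2 use the Jacobian-based covariance at the optimum
  with the delta method for derived ratios. For MRTM the plain OLS
  covariance is systematically optimistic (about one third low) because
  frame noise also enters the regressors — the cumulative integrals carry
  the accumulated noise of both TACs. The reported covariance therefore
  propagates per-frame noise through the quadrature matrix into every term
  of the operational equation, with the variance profile taken as
  value·e^(λt)/Δt (count statistics) and its scale estimated from the
  residuals after removing the regression projection. Monte-Carlo
  calibration puts the reported k2′ %SE within a few percent of the
  empirical replicate SD at all tested noise levels.
* **Weights.** Uniform frame weights by default; duration-decay weights
  w_j = Δt_j·e^(−λ t_j) are available behind the `weights` option.
* **AIC** uses the Gaussian-residual form n·ln(RSS/n) + 2k without
  small-sample correction; only differences between models on the same
  data are meaningful. RSS = 0 maps to −inf.
* **Degenerate inputs.** Identical target and reference make the
  multilinear design collinear; the fit returns BP_ND = 0 with an explicit
  flag rather than an arbitrary coefficient split. All-zero targets and
  references are rejected. Negative frame values (possible in
  reconstructed PET) pass through and are tolerated by all fitters.

## Parametric maps

Each masked voxel is fitted by the same regional code path sharing one
precomputed reference basis, so a homogeneous region reproduces the
regional fit exactly. A voxel is failed when its fit raises, produces
non-finite parameters, or lands outside BP_ND ∈ (−1, 50] (open at −1: DVR=0
is degenerate); for the graphical method additionally |DVR| > 51. Failed
voxels are NaN, never zero, and every map records its failure count and
exclusion fraction. No spatial smoothing or regularization is applied —
voxels are independent, which is exactly what makes the multilinear model's
noise sensitivity visible as scattered failed voxels while SRTM maps stay
clean.

## Time stability

Outcomes are refitted on TACs truncated at 5-min steps from 90 down to
45 min; the per-subject percent change is taken against the 90-min value
and aggregated as mean ± SD (n−1) per genotype. A duration is acceptable
when |mean| < 10% and SD < 5%. Subjects whose truncated fit fails are
dropped at that duration only.

## Reproducibility statistics

TRV is signed, 100·(retest − test)/((test+retest)/2); aTRV is its
magnitude; both signed and absolute group summaries are reported because
a group's printed TRV can otherwise be sign-ambiguous. Bland–Altman
operates on these percent differences (bias ± 1.96·SD), matching how such
biases are conventionally reported in percent. The ICC is the two-way
absolute-agreement single-measurement form computed on genotype-demeaned
values — removing the genotype means realizes "genotype as a fixed effect"
before the variance decomposition — estimating σ²_subject/(σ²_subject +
σ²_error). The unpaired t-test is classical pooled-variance (Welch behind
a flag); Cohen's d uses the unweighted two-group RMS SD. Report rounding is
one decimal for percents and d, three for ICC.

## Synthetic data: what it emulates and what it does not

The generator exists because the study's scans are not public; it
reproduces the statistical structure the analysis consumes, not scanner
physics.

* **Plasma input**: Feng-type bolus (delay 0.25 min, sharp peak near
  0.55 min, slow tail). It is a fixture — reference-tissue methods never
  see it — so its parameters are documented constants, not claims.
* **Reference kinetics**: K1′ = 0.9 mL/cm³/min, k2′ = 0.35 min⁻¹, giving
  cerebellar washout on the scale mouse data show.
* **Subjects**: BP_ND and R1 drawn per subject from truncated normals
  (lower bound 0) with genotype means/SDs taken from the published group
  table (e.g. WT 11.54 ± 2.03, HET 7.09 ± 0.65 under SRTM); the striatum
  is generated by the SRTM forward model with k2 = R1·k2′.
* **Noise**: independent Gaussian per frame with σ_j =
  α·√(C(t_j)·e^(λt_j)/Δt_j), λ = ln2/20.3 min⁻¹ (C-11). Regional TACs use
  α = 0.05; voxel-level experiments use α = 0.5, since a VOI of ~50–100
  voxels averages away an order of magnitude of noise. These are realism
  choices, fixed once.
* **Test–retest**: the retest session perturbs each subject's parameters
  by a 3%-CV factor, a stand-in for day-to-day biological and procedural
  variability (the study provides no within-subject variance
  decomposition). Simulated aTRV lands at 2–3%, the same order as the
  3.5–5.6% observed in vivo.
* **Model mismatch**: the two-tissue cohort (K1 0.9, k2 0.35, k3 0.07,
  k4 0.006 min⁻¹) has genuinely slow dissociation, so specific binding is
  still equilibrating at 90 min and SRTM BP_ND falls as the scan is
  truncated — the direction observed in vivo. Note that moderately slow
  k4 (~0.02) produces the opposite sign; the bias direction is a real
  function of where the kinetics sit, so the defaults were chosen in the
  genuinely slow regime. Simulated magnitude (≈ −6% at 60 min) is smaller
  than the in-vivo −13 to −18%, as expected when the true kinetic departure
  is unknown.
* **Phantom**: two disjoint ellipsoids (striatum 0.0215 cm³, cerebellum
  0.0507 cm³ at 0.776 mm isotropic voxels) on a 32³ grid. No resolution
  modelling, partial volume, attenuation, scatter or anatomy beyond that.
* **Seeding**: one global seed fans out through per-subject/per-session
  spawn keys, so enlarging a cohort never reshuffles existing subjects.

Consequently, passing tests demonstrate correctness of the estimators and
statistics under the stated noise and kinetic models — parameter recovery,
cross-model agreement, variance-component recovery, bias directions — not
agreement with any particular animal's in-vivo values, which depend on
radiochemistry, reconstruction and physiology the generator does not model.

## Problem sizes

Defaults used by the analysis drivers and the acceptance script: cohorts
of 9+14 (cross-sectional) and 4+7 paired subjects as in the study;
20-subject cohorts for the stability-direction and map-agreement
experiments; 10 noise seeds for the failed-voxel comparison; a 32³ phantom
(study-sized VOIs occupy ~150 voxels); 200 subjects for ICC recovery; 50
replicates for %SE calibration. These sizes make every Monte-Carlo check
stable while keeping a full run in the tens of seconds on one CPU.

## Known limitations

* k2′ from SRTM (k2/R1) is only exact for one-tissue-like references; the
  multilinear estimate is preferred for fixing k2′, as its %SE is smaller.
* The Logan method carries the usual noise-dependent negative bias; it is
  reported as-is, with no PCA/likelihood debiasing.
* The ICC realization (demean-then-ANOVA) is one defensible reading of
  "mixed model with genotype as fixed effect"; proprietary software may
  partition variance slightly differently.
* No partial-volume correction, registration or motion handling; label
  and dynamic volumes must share a grid exactly.
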