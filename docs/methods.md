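# Methods

## Signal models and conventions

All four models describe the orientation-averaged, normalized decay
S(b)/S(0) of the diffusion-weighted signal.  Diffusivities (ADC, D, D*,
DDC, D_m) are stored in units of 10⁻³ mm²/s and converted internally
before forming the dimensionless product b·D; this keeps user-facing
values on the scale clinical tables print (glioma ADC ≈ 1.0–1.4).  S(0) is
fixed to the measured b=0 intensity, not treated as a free fit parameter:
the model equations are ratios to S(0), and freeing it mostly trades bias
for variance at the SNR of interest.

Orientation averaging uses the geometric mean across directions per
b-shell (the arithmetic mean of log-signals), which is the correct
average for exponentially decaying magnitudes; the b=0 shell has no
diffusion encoding and is passed through as a plain mean.  Non-positive
samples are excluded from the log-mean and counted; a shell with no valid
direction invalidates the voxel.

## Mittag-Leffler evaluation

The CTRW kernel needs E_α(−x) for α ∈ (0, 1], x ≥ 0 — the completely
monotone branch.  A single power series is not a usable evaluator here:
although E_α is entire, for small α the alternating series passes through
intermediate terms of magnitude 10⁹⁰⁺ before converging (the peak term
grows like exp(k·ln x − lnΓ(αk+1))), so double precision loses everything
to cancellation.  The implementation therefore switches between three
regimes per element:

* **power series** wherever the predicted peak term stays ≤ 10⁴ (small x,
  or α near 1 — this covers the entire region visited by tissue-scale
  fitting, where x = (b·D_m)^β ≤ ~8 and fitted α ≥ 0.7); summation error
  is then ≤ ~10⁻¹¹;
* **Stieltjes spectral integral**
  E_α(−x) = sin(απ)/(απ) ∫₀^∞ exp(−(xu)^{1/α}) / (u² + 2u·cos(απ) + 1) du
  by adaptive quadrature elsewhere below x = 100.  The integrand is
  smooth, positive and cancellation-free; quadrature break points are
  placed at the decay knee (u = 1/x) and the denominator minimum
  (u = −cos απ);
* **asymptotic inverse-power series** Σ_k (−1)^{k+1} x^{−k}/Γ(1−αk) with
  optimal truncation for x ≥ 100 (terms at Γ poles vanish and are
  skipped).

α = 1 short-circuits to exp(−x) exactly, avoiding series cancellation at
the boundary the fitters visit.  Verified accuracy against independent
high-precision oracles (mpmath power series and fixed-Talbot Laplace
inversion of s^{α−1}/(s^α+x)): worst absolute error ≈ 2×10⁻⁹ on
x ∈ [0, 5] × α ∈ [0.05, 1], ≈ 6×10⁻⁹ on 5 < x < 50, relative ~10⁻⁴ in the
deep tail.  The documented contract is 10⁻⁸ absolute on x ∈ [0, 5].

A note on the asymptotic leading term: E_α(−x) ≈ x⁻¹/Γ(1−α) only holds to
1% once the second term x⁻²/Γ(1−2α) is negligible; the ratio is
≈ x⁻¹·Γ(1−α)/|Γ(1−2α)|, which is ~3% at x = 50 for α = 0.9.  The property
tests assert the 1% agreement from x = 500 and check 50 ≤ x < 500 against
the oracle directly.

## Fitting

All fits are deterministic bounded nonlinear least squares (trust-region
reflective) on the normalized signal over all 13 b-values, with residual
sum of squares as the loss.  Default bounds: diffusivities (10⁻⁴, 4]
(D ≤ 3, D* ≤ 500) ×10⁻³ mm²/s, f ∈ [0, 0.5], α and β ∈ [0.1, 1].  The α/β
lower bound of 0.1 excludes a pathological corner far below tissue values
(fitted indices in practice stay ≥ 0.7) where the kernel is expensive.

* **mono**: ADC over all b-values (not the clinical two-point b=0/1000
  formula), initialized from the log-linear slope.
* **IVIM**: segmented — D from the log-linear fit on b ≥ 200 s/mm² (the
  largest shell boundary below which perfusion still contributes), then
  (f, D*) with D frozen, then one joint refinement parameterized as
  (D, D*−D, f) so D < D* holds by construction.  The split is a config
  knob and must be a member of the scheme.
* **SEM**: (DDC, α) initialized from the mono fit (DDC ← ADC, α ← 0.9).
* **CTRW**: multi-start over (α, β) ∈ {(0.9, 0.95), (0.7, 0.9),
  (0.95, 0.8)} with D_m ← ADC, best residual wins, residual ties broken
  toward larger α.  The multi-start guards against the partially
  exchangeable roles of α and β on a 13-point curve.

Solver tolerances are 10⁻¹⁰ (xtol/ftol/gtol) — orders of magnitude below
the 10⁻³/10⁻² recovery contracts, chosen for runtime on whole-cohort
fits.  Voxel-level failures (non-positive signals, solver breakdown) are
recorded in a validity mask and never abort a volume; degenerate constant
signals return the lower ADC bound with a `degenerate` flag.

## VOI analysis

The VOI is consumed as a given binary mask; the delineation protocol
(contrast-enhancing region, or the T2-dark-fluid hyperintensity when no
enhancement is present, avoiding hemorrhage/calcification/edema/necrosis)
is an upstream labeling step, documented but not computable here.  The
VOI mean pools all valid voxels of the 3D mask as one population (no
slice-wise averaging); the voxel volume defaults to 2.2³ mm³ from the
acquisition geometry.  VOI volumes are reported in mm³.

## Group statistics

Each parameter × genotype comparison is gated: Shapiro-Wilk per group at
α = 0.05, both groups must pass; then Levene's test at 0.05 chooses
pooled vs Welch t; otherwise the two-sided Mann-Whitney U.  (The gate
thresholds are conventional choices; the source analysis names the tests
but not the α or the both-groups rule.)  Summaries are mean ± SD on the
t path and median (Q1, Q3) on the U path.  The 18 raw p-values (9
parameters × 2 questions) are adjusted together by Benjamini-Hochberg;
reports carry both raw and adjusted values since published tables are
ambiguous about which they print.

Cohen's d uses the pooled SD on raw values regardless of the gate (the
only reading consistent with d being reported alongside U statistics),
with group order fixed as (wild-type, mutant) and (non-codeleted,
codeleted): a negative d means the second group is higher.  Chi-square
tests of 2×k count tables apply Yates continuity correction only for 2×2
tables with an expected count < 10.  Inter-rater agreement is ICC(2,1) —
two-way random effects, absolute agreement, single rater — from the ANOVA
decomposition with the standard F-bound 95% CI; an exact-agreement matrix
(MSE = 0) returns a degenerate CI at the point estimate.

## ROC diagnostics

The empirical ROC is traced over all observed values; AUC is the
trapezoidal area, identical to the normalized Mann-Whitney statistic with
half-credit for ties; the 95% CI uses DeLong's structural-components
variance.  The classifier direction is auto-oriented so AUC ≥ 0.5 and
recorded.  The operating threshold maximizes Youden's J with ties broken
toward the smaller threshold, and the decision rule is inclusive
(predict positive at values on the positive side of, or equal to, the
threshold).  Positive classes follow the clinical convention: IDH-mutant
for the IDH question; 1p/19q non-codeleted for the codeletion question
(asked within IDH-mutant subjects, 12 vs 31).  Stratified re-evaluation
applies a cohort-level threshold unchanged within morphology strata;
strata missing a class report accuracy only.

`accuracy_from_rates` inverts printed (sensitivity, specificity, group
sizes) to integer confusion counts, rejecting rates farther than 0.005
from every integer count, and recomputes the accuracy — this makes
published operating-point tables checkable without raw data.

## Synthetic cohort

The generator emulates the study's inputs at the cohort level, not the
anatomy: per-subject "true" parameters are drawn from group
distributions, per-voxel signals are synthesized from a forward model and
Rician-corrupted per direction, and each VOI is packed into a small
volume with a mask.

* **Group distributions**: normal, with location = printed median and
  sd = IQR/1.349 where the published summary is median (Q1, Q3), or the
  printed mean/SD directly.  A lognormal family (median-parameterized) is
  available for skewed parameters.  Draws are clipped to physical bounds;
  a spec whose clipping alters more than half the draws is rejected.
* **Generating model**: CTRW by default — the richest of the four — so
  fitting the other models to the synthetic signals reproduces the model
  mismatch present in real tissue (a visible consequence: fitted IVIM_D
  can separate the groups more sharply than its generating spec alone
  implies, because it inherits contrast from the CTRW truth).  A config
  switch enables per-model self-generation for pure round-trip tests.
* **Noise**: Rician per direction before averaging, SNR defined at b=0 on
  the normalized signal: observed = |s + (g₁ + i g₂)/SNR|.  SNR 50 is the
  cohort default.
* **Intra-VOI heterogeneity**: voxel parameters are the subject's truth
  times (1 + 0.05·g), clipped — a 5% CV reflecting that the VOI is a
  delineated *solid* tumor region excluding necrosis and cysts.
* **Scale**: VOIs default to 24–64 voxels (8–16 in the acceptance run)
  versus thousands in clinical delineations; this is a deliberate
  runtime scale-down.  Group contrasts live in the between-subject
  distributions and are unaffected; VOI-mean noise is slightly larger
  than clinical.
* **Morphology**: binary flags (cystic/necrosis, hemorrhage, edema,
  enhancement) and a location class drawn per subject at the published
  per-group rates; an optional `enhancement_alpha_shift` lowers the CTRW
  and SEM α of enhancing subjects to emulate the reduced α observed in
  enhancing tumors (default 0 — the main cohort does not build that
  association in).

For normal specs the generator also emits the analytic expected AUC,
Φ(|Δμ|/√(σ₁²+σ₂²)), with the IDH-mutant side pooled as the 31:12 mixture
of the two mutant groups.  The end-to-end check asks the fitted CTRW_α
IDH AUC to land within ±0.08 of this analytic value.

What a green synthetic run does *not* establish: the generator draws the
nine parameters independently within subject (no correlation structure),
contains no partial-volume, motion, susceptibility or calcification
effects, and its signals come from a single generating model — so it
validates the estimation chain, not the biology.

## Known limitations

* The spectral-integral fallback costs ~0.3 ms per scalar; fitters that
  wander into small α at high b pay for it (bounded by the α ≥ 0.1
  constraint).
* DeLong CIs are asymptotic and can be optimistic at n = 12 per class.
* The segmented IVIM fit assumes perfusion is negligible above the split
  b-value; with D* near the split scale the stage-1 D absorbs perfusion
  signal, as in any segmented implementation.
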