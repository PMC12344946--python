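# qdwi — quantitative multi-b-value diffusion MRI for glioma genotyping

`qdwi` implements the quantitative analysis chain used to predict the IDH
mutation and 1p/19q codeletion status of adult diffuse gliomas from
multi-b-value diffusion-weighted MRI (DWI): voxelwise fitting of four
diffusion signal models, VOI-level parameter extraction, normality-gated
group statistics with false-discovery-rate control, and ROC diagnostics
with Youden-index operating points.  It is aimed at imaging scientists who
want a tested, reproducible reference for these models — including the
numerically delicate Mittag-Leffler kernel of the continuous-time random
walk (CTRW) model — together with a synthetic cohort generator that stands
in for patient data.

## The models

For the normalized signal S(b)/S(0) at diffusion weighting b (s/mm²):

| model | equation | parameters |
|---|---|---|
| mono-exponential | exp(−b·ADC) | ADC |
| IVIM (bi-exponential) | f·exp(−b·D*) + (1−f)·exp(−b·D) | D, D*, f |
| stretched exponential | exp(−(b·DDC)^α) | DDC, α |
| CTRW | E_α(−(b·D_m)^β) | D_m, α, β |

where E_α is the one-parameter Mittag-Leffler function
E_α(z) = Σ_k z^k / Γ(αk+1), the natural generalization of the exponential
that arises from random walks with heavy-tailed waiting times.  The CTRW
temporal index α and spatial index β quantify diffusion heterogeneity in
time and space; both are bounded in (0, 1].  Diffusivities are expressed
in 10⁻³ mm²/s throughout, the scale on which clinical values are printed.

The default acquisition scheme is 13 b-values (0, 10, 20, 30, 50, 70, 100,
150, 200, 400, 800, 1500, 2000 s/mm²) with 30 diffusion-encoding
directions; signals are orientation-averaged (geometric mean per shell)
before fitting.

## Worked example

Fit the CTRW model to a noisy synthetic decay curve:

```python
import numpy as np
from qdwi import (DWISignal, CTRWParams, ctrw_signal, default_scheme,
                  fit_ctrw, mittag_leffler_neg)

scheme = default_scheme()
truth = CTRWParams(dm=1.218, alpha=0.825, beta=0.938)
clean = ctrw_signal(scheme.b, truth)
print("E_0.825(-1):", round(mittag_leffler_neg(1.0, 0.825), 6))

rng = np.random.default_rng(0)
noisy = np.sqrt((clean + rng.standard_normal(13) / 50) ** 2
                + (rng.standard_normal(13) / 50) ** 2)   # Rician, SNR 50
fit = fit_ctrw(DWISignal(scheme, noisy[0], noisy))
print(f"fitted: Dm={fit.params.dm:.3f}  alpha={fit.params.alpha:.3f}  "
      f"beta={fit.params.beta:.3f}  (rss={fit.rss:.2e})")
```

prints

```
E_0.825(-1): 0.384028
fitted: Dm=1.274  alpha=0.866  beta=0.961  (rss=2.88e-03)
```

— a single voxel at SNR 50 recovers the generating parameters to within a
few percent; VOI averaging over tens of voxels tightens this further (the
noiseless round-trip is exact to the solver tolerance).

## The analysis

The `analysis/` scripts run the full study pipeline on synthetic data:

1. `01_simulate_cohort.py` — generate a 95-subject cohort (52 IDH
   wild-type, 12 IDH-mutant non-codeleted, 31 IDH-mutant codeleted) whose
   per-group parameter distributions match the published medians/IQRs of a
   clinical glioma cohort, with Rician noise at SNR 50.
2. `02_fit_parameter_maps.py` — fit all four models voxelwise, extract VOI
   means, assemble `results/cohort_table.csv`, and measure two-reading
   ICC(2,1) reproducibility.
3. `03_group_statistics.py` — Shapiro-Wilk/Levene-gated t, Welch-t or
   Mann-Whitney U tests for the 18 parameter x genotype hypotheses,
   Benjamini-Hochberg correction, Cohen's d, and chi-square tests of the
   morphology flags.
4. `04_roc_diagnostics.py` — ROC curves with DeLong 95% CIs and
   Youden-index thresholds per parameter and question, plus re-evaluation
   of the fixed CTRW_α threshold within morphology strata.
5. `05_accuracy_reconstruction.py` — verify that the published operating
   points are internally consistent: each printed accuracy is reproduced
   from the printed sensitivity/specificity and the group sizes by integer
   confusion-matrix arithmetic.

Intermediate NIfTI volumes live under `scratch/`; tables land in
`results/`.

## Acceptance script

`scripts/acceptance.py` re-runs the core computation from scratch — it
simulates the reference-preset cohort at the given seed, fits all models
voxelwise, runs the group statistics and ROC diagnostics, reconstructs the
published operating-point accuracies, and writes the results JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
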