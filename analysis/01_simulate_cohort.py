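"""Simulate the reference glioma cohort.

Generates the 95-subject synthetic cohort (52 IDH wild-type / 12 mutant
non-codeleted / 31 mutant codeleted) with the 13-b-value, 30-direction
scheme and Rician noise at SNR 50, writes the NIfTI fixture tree under
scratch/cohort, and records the analytic AUC each parameter is expected to
reach given the generating group distributions.

VOIs are scaled down to 24-64 voxels per subject (clinical VOIs run to
thousands of voxels) to keep the full pipeline tractable on one CPU; the
group contrasts are unaffected because they live in the between-subject
distributions.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from qdwi.simulate import generate_cohort, reference_cohort_config  # noqa: E402

SEED = 20260917


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    cfg = reference_cohort_config(seed=SEED)
    cohort = generate_cohort(cfg, out_dir=ROOT / "scratch" / "cohort")
    cohort.expected_auc.to_csv(results / "expected_auc.csv", index=False)
    n_vox = [int(s.mask.sum()) for s in cohort.subjects]
    print(f"simulated {len(cohort.subjects)} subjects "
          f"(VOI sizes {min(n_vox)}-{max(n_vox)} voxels, SNR {cfg.snr})")
    for question, grp in cohort.expected_auc.groupby("question"):
        best = grp.sort_values("expected_auc").iloc[-1]
        print(f"largest analytic AUC for {question}: {best.parameter} "
              f"({best.expected_auc:.3f})")
    print("the CTRW temporal heterogeneity index carries the strongest "
          "IDH contrast by construction of the group distributions")


if __name__ == "__main__":
    main()
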