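"""Group statistics: 9 parameters x 2 molecular questions.

Runs the normality-gated comparisons (Shapiro-Wilk -> Levene -> pooled/Welch
t or Mann-Whitney U) for IDH status and, within IDH-mutant subjects, 1p/19q
codeletion; adjusts the 18 p-values jointly with Benjamini-Hochberg; reports
Cohen's d per row; and tabulates the morphology flags per group with
chi-square tests.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from qdwi.stats import chi_square_categorical, run_group_comparisons  # noqa: E402
from qdwi.voi import MORPHOLOGY_FLAGS, CohortTable  # noqa: E402


def main() -> None:
    table = CohortTable.from_csv(ROOT / "results" / "cohort_table.csv")
    comparisons = run_group_comparisons(table)
    comparisons.to_csv(ROOT / "results" / "group_comparisons.csv",
                       index=False, float_format="%.6g")
    sig = comparisons[comparisons.p_bh < 0.05]
    print(f"{len(sig)}/18 hypotheses significant after BH correction:")
    for _, r in sig.iterrows():
        print(f"  {r.question:7s} {r.parameter:11s} {r.test:15s} "
              f"p_bh={r.p_bh:.4f} d={r.cohens_d:+.2f}")

    df = table.df
    rows = []
    for flag in MORPHOLOGY_FLAGS:
        counts = np.array([
            [int(df[(df.idh_status == g) & (df[flag])].shape[0]),
             int(df[(df.idh_status == g) & (~df[flag].astype(bool))].shape[0])]
            for g in ("wild-type", "mutant")])
        if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
            continue
        stat, p = chi_square_categorical(counts)
        rows.append({"flag": flag, "chi2": stat, "p": p})
    morph = pd.DataFrame(rows)
    morph.to_csv(ROOT / "results" / "morphology_tests.csv", index=False,
                 float_format="%.6g")
    print("morphology flags vs IDH status (chi-square):")
    print(morph.to_string(index=False))


if __name__ == "__main__":
    main()
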