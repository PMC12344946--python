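"""End-to-end cohort analysis: fit maps, extract VOI means, build the table.

Ties the modules together the way the study pipeline runs: for every
subject, fit all four diffusion models voxelwise inside the VOI mask,
average each parametric map over the VOI, and assemble the per-subject
rows into a :class:`~qdwi.voi.CohortTable` ready for group statistics and
ROC analysis.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .fitting import MODEL_PARAMETERS, FitConfig, fit_parameter_maps
from .roc import roc_analysis
from .simulate import SyntheticCohort, SyntheticSubject
from .voi import (DEFAULT_VOXEL_VOLUME_MM3, SubjectRecord, CohortTable,
                  build_cohort_table, extract_voi_mean)

logger = logging.getLogger(__name__)

__all__ = ["fit_subject", "fit_cohort", "roc_table"]


def fit_subject(subject: SyntheticSubject, cfg: FitConfig = FitConfig(),
                models: tuple[str, ...] = tuple(MODEL_PARAMETERS),
                scheme=None) -> SubjectRecord:
    """Fit the requested models for one subject and pool the VOI means."""
    means: dict[str, float] = {}
    n_vox = 0
    for model in models:
        maps = fit_parameter_maps(subject.volume_4d, scheme, subject.mask,
                                  model, cfg)
        for pmap in maps:
            try:
                voi = extract_voi_mean(pmap, subject.mask)
            except ValueError:
                logger.warning("subject %s: no valid voxels for %s",
                               subject.subject_id, pmap.name)
                continue
            means[pmap.name] = voi.mean
            n_vox = voi.n_voxels
    return SubjectRecord(
        subject_id=subject.subject_id, idh_status=subject.idh_status,
        codeletion_status=subject.codeletion_status, parameter_means=means,
        morphology=subject.morphology, location=subject.location,
        voi_volume_mm3=n_vox * DEFAULT_VOXEL_VOLUME_MM3)


def fit_cohort(cohort: SyntheticCohort, cfg: FitConfig = FitConfig(),
               models: tuple[str, ...] = tuple(MODEL_PARAMETERS)
               ) -> CohortTable:
    """Fit every subject of a synthetic cohort into a cohort table."""
    scheme = cohort.config.scheme
    records = [fit_subject(sub, cfg, models, scheme)
               for sub in cohort.subjects]
    table = build_cohort_table(records)
    table.df["group"] = [sub.group for sub in cohort.subjects]
    return table


def roc_table(cohort_table: CohortTable) -> pd.DataFrame:
    """ROC results for every parameter and both molecular questions.

    Positive classes follow the clinical convention: IDH-mutant for the
    IDH question; 1p/19q non-codeleted for the codeletion question (asked
    within IDH-mutant subjects only).
    """
    df = cohort_table.df
    rows = []
    for question, column, positive, subset in (
            ("IDH", "idh_status", "mutant", None),
            ("1p/19q", "codeletion_status", "non-codeleted",
             ("idh_status", "mutant"))):
        sub = df if subset is None else df[df[subset[0]] == subset[1]]
        for param in cohort_table.parameters:
            vals = sub[param].to_numpy(dtype=float)
            keep = np.isfinite(vals)
            res = roc_analysis(vals[keep],
                               sub[column].to_numpy()[keep],
                               positive, parameter=param, question=question)
            rows.append({
                "question": question, "parameter": param,
                "threshold": res.threshold, "auc": res.auc,
                "ci_lo": res.ci_95[0], "ci_hi": res.ci_95[1],
                "sensitivity": res.sensitivity,
                "specificity": res.specificity, "accuracy": res.accuracy,
                "direction": res.direction, "n_pos": res.n_pos,
                "n_neg": res.n_neg})
    return pd.DataFrame(rows)
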