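"""VOI-level parameter extraction and cohort table assembly.

The volume of interest (VOI) is consumed as a given binary mask over the
solid-tumor region; its delineation (enhancing region, or T2-dark-fluid
hyperintensity for non-enhancing tumors) is an upstream labeling protocol,
not computed here.  The VOI mean pools all valid voxels of the 3D mask as a
single population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import PARAMETER_NAMES, ParameterMap

logger = logging.getLogger(__name__)

__all__ = ["VOIMean", "SubjectRecord", "CohortTable", "extract_voi_mean",
           "build_cohort_table", "DEFAULT_VOXEL_VOLUME_MM3",
           "MORPHOLOGY_FLAGS"]

#: 2.2 mm isotropic-equivalent voxel (220 mm FOV / 100 matrix, 2.2 mm slices)
DEFAULT_VOXEL_VOLUME_MM3 = 2.2 * 2.2 * 2.2

MORPHOLOGY_FLAGS = ("cystic_necrosis", "hemorrhage", "edema", "enhancement")

IDH_LEVELS = ("wild-type", "mutant")
CODELETION_LEVELS = ("codeleted", "non-codeleted", "not-applicable")


@dataclass(frozen=True)
class VOIMean:
    """Mean of one parametric map over a VOI."""

    mean: float
    n_voxels: int
    volume_mm3: float


def extract_voi_mean(pmap: ParameterMap, mask: np.ndarray,
                     voxel_volume_mm3: float = DEFAULT_VOXEL_VOLUME_MM3
                     ) -> VOIMean:
    """Arithmetic mean of a map over voxels in the mask that fitted validly.

    Raises if the mask is empty or contains no valid voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != pmap.data.shape:
        raise ValueError("mask must align with the parameter map grid")
    if not mask.any():
        raise ValueError("empty VOI mask")
    use = mask & pmap.valid
    n = int(use.sum())
    if n == 0:
        raise ValueError(f"no valid voxels under the mask for {pmap.name}")
    return VOIMean(mean=float(pmap.data[use].mean()), n_voxels=n,
                   volume_mm3=n * voxel_volume_mm3)


@dataclass
class SubjectRecord:
    """One subject: molecular labels, morphology flags and VOI parameter means."""

    subject_id: str
    idh_status: str
    codeletion_status: str
    parameter_means: dict[str, float]
    morphology: dict[str, object] | None = None
    location: str | None = None
    voi_volume_mm3: float = float("nan")

    def __post_init__(self) -> None:
        if self.idh_status not in IDH_LEVELS:
            raise ValueError(f"idh_status must be one of {IDH_LEVELS}")
        if self.codeletion_status not in CODELETION_LEVELS:
            raise ValueError(
                f"codeletion_status must be one of {CODELETION_LEVELS}")
        if (self.idh_status == "wild-type"
                and self.codeletion_status != "not-applicable"):
            raise ValueError("codeletion status applies to IDH-mutant only")
        if (self.idh_status == "mutant"
                and self.codeletion_status == "not-applicable"):
            raise ValueError("IDH-mutant subjects need a codeletion status")


class CohortTable:
    """Per-subject VOI-mean parameters plus molecular labels.

    Backed by a :class:`pandas.DataFrame` with one row per subject.  Rows
    with a missing parameter are kept but flagged incomplete; statistics
    drop missing values per comparison.
    """

    LABEL_COLUMNS = ("subject_id", "group", "idh_status", "codeletion_status")

    def __init__(self, df: pd.DataFrame,
                 parameters: tuple[str, ...] = PARAMETER_NAMES):
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicate subject ids: {sorted(set(dupes))}")
        self.df = df.reset_index(drop=True)
        self.parameters = tuple(parameters)

    def __len__(self) -> int:
        return len(self.df)

    def values_for(self, parameter: str, **selectors) -> np.ndarray:
        """Finite parameter values for subjects matching the selectors."""
        if parameter not in self.parameters:
            raise KeyError(parameter)
        sel = np.ones(len(self.df), dtype=bool)
        for col, val in selectors.items():
            sel &= (self.df[col] == val).to_numpy()
        vals = self.df.loc[sel, parameter].to_numpy(dtype=float)
        return vals[np.isfinite(vals)]

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path: str | Path,
                 parameters: tuple[str, ...] = PARAMETER_NAMES) -> "CohortTable":
        return cls(pd.read_csv(path), parameters)


def build_cohort_table(records: list[SubjectRecord],
                       parameters: tuple[str, ...] = PARAMETER_NAMES
                       ) -> CohortTable:
    """Assemble subject records into a cohort table.

    Missing parameters become NaN; such rows are flagged ``complete=False``
    and logged, and are dropped per-parameter by downstream statistics.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "subject_id": rec.subject_id,
            "idh_status": rec.idh_status,
            "codeletion_status": rec.codeletion_status,
            "voi_volume_mm3": rec.voi_volume_mm3,
            "location": rec.location,
        }
        for flag in MORPHOLOGY_FLAGS:
            row[flag] = (rec.morphology or {}).get(flag)
        missing = [p for p in parameters
                   if not np.isfinite(rec.parameter_means.get(p, np.nan))]
        for p in parameters:
            row[p] = rec.parameter_means.get(p, np.nan)
        row["complete"] = not missing
        if missing:
            logger.warning("subject %s incomplete: missing %s",
                           rec.subject_id, ", ".join(missing))
        rows.append(row)
    return CohortTable(pd.DataFrame(rows), parameters)
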