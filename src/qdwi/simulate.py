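"""Synthetic multi-b-value DWI cohort generator.

Simulates per-subject "true" diffusion parameters from group-level
distributions (defaults reproduce the published glioma cohort medians/IQRs
in :mod:`qdwi.reference`), synthesizes per-voxel multi-b, multi-direction
signals from a forward model, corrupts them with Rician noise, and packs
each subject's VOI into a small NIfTI-compatible volume with a binary mask.

Conventions (see docs/methods.md for rationale):

* inter-subject distributions are normal with sd = IQR/1.349 where the
  published summary is median (Q1, Q3), or the printed sd where the summary
  is mean +/- sd; a lognormal family is available for skewed parameters;
* the generating forward model is CTRW — the richest of the four — so that
  fitting the other models to the synthetic data mirrors the model mismatch
  present in real tissue; per-model self-generation is a config switch;
* Rician noise is applied per diffusion-encoding direction before
  orientation averaging, with SNR defined at b=0 on the normalized signal:
  observed = |signal + (g1 + i g2)/SNR|, g ~ N(0,1);
* intra-VOI heterogeneity multiplies each voxel's parameters by
  (1 + CV * g), clipped to physical bounds.

A fixed seed makes every output byte-identical across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import reference
from .fitting import PARAMETER_NAMES, DirectionAverage, average_directions
from .models import CTRWParams, IVIMParams, MonoParams, SEMParams, \
    ctrw_signal, ivim_signal, mono_signal, sem_signal
from .scheme import BValueScheme, default_scheme, write_bval

logger = logging.getLogger(__name__)

__all__ = ["GroupSpec", "SyntheticCohortConfig", "SyntheticSubject",
           "SyntheticCohort", "sample_subject_params",
           "synthesize_voi_signals", "generate_cohort", "default_group_specs",
           "reference_cohort_config", "iqr_to_sd", "analytic_auc",
           "expected_auc_table", "PARAM_CLIP_BOUNDS"]

#: physical clipping bounds per parameter (diffusivities in 1e-3 mm²/s)
PARAM_CLIP_BOUNDS = {
    "Mono_ADC": (0.05, 4.0), "IVIM_D": (0.05, 3.0), "IVIM_Dstar": (0.5, 500.0),
    "IVIM_f": (0.0, 0.5), "SEM_DDC": (0.05, 4.0), "SEM_alpha": (0.1, 1.0),
    "CTRW_Dm": (0.05, 4.0), "CTRW_alpha": (0.1, 1.0), "CTRW_beta": (0.1, 1.0),
}

_GENERATORS = {
    "mono": (("Mono_ADC",),
             lambda b, v: mono_signal(b, MonoParams(v["Mono_ADC"]))),
    "ivim": (("IVIM_D", "IVIM_Dstar", "IVIM_f"),
             lambda b, v: ivim_signal(
                 b, IVIMParams(v["IVIM_D"], v["IVIM_Dstar"], v["IVIM_f"]))),
    "sem": (("SEM_DDC", "SEM_alpha"),
            lambda b, v: sem_signal(b, SEMParams(v["SEM_DDC"],
                                                 v["SEM_alpha"]))),
    "ctrw": (("CTRW_Dm", "CTRW_alpha", "CTRW_beta"),
             lambda b, v: ctrw_signal(
                 b, CTRWParams(v["CTRW_Dm"], v["CTRW_alpha"],
                               v["CTRW_beta"]))),
}


def iqr_to_sd(q1: float, q3: float) -> float:
    """SD of a normal with the given interquartile range (IQR/1.349)."""
    return (q3 - q1) / 1.349


@dataclass(frozen=True)
class GroupSpec:
    """Generating distributions for one molecular group.

    ``distributions`` maps parameter name to ``(family, loc, scale)`` with
    family "normal" (loc = mean, scale = sd) or "lognormal" (loc = median,
    scale approximately the sd; the log-sd is taken as scale/loc).
    """

    label: str
    n_subjects: int
    distributions: dict[str, tuple[str, float, float]]
    idh_status: str = "wild-type"
    codeletion_status: str = "not-applicable"
    voxels_per_voi: tuple[int, int] = (24, 64)
    intra_voi_cv: float = 0.05
    morphology_rates: dict = field(default_factory=dict)
    #: additive shift of CTRW/SEM alpha in subjects with enhancement,
    #: used to emulate the reduced alpha seen in enhancing tumors
    enhancement_alpha_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 3:
            raise ValueError("groups need n_subjects >= 3")
        for name, (family, _loc, scale) in self.distributions.items():
            if family not in ("normal", "lognormal"):
                raise ValueError(f"unknown family {family!r} for {name}")
            if scale < 0:
                raise ValueError(f"negative scale for {name}")
        lo, hi = self.voxels_per_voi
        if not (1 <= lo <= hi):
            raise ValueError("invalid voxels_per_voi range")


def _summary_to_distribution(summary) -> tuple[str, float, float]:
    if summary[0] == "median_iqr":
        _, med, q1, q3 = summary
        return ("normal", med, iqr_to_sd(q1, q3))
    _, mean, sd = summary
    return ("normal", mean, sd)


def default_group_specs() -> list[GroupSpec]:
    """The three molecular groups of the reference cohort (52/12/31)."""
    status = {
        "idh-wild": ("wild-type", "not-applicable"),
        "mutant-noncodel": ("mutant", "non-codeleted"),
        "mutant-codel": ("mutant", "codeleted"),
    }
    specs = []
    for label, n in reference.GROUP_SIZES.items():
        dists = {p: _summary_to_distribution(s)
                 for p, s in reference.GROUP_SUMMARIES[label].items()}
        idh, codel = status[label]
        specs.append(GroupSpec(
            label=label, n_subjects=n, distributions=dists,
            idh_status=idh, codeletion_status=codel,
            morphology_rates=reference.MORPHOLOGY_RATES[label]))
    return specs


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full recipe for one synthetic cohort."""

    groups: tuple[GroupSpec, ...] = field(
        default_factory=lambda: tuple(default_group_specs()))
    scheme: BValueScheme = field(default_factory=default_scheme)
    snr: float = 50.0
    seed: int = 0
    generating_model: str = "ctrw"

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.generating_model not in _GENERATORS:
            raise ValueError(f"unknown model {self.generating_model!r}")


def sample_subject_params(spec: GroupSpec, rng: np.random.Generator
                          ) -> pd.DataFrame:
    """One row of true parameters per subject, clipped to physical bounds.

    Errors if clipping alters more than half of the draws for any
    parameter — that indicates a spec inconsistent with the bounds.
    """
    cols = {}
    for name in PARAMETER_NAMES:
        if name not in spec.distributions:
            raise KeyError(f"spec {spec.label} missing {name}")
        family, loc, scale = spec.distributions[name]
        if family == "normal":
            draws = rng.normal(loc, scale, size=spec.n_subjects)
        else:
            sigma = scale / loc if loc > 0 else 0.0
            draws = loc * np.exp(rng.normal(0.0, sigma, size=spec.n_subjects))
        lo, hi = PARAM_CLIP_BOUNDS[name]
        clipped = np.clip(draws, lo, hi)
        n_clip = int(np.sum(clipped != draws))
        if n_clip > 0.5 * spec.n_subjects:
            raise ValueError(
                f"{spec.label}/{name}: clipping rejects {n_clip}/"
                f"{spec.n_subjects} draws; spec inconsistent with bounds")
        cols[name] = clipped
    return pd.DataFrame(cols)


def _rician(noiseless: np.ndarray, snr: float,
            rng: np.random.Generator) -> np.ndarray:
    sigma = 1.0 / snr
    g1 = rng.standard_normal(noiseless.shape)
    g2 = rng.standard_normal(noiseless.shape)
    return np.sqrt((noiseless + sigma * g1) ** 2 + (sigma * g2) ** 2)


def synthesize_voi_signals(true_params: dict, scheme: BValueScheme,
                           snr: float, n_voxels: int,
                           rng: np.random.Generator,
                           intra_voi_cv: float = 0.0,
                           model: str = "ctrw"):
    """Per-voxel noisy signals for one VOI.

    Returns ``(per_direction, averaged)``: the raw (n_voxels, n_b, n_dir)
    Rician-noised array on the normalized scale (S(0) truth = 1) and its
    orientation average.  ``snr -> inf`` recovers the forward model exactly.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    if snr <= 0:
        raise ValueError("snr must be positive")
    names, forward = _GENERATORS[model]
    b = scheme.b
    noiseless = np.empty((n_voxels, scheme.n_b))
    for i in range(n_voxels):
        voxel = {}
        for name in names:
            lo, hi = PARAM_CLIP_BOUNDS[name]
            jitter = 1.0 + intra_voi_cv * rng.standard_normal() \
                if intra_voi_cv > 0 else 1.0
            voxel[name] = float(np.clip(true_params[name] * jitter, lo, hi))
        noiseless[i] = forward(b, voxel)
    per_direction = _rician(
        np.repeat(noiseless[:, :, None], scheme.n_directions, axis=2),
        snr, rng)
    averaged = average_directions(per_direction, scheme)
    return per_direction, averaged


@dataclass
class SyntheticSubject:
    """One simulated subject: labels, truth, packed volume and mask."""

    subject_id: str
    group: str
    idh_status: str
    codeletion_status: str
    morphology: dict
    location: str
    true_params: dict[str, float]
    volume_4d: np.ndarray
    mask: np.ndarray


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth and analytic expectations."""

    config: SyntheticCohortConfig
    subjects: list[SyntheticSubject]
    truth: pd.DataFrame
    expected_auc: pd.DataFrame


def _pack_voi(averaged: DirectionAverage, n_voxels: int, s0_scale: float
              ) -> tuple[np.ndarray, np.ndarray]:
    """Pack per-voxel curves into a small 3D box with a leading-voxel mask."""
    nx, ny = 4, 4
    nz = int(np.ceil(n_voxels / (nx * ny)))
    n_b = averaged.data.shape[-1]
    vol = np.zeros((nx, ny, nz, n_b))
    mask = np.zeros((nx, ny, nz), dtype=bool)
    flat_vol = vol.reshape(-1, n_b)
    flat_mask = mask.reshape(-1)
    flat_vol[:n_voxels] = s0_scale * np.nan_to_num(averaged.data, nan=0.0)
    flat_mask[:n_voxels] = averaged.valid.all(axis=-1)
    return vol, mask


def _draw_morphology(rates: dict, rng: np.random.Generator
                     ) -> tuple[dict, str]:
    flags = {}
    for name in ("cystic_necrosis", "hemorrhage", "edema", "enhancement"):
        p = rates.get(name, 0.0)
        flags[name] = bool(rng.random() < p)
    loc_counts = rates.get("location", {"other": 1})
    labels = list(loc_counts)
    weights = np.array([loc_counts[k] for k in labels], dtype=float)
    location = str(rng.choice(labels, p=weights / weights.sum()))
    return flags, location


def generate_cohort(cfg: SyntheticCohortConfig,
                    out_dir: str | Path | None = None,
                    s0_scale: float = 1000.0) -> SyntheticCohort:
    """Generate the full cohort; optionally write it to disk.

    When ``out_dir`` is given, writes per-subject 4D NIfTI volumes and 3D
    masks, an FSL-style bval file, a labels CSV and a ground-truth CSV.
    The analytic expected AUC per parameter (see :func:`analytic_auc`) is
    always computed.
    """
    rng = np.random.default_rng(cfg.seed)
    subjects: list[SyntheticSubject] = []
    truth_rows = []
    for spec in cfg.groups:
        params = sample_subject_params(spec, rng)
        for i in range(spec.n_subjects):
            sid = f"sub-{len(subjects):03d}"
            true_p = {k: float(v) for k, v in params.iloc[i].items()}
            flags, location = _draw_morphology(spec.morphology_rates, rng)
            if flags["enhancement"] and spec.enhancement_alpha_shift:
                for key in ("CTRW_alpha", "SEM_alpha"):
                    lo, hi = PARAM_CLIP_BOUNDS[key]
                    true_p[key] = float(np.clip(
                        true_p[key] + spec.enhancement_alpha_shift, lo, hi))
            n_vox = int(rng.integers(spec.voxels_per_voi[0],
                                     spec.voxels_per_voi[1] + 1))
            _, averaged = synthesize_voi_signals(
                true_p, cfg.scheme, cfg.snr, n_vox, rng,
                intra_voi_cv=spec.intra_voi_cv, model=cfg.generating_model)
            vol, mask = _pack_voi(averaged, n_vox, s0_scale)
            subjects.append(SyntheticSubject(
                subject_id=sid, group=spec.label,
                idh_status=spec.idh_status,
                codeletion_status=spec.codeletion_status,
                morphology=flags, location=location, true_params=true_p,
                volume_4d=vol, mask=mask))
            truth_rows.append({"subject_id": sid, "group": spec.label,
                               **true_p})
    truth = pd.DataFrame(truth_rows)
    cohort = SyntheticCohort(config=cfg, subjects=subjects, truth=truth,
                             expected_auc=expected_auc_table(cfg.groups))
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> None:
    import nibabel as nib

    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag([2.2, 2.2, 2.2, 1.0])
    label_rows = []
    for sub in cohort.subjects:
        sub_dir = out_dir / sub.subject_id
        sub_dir.mkdir(exist_ok=True)
        nib.save(nib.Nifti1Image(sub.volume_4d.astype(np.float32), affine),
                 sub_dir / "dwi.nii.gz")
        nib.save(nib.Nifti1Image(sub.mask.astype(np.uint8), affine),
                 sub_dir / "voi_mask.nii.gz")
        label_rows.append({
            "subject_id": sub.subject_id, "group": sub.group,
            "idh_status": sub.idh_status,
            "codeletion_status": sub.codeletion_status,
            "location": sub.location, **sub.morphology})
    write_bval(out_dir / "dwi.bval", cohort.config.scheme.b)
    pd.DataFrame(label_rows).to_csv(out_dir / "labels.csv", index=False)
    cohort.truth.to_csv(out_dir / "truth.csv", index=False,
                        float_format="%.12g")
    logger.info("wrote %d subjects to %s", len(cohort.subjects), out_dir)


def reference_cohort_config(seed: int = 0, snr: float = 50.0,
                        voxels_per_voi: tuple[int, int] | None = None,
                        **kwargs) -> SyntheticCohortConfig:
    """The reference-cohort preset: groups 52/12/31, SNR 50 at b=0."""
    groups = default_group_specs()
    if voxels_per_voi is not None:
        groups = [replace(g, voxels_per_voi=voxels_per_voi) for g in groups]
    return SyntheticCohortConfig(groups=tuple(groups), seed=seed, snr=snr,
                                 **kwargs)


def _moments(dist: tuple[str, float, float]) -> tuple[float, float]:
    family, loc, scale = dist
    if family == "normal":
        return loc, scale
    sigma = scale / loc if loc > 0 else 0.0
    mean = loc * np.exp(sigma ** 2 / 2)
    var = loc ** 2 * np.exp(sigma ** 2) * (np.exp(sigma ** 2) - 1)
    return mean, float(np.sqrt(var))


def _mixture_moments(parts: list[tuple[float, float, float]]
                     ) -> tuple[float, float]:
    """Moments of a mixture given (weight, mean, sd) components."""
    w = np.array([p[0] for p in parts], dtype=float)
    w = w / w.sum()
    mu = np.array([p[1] for p in parts])
    sd = np.array([p[2] for p in parts])
    mean = float(np.sum(w * mu))
    var = float(np.sum(w * (sd ** 2 + mu ** 2)) - mean ** 2)
    return mean, float(np.sqrt(var))


def analytic_auc(mu_pos: float, sd_pos: float, mu_neg: float,
                 sd_neg: float) -> float:
    """Expected AUC of two normal populations: Phi(|dmu| / sqrt(v1+v2))."""
    denom = np.sqrt(sd_pos ** 2 + sd_neg ** 2)
    if denom == 0:
        return 0.5
    return float(norm.cdf(abs(mu_pos - mu_neg) / denom))


def expected_auc_table(groups: tuple[GroupSpec, ...]) -> pd.DataFrame:
    """Analytic AUC implied by the generating specs, per parameter/question.

    The IDH-mutant side pools the two mutant groups as a mixture weighted
    by group size.
    """
    by_status: dict[str, list[GroupSpec]] = {}
    for g in groups:
        by_status.setdefault(g.idh_status, []).append(g)
    rows = []
    for param in PARAMETER_NAMES:
        wild = [(g.n_subjects, *_moments(g.distributions[param]))
                for g in by_status.get("wild-type", [])]
        mut = [(g.n_subjects, *_moments(g.distributions[param]))
               for g in by_status.get("mutant", [])]
        if wild and mut:
            mw, sw = _mixture_moments(wild)
            mm, sm = _mixture_moments(mut)
            rows.append({"question": "IDH", "parameter": param,
                         "expected_auc": analytic_auc(mm, sm, mw, sw)})
        codel = [g for g in by_status.get("mutant", [])
                 if g.codeletion_status == "codeleted"]
        noncodel = [g for g in by_status.get("mutant", [])
                    if g.codeletion_status == "non-codeleted"]
        if codel and noncodel:
            mc, sc = _mixture_moments(
                [(g.n_subjects, *_moments(g.distributions[param]))
                 for g in codel])
            mn, sn = _mixture_moments(
                [(g.n_subjects, *_moments(g.distributions[param]))
                 for g in noncodel])
            rows.append({"question": "1p/19q", "parameter": param,
                         "expected_auc": analytic_auc(mn, sn, mc, sc)})
    return pd.DataFrame(rows)
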