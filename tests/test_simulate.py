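"""Synthetic cohort generator: distributions, noise model, determinism."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import i0e, i1e

from qdwi.fitting import PARAMETER_NAMES
from qdwi.pipeline import fit_cohort
from qdwi.scheme import default_scheme
from qdwi.simulate import (GroupSpec, SyntheticCohortConfig,
                           default_group_specs, expected_auc_table,
                           generate_cohort, iqr_to_sd,
                           reference_cohort_config, sample_subject_params,
                           synthesize_voi_signals)
from qdwi import reference


def _spec(n=10, **kwargs):
    dists = {p: ("normal", loc, 0.0) for p, loc in zip(
        PARAMETER_NAMES, (1.1, 1.0, 8.0, 0.09, 1.2, 0.87, 1.2, 0.85, 0.94))}
    defaults = dict(label="test", n_subjects=n, distributions=dists)
    defaults.update(kwargs)
    return GroupSpec(**defaults)


class TestSampling:
    def test_zero_scale_hits_location(self, rng):
        params = sample_subject_params(_spec(), rng)
        assert (params["CTRW_alpha"] == 0.85).all()
        assert (params["IVIM_f"] == 0.09).all()

    def test_default_specs_match_printed_medians(self):
        """Large-n medians reproduce the printed group medians.

        The IDH-mutant side is the 31:12 codeleted/non-codeleted mixture;
        its pooled median must sit near the printed mutant-group value
        (0.867 for the CTRW temporal index, vs 0.825 in wild-type).
        """
        rng = np.random.default_rng(7)
        scale = 40
        specs = {s.label: s for s in default_group_specs()}
        wild = sample_subject_params(
            replace(specs["idh-wild"], n_subjects=52 * scale), rng)
        mut = np.concatenate([
            sample_subject_params(
                replace(specs["mutant-codel"], n_subjects=31 * scale),
                rng)["CTRW_alpha"],
            sample_subject_params(
                replace(specs["mutant-noncodel"], n_subjects=12 * scale),
                rng)["CTRW_alpha"]])
        assert np.median(wild["CTRW_alpha"]) == pytest.approx(0.825, abs=0.01)
        assert np.median(mut) == pytest.approx(0.867, abs=0.01)

    def test_draws_respect_bounds(self):
        rng = np.random.default_rng(3)
        spec = _spec(n=500, distributions={
            p: ("normal", loc, 0.2) for p, loc in zip(
                PARAMETER_NAMES,
                (1.1, 1.0, 8.0, 0.2, 1.2, 0.9, 1.2, 0.9, 0.95))})
        params = sample_subject_params(spec, rng)
        assert (params["CTRW_alpha"] <= 1.0).all()
        assert (params["CTRW_beta"] <= 1.0).all()
        assert (params["SEM_alpha"] <= 1.0).all()
        assert (params["IVIM_f"] <= 0.5).all()
        assert (params >= 0).all().all()

    def test_excessive_clipping_rejected(self, rng):
        bad = _spec(distributions={p: ("normal", 9.0, 0.01)
                                   for p in PARAMETER_NAMES})
        with pytest.raises(ValueError, match="clipping"):
            sample_subject_params(bad, rng)

    def test_lognormal_family(self, rng):
        dists = dict(_spec().distributions)
        dists["Mono_ADC"] = ("lognormal", 1.2, 0.24)
        params = sample_subject_params(_spec(n=4000, distributions=dists),
                                       rng)
        # median preserved under the lognormal parameterization
        assert np.median(params["Mono_ADC"]) == pytest.approx(1.2, abs=0.02)

    def test_one_subject_group_rejected(self):
        with pytest.raises(ValueError):
            _spec(n=1)


class TestSignals:
    truth = dict(CTRW_Dm=1.218, CTRW_alpha=0.825, CTRW_beta=0.938)

    def test_noise_free_limit(self, scheme, rng):
        from qdwi.models import CTRWParams, ctrw_signal
        _, avg = synthesize_voi_signals(self.truth, scheme, snr=1e9,
                                        n_voxels=3, rng=rng)
        expected = ctrw_signal(scheme.b, CTRWParams(1.218, 0.825, 0.938))
        assert np.max(np.abs(avg.data - expected[None, :])) < 1e-6

    def test_rician_b0_mean_matches_moment_oracle(self, scheme):
        """Mean observed S(0) equals the closed-form Rician mean.

        E|S| = sigma sqrt(pi/2) L_{1/2}(-nu^2 / 2 sigma^2), evaluated here
        with exponentially scaled Bessel functions for stability.
        """
        rng = np.random.default_rng(11)
        snr = 50.0
        per_dir, _ = synthesize_voi_signals(self.truth, scheme, snr=snr,
                                            n_voxels=4000, rng=rng)
        nu, sigma = 1.0, 1.0 / snr
        t = nu ** 2 / (4 * sigma ** 2)
        mean_rice = (sigma * np.sqrt(np.pi / 2)
                     * ((1 + 2 * t) * i0e(t) + 2 * t * i1e(t)))
        observed = per_dir[:, 0, :].mean()
        assert observed == pytest.approx(mean_rice, rel=5e-4)

    def test_seed_determinism(self, scheme):
        a = synthesize_voi_signals(self.truth, scheme, 50.0, 5,
                                   np.random.default_rng(42))[0]
        b = synthesize_voi_signals(self.truth, scheme, 50.0, 5,
                                   np.random.default_rng(42))[0]
        np.testing.assert_array_equal(a, b)

    def test_preconditions(self, scheme, rng):
        with pytest.raises(ValueError):
            synthesize_voi_signals(self.truth, scheme, 50.0, 0, rng)
        with pytest.raises(ValueError):
            synthesize_voi_signals(self.truth, scheme, -1.0, 3, rng)


def _tiny_config(seed=0, **kwargs):
    groups = []
    for label, idh, codel, alpha in (
            ("w", "wild-type", "not-applicable", 0.82),
            ("mn", "mutant", "non-codeleted", 0.90),
            ("mc", "mutant", "codeleted", 0.86)):
        dists = {p: ("normal", loc, 0.02) for p, loc in zip(
            PARAMETER_NAMES, (1.1, 1.0, 8.0, 0.09, 1.2, 0.87, 1.25, alpha,
                              0.94))}
        groups.append(GroupSpec(label=label, n_subjects=3,
                                distributions=dists, idh_status=idh,
                                codeletion_status=codel,
                                voxels_per_voi=(4, 6), intra_voi_cv=0.0))
    return SyntheticCohortConfig(groups=tuple(groups), seed=seed, **kwargs)


class TestGenerateCohort:
    def test_on_disk_fixture(self, tmp_path):
        cohort = generate_cohort(_tiny_config(), out_dir=tmp_path)
        assert len(cohort.subjects) == 9
        assert sorted(p.name for p in tmp_path.glob("sub-*")) == \
            sorted(s.subject_id for s in cohort.subjects)
        assert (tmp_path / "dwi.bval").exists()
        assert (tmp_path / "labels.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        bvals = np.loadtxt(tmp_path / "dwi.bval")
        np.testing.assert_allclose(bvals, default_scheme().b)

    def test_reference_preset_composition(self):
        cfg = reference_cohort_config(seed=5)
        assert sum(g.n_subjects for g in cfg.groups) == 95
        assert {g.n_subjects for g in cfg.groups} == {52, 12, 31}
        assert cfg.snr == 50.0 and cfg.scheme.n_b == 13

    def test_byte_identical_given_seed(self):
        a = generate_cohort(_tiny_config(seed=9))
        b = generate_cohort(_tiny_config(seed=9))
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.volume_4d, sb.volume_4d)
        assert a.truth.equals(b.truth)

    def test_expected_auc_closed_form(self):
        from scipy.stats import norm
        cfg = _tiny_config()
        table = expected_auc_table(cfg.groups)
        row = table[(table.question == "1p/19q")
                    & (table.parameter == "CTRW_alpha")].iloc[0]
        assert row.expected_auc == pytest.approx(
            norm.cdf(abs(0.90 - 0.86) / np.sqrt(0.02 ** 2 + 0.02 ** 2)))

    def test_enhancement_shift_lowers_alpha(self):
        groups = tuple(
            replace(g, enhancement_alpha_shift=-0.05,
                    morphology_rates={"enhancement": 1.0,
                                      "location": {"other": 1}})
            for g in _tiny_config().groups)
        cohort = generate_cohort(SyntheticCohortConfig(groups=groups, seed=2))
        plain = generate_cohort(_tiny_config(seed=2))
        for shifted, base in zip(cohort.subjects, plain.subjects):
            assert shifted.true_params["CTRW_alpha"] == pytest.approx(
                base.true_params["CTRW_alpha"] - 0.05, abs=1e-12)


class TestPipelineRecovery:
    @pytest.mark.parametrize("model,tol", [("mono", 0.01), ("sem", 0.01),
                                           ("ivim", 0.03), ("ctrw", 0.03)])
    def test_self_generated_voi_recovery(self, model, tol):
        """CV=0, SNR>=200: VOI-mean fits recover subject ground truth."""
        cfg = _tiny_config(seed=4, snr=500.0, generating_model=model)
        cohort = generate_cohort(cfg)
        table = fit_cohort(cohort, models=(model,))
        from qdwi.fitting import MODEL_PARAMETERS
        for name in MODEL_PARAMETERS[model]:
            fitted = table.df[name].to_numpy(dtype=float)
            truth = cohort.truth[name].to_numpy(dtype=float)
            if name == "IVIM_f":
                np.testing.assert_allclose(fitted, truth, atol=tol)
            else:
                np.testing.assert_allclose(fitted, truth, rtol=tol)

    def test_truth_level_group_directions(self):
        """Sampled group medians replicate the reported contrast signs
        (mutant higher for the five IDH-significant parameters; codeleted
        lower for the three 1p/19q-significant ones) across replicates."""
        specs = {s.label: s for s in default_group_specs()}
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            rng = np.random.default_rng(100 + seed)
            wild = sample_subject_params(specs["idh-wild"], rng)
            codel = sample_subject_params(specs["mutant-codel"], rng)
            noncodel = sample_subject_params(specs["mutant-noncodel"], rng)
            ok = all(
                np.median(np.r_[codel[p], noncodel[p]]) > np.median(wild[p])
                for p in reference.IDH_HIGHER_IN_MUTANT)
            ok &= all(np.median(codel[p]) < np.median(noncodel[p])
                      for p in reference.CODELETION_LOWER_IN_CODELETED)
            hits += ok
        assert hits >= 0.95 * n_rep
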