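import numpy as np
import pytest

from statedyn.design import OFF_TO_ON, build_block_design
from statedyn.simulate import (
    STATE_OFF,
    STATE_ON,
    STATE_TRANSITION,
    SyntheticConfig,
    default_control_specs,
    default_state_specs,
    generate_cohort,
    generate_subject,
    plant_state_sequence,
    simulate_state_run,
)
from conftest import reduced_config

AI, PRL, CG, ARSC = 0, 1, 2, 3   # canonical ROI ordering


class TestDefaultSpecs:
    def test_state_signatures(self):
        off, on, tr = default_state_specs(9)
        assert np.all(off.mean == 0)
        assert on.mean[AI] > 0 and on.mean[PRL] > 0
        assert on.mean[ARSC] < 0                       # anterior RSC suppressed
        assert on.cov[AI, ARSC] < off.cov[AI, ARSC]    # AI-aRSC decoupling
        assert on.cov[PRL, CG] > off.cov[PRL, CG]      # PrL-Cg strengthening
        assert np.all(tr.mean[3:6] < -0.5)             # anterior-mid RSC suppressed
        assert np.all(tr.mean[7:9] > 0)                # posterior RSC activated

    @pytest.mark.parametrize("n_rois", [3, 5, 9, 12])
    def test_covariances_positive_definite(self, n_rois):
        for spec in default_state_specs(n_rois) + default_control_specs(n_rois):
            assert np.linalg.eigvalsh(spec.cov).min() > 0
            assert abs(spec.dynamics) < 1

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError, match="n_rois"):
            default_state_specs(2)


class TestPlantSequence:
    def test_zero_dwell_reproduces_condition_labels(self, study_design):
        seq = plant_state_sequence(study_design, "experimental",
                                   transition_dwell=0, rng=0, jitter=False)
        expected = np.where(study_design.condition_labels == "ON",
                            STATE_ON, STATE_OFF)
        np.testing.assert_array_equal(seq, expected)

    def test_every_boundary_passes_through_transition(self, study_design):
        seq = plant_state_sequence(study_design, "experimental",
                                   transition_dwell=5, rng=1)
        for b, dirn in study_design.boundaries:
            assert seq[b] == STATE_TRANSITION
            # no direct OFF->ON step anywhere in the run
        for a, b2 in zip(seq[:-1], seq[1:]):
            assert not (a == STATE_OFF and b2 == STATE_ON)
            assert not (a == STATE_ON and b2 == STATE_OFF)

    def test_control_sequence_deterministic_under_seed(self, study_design):
        s1 = plant_state_sequence(study_design, "control", rng=7)
        s2 = plant_state_sequence(study_design, "control", rng=7)
        np.testing.assert_array_equal(s1, s2)
        assert set(np.unique(s1)) <= {"OFF", "nuisance1", "nuisance2"}

    def test_dwell_longer_than_block_rejected(self, study_design):
        with pytest.raises(ValueError, match="transition_dwell"):
            plant_state_sequence(study_design, "experimental",
                                 transition_dwell=20, rng=0)


class TestGenerateSubject:
    def test_same_seed_identical(self):
        cfg = reduced_config()
        a, _ = generate_subject(cfg, "experimental", 42)
        b, _ = generate_subject(cfg, "experimental", 42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_output_is_z_scored(self):
        cfg = reduced_config()
        ts, _ = generate_subject(cfg, "experimental", 3)
        assert np.all(np.abs(ts.data.mean(axis=0)) < 1e-10)
        assert np.all(np.abs(ts.data.std(axis=0) - 1) < 1e-10)

    def test_sequence_matches_design_length(self):
        cfg = reduced_config()
        ts, gt = generate_subject(cfg, "experimental", 3)
        assert gt.sequence.size == ts.n_timepoints == cfg.design().n_timepoints

    def test_sample_covariance_converges_to_state_covariance(self):
        # law of large numbers against the independent sample-covariance oracle
        spec = default_state_specs(9)[1]
        errs = []
        for T in (2000, 40000):
            x = simulate_state_run(spec, T, np.random.default_rng(0))
            emp = np.cov((x - spec.mean).T)
            errs.append(np.linalg.norm(emp - spec.cov) / np.linalg.norm(spec.cov))
        assert errs[1] < errs[0]
        assert errs[1] < 0.05

    def test_state_mean_difference_matches_planted(self):
        # direct averaging on ground-truth labels, idealised observation chain
        cfg = SyntheticConfig(n_experimental=10, n_control=0,
                              observation_noise_sd=0.0, smoothing_fwhm=0.0,
                              hemodynamic_lag=0.0, seed=7)
        on = {s.name: s for s in cfg.states}[STATE_ON]
        off = {s.name: s for s in cfg.states}[STATE_OFF]
        diffs = []
        for ts, gt in generate_cohort(cfg):
            emp = ts.data[gt.sequence == STATE_ON].mean(0) \
                - ts.data[gt.sequence == STATE_OFF].mean(0)
            planted = gt.mean_in_output_units(on) - gt.mean_in_output_units(off)
            diffs.append(emp - planted)
        assert np.abs(np.mean(diffs, axis=0)).max() < 0.12

    def test_per_state_covariance_recoverable(self):
        # pooled sample-covariance oracle on ground-truth samples, idealised
        # chain (no smoothing/noise/lag) at the default run length
        cfg = SyntheticConfig(n_experimental=40, n_control=0,
                              observation_noise_sd=0.0, smoothing_fwhm=0.0,
                              hemodynamic_lag=0.0, seed=7)
        spec_by = {s.name: s for s in cfg.states}
        for name in (STATE_OFF, STATE_ON, STATE_TRANSITION):
            chunks = []
            for ts, gt in generate_cohort(cfg):
                sel = gt.sequence == name
                # undo the per-subject affine normalization
                chunks.append((ts.data[sel]
                               - gt.mean_in_output_units(spec_by[name])) * gt.scale)
            pooled = np.vstack(chunks)
            emp = pooled.T @ pooled / pooled.shape[0]
            tgt = spec_by[name].cov
            assert np.linalg.norm(emp - tgt) / np.linalg.norm(tgt) < 0.10

    def test_correlation_structure_survives_full_observation_chain(self):
        cfg = SyntheticConfig(seed=7)
        spec_by = {s.name: s for s in cfg.states}
        cohort = [c for c in generate_cohort(cfg) if c[0].group == "experimental"]
        iu = np.triu_indices(9, 1)
        for name in (STATE_OFF, STATE_ON, STATE_TRANSITION):
            pooled = np.vstack([ts.data[gt.sequence == name]
                                - ts.data[gt.sequence == name].mean(0)
                                for ts, gt in cohort])
            emp = np.corrcoef(pooled, rowvar=False)
            c = spec_by[name].cov
            tgt = c / np.sqrt(np.outer(np.diag(c), np.diag(c)))
            assert np.median(np.abs(emp[iu] - tgt[iu])) < 0.10


class TestGenerateCohort:
    def test_default_cohort_composition(self):
        cohort = generate_cohort(SyntheticConfig(seed=0))
        assert len(cohort) == 16
        groups = [ts.group for ts, _ in cohort]
        assert groups.count("experimental") == 9
        assert groups.count("control") == 7

    def test_single_subject_cohort(self):
        cohort = generate_cohort(reduced_config(n_experimental=1, n_control=0))
        assert len(cohort) == 1

    def test_master_seed_reproducibility(self):
        c1 = generate_cohort(reduced_config(seed=5))
        c2 = generate_cohort(reduced_config(seed=5))
        for (a, ga), (b, gb) in zip(c1, c2):
            np.testing.assert_array_equal(a.data, b.data)
            np.testing.assert_array_equal(ga.sequence, gb.sequence)

    def test_occupancy_depends_on_design_only_in_experimental(self):
        # planted ON occupancy: higher inside ON blocks for every experimental
        # subject; in controls no dependence beyond sampling error (20 seeds)
        design = build_block_design(60, 4, 20, 40, 1)
        on_mask = design.condition_labels == "ON"
        for seed in range(5):
            cfg = reduced_config(seed=seed)
            for ts, gt in generate_cohort(cfg):
                if ts.group != "experimental":
                    continue
                occ_on = np.mean(gt.sequence[on_mask] == STATE_ON)
                occ_off = np.mean(gt.sequence[~on_mask] == STATE_ON)
                assert occ_on > occ_off
        diffs = []
        for seed in range(20):
            seq = plant_state_sequence(design, "control", rng=seed)
            for name in np.unique(seq):
                diffs.append(np.mean(seq[on_mask] == name)
                             - np.mean(seq[~on_mask] == name))
        assert abs(np.mean(diffs)) < 0.05

    def test_bad_covariance_rejected(self):
        from statedyn.simulate import StateSpec

        with pytest.raises(ValueError, match="positive definite"):
            StateSpec("bad", np.zeros(2), np.array([[1.0, 2.0], [2.0, 1.0]]))


def test_write_cohort_round_trip(tmp_path):
    from statedyn.pipeline import load_cohort_dir
    from statedyn.simulate import write_cohort

    cfg = reduced_config(n_experimental=2, n_control=1)
    cohort = generate_cohort(cfg)
    write_cohort(cohort, tmp_path)
    back = load_cohort_dir(tmp_path)
    assert len(back) == 3
    by_id = {ts.subject_id: ts for ts, _ in back}
    for ts, _ in cohort:
        np.testing.assert_allclose(by_id[ts.subject_id].data, ts.data, atol=1e-9)
        assert by_id[ts.subject_id].group == ts.group
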