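import numpy as np
import pytest

import lifelog_rsa as lr
from lifelog_rsa.group_inference import (
    PermutationNull,
    StatMap,
    _stat_volume,
    conjunction_map,
    group_tmap,
    roi_tests,
    tfce,
    threshold_one_tailed,
    threshold_two_tailed,
)
from lifelog_rsa.searchlight_rsa import ModelSpec


class TestGroupTmap:
    def test_closed_form_three_subjects(self):
        maps = [np.full((2, 2, 2), v) for v in (1.0, 2.0, 3.0)]
        t = group_tmap(maps)
        assert t[0, 0, 0] == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))

    def test_symmetric_values_give_zero(self):
        maps = [np.full((2, 2, 2), v) for v in (-1.0, 0.0, 1.0)]
        assert group_tmap(maps)[0, 0, 0] == 0.0

    def test_zero_variance_gets_signed_infinity_sentinel(self):
        maps = [np.full((2, 2, 2), 0.7) for _ in range(4)]
        t = group_tmap(maps)
        assert np.isposinf(t).all()
        t_neg = group_tmap([-m for m in maps])
        assert np.isneginf(t_neg).all()
        t_zero = group_tmap([np.zeros((2, 2, 2)) for _ in range(4)])
        assert (t_zero == 0).all()

    def test_undefined_where_any_subject_undefined(self):
        a = np.ones((2, 2, 2))
        b = np.ones((2, 2, 2)) * 2
        b[0, 0, 0] = np.nan
        t = group_tmap([a, b, a * 3])
        assert np.isnan(t[0, 0, 0]) and np.isfinite(t[1, 1, 1])

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            group_tmap([np.ones((2, 2, 2))])


class TestTfce:
    def test_zero_map_stays_zero(self):
        assert np.all(tfce(np.zeros((4, 4, 4))) == 0.0)

    def test_single_voxel_analytic_limit(self):
        # isolated voxel, E=0.5, H=2: integral of h^2 dh -> t^3/3 as dh -> 0
        t = np.zeros((5, 5, 5))
        t[2, 2, 2] = 3.0
        enh = tfce(t, dh=3.0 / 10_000)
        assert enh[2, 2, 2] == pytest.approx(27.0 / 3.0, rel=1e-3)
        # negative tail is enhanced symmetrically
        enh_neg = tfce(-t, dh=3.0 / 10_000)
        assert enh_neg[2, 2, 2] == pytest.approx(-27.0 / 3.0, rel=1e-3)

    def test_larger_blob_gets_larger_peak(self):
        t = np.zeros((4, 12, 12))
        t[1, 1:3, 1:3] = 2.0  # 4-voxel blob
        t[1, 6:10, 6:10] = 2.0  # 16-voxel blob
        enh = tfce(t)
        assert enh[1, 7, 7] > enh[1, 1, 1]

    def test_monotone_in_voxel_height(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=(6, 6, 6))
        base = tfce(t, dh=0.05)
        t2 = t.copy()
        t2[3, 3, 3] += 1.5
        raised = tfce(t2, dh=0.05)
        pos = t >= 0
        assert np.all(raised[pos] >= base[pos] - 1e-9)

    def test_nonfinite_voxels_do_not_join_clusters(self):
        t = np.zeros((3, 3, 3))
        t[0, 0, 0] = np.inf
        t[1, 1, 1] = 2.0
        enh = tfce(t, dh=0.1)
        assert np.isnan(enh[0, 0, 0]) and np.isfinite(enh[1, 1, 1])

    def test_bad_parameters_rejected(self):
        with pytest.raises(ValueError):
            tfce(np.zeros((2, 2, 2)), E=0.0)
        with pytest.raises(ValueError, match="connectivity"):
            tfce(np.zeros((2, 2, 2)), connectivity=18)


class TestPermutationMachinery:
    def test_identity_permutation_reproduces_observed_map(self, small_study, small_pairs):
        sls = lr.study_searchlights(small_study, lr.CONTENT_MODEL, pairs=small_pairs)
        t_obs, e_obs = _stat_volume(sls, None, "Hamm", None, {})
        ident = [np.arange(s.n_trials) for s in sls]
        t_id, e_id = _stat_volume(sls, ident, "Hamm", None, {})
        assert np.allclose(t_obs, t_id, equal_nan=True)
        assert np.allclose(e_obs, e_id, equal_nan=True)

    def test_null_draws_are_reproducible_for_a_seed(self, small_study, small_pairs):
        sls = lr.study_searchlights(small_study, lr.CONTENT_MODEL, pairs=small_pairs)
        n1 = lr.permutation_null(sls, "Hamm", n_perm=5, seed=42)
        n2 = lr.permutation_null(sls, "Hamm", n_perm=5, seed=42)
        assert np.array_equal(n1.null_max, n2.null_max)
        assert np.array_equal(n1.null_min, n2.null_min)

    def test_permuted_signal_is_broken(self, small_study, small_pairs):
        """A random trial relabeling destroys the in-region Hamm effect."""
        sls = lr.study_searchlights(small_study, lr.CONTENT_MODEL, pairs=small_pairs)
        region = small_study.ground_truth.signal_mask(small_study.cfg.grid_shape)
        t_obs, _ = _stat_volume(sls, None, "Hamm", None, {})
        rng = np.random.default_rng(7)
        perms = [rng.permutation(s.n_trials) for s in sls]
        t_perm, _ = _stat_volume(sls, perms, "Hamm", None, {})
        assert np.nanmean(t_obs[region]) > 3 * abs(np.nanmean(t_perm[region]))


class TestThresholding:
    def _stat(self, tfce_map, null_max, null_min):
        null = PermutationNull(
            null_max=np.asarray(null_max, float),
            null_min=np.asarray(null_min, float),
            n_perm=len(null_max), seed=0, statistic="term",
        )
        return StatMap(t=tfce_map.copy(), tfce=tfce_map, null=null)

    def test_dominant_null_gives_empty_mask(self):
        enh = np.full((3, 3, 3), 5.0)
        stat = self._stat(enh, np.full(100, 50.0), np.full(100, -50.0))
        sig = threshold_two_tailed(stat)
        assert not sig.any()

    def test_mask_shrinks_as_alpha_drops(self):
        rng = np.random.default_rng(0)
        enh = rng.normal(scale=3.0, size=(5, 5, 5))
        null_max = rng.normal(2.0, 1.0, 200)
        null_min = -rng.normal(2.0, 1.0, 200)
        stat = self._stat(enh, null_max, null_min)
        masks = [threshold_two_tailed(stat, a).sum() for a in (0.2, 0.05, 0.01)]
        assert masks[0] >= masks[1] >= masks[2]

    def test_one_tailed_uses_95th_percentile(self):
        enh = np.zeros((2, 2, 2))
        enh[0, 0, 0] = 10.0
        stat = self._stat(enh, np.arange(100.0), np.zeros(100))
        sig = threshold_one_tailed(stat, alpha=0.05)
        assert stat.thresholds["hi"] == pytest.approx(
            np.quantile(np.arange(100.0), 0.95)
        )
        assert not sig.any()  # 10 < 94.05


class TestConjunction:
    def test_negated_map_identity(self):
        rng = np.random.default_rng(1)
        t = rng.normal(size=(4, 4, 4))
        assert np.allclose(conjunction_map(t, -t), t)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            conjunction_map(np.zeros((3, 3, 3)), np.zeros((4, 4, 4)))

    def test_detects_attenuated_region_not_plain_region(self):
        """Conjunction needs both the content effect and its attenuation."""
        base = dict(
            n_participants=4, n_events=36, grid_shape=(8, 8, 8),
            signal_center=(4, 4, 4),
        )
        study_att = lr.simulate_study(lr.GeneratorConfig(seed=202, **base))
        study_flat = lr.simulate_study(
            lr.GeneratorConfig(seed=202, attenuation=1.0, **base)
        )
        region = study_att.ground_truth.signal_mask((8, 8, 8))
        t_att, _ = _stat_volume(
            lr.study_searchlights(study_att, lr.VIVIDNESS_MODEL),
            None, "Hamm", "Hamm:Vivid", {},
        )
        t_flat, _ = _stat_volume(
            lr.study_searchlights(study_flat, lr.VIVIDNESS_MODEL),
            None, "Hamm", "Hamm:Vivid", {},
        )
        assert np.nanmean(t_att[region]) > np.nanmean(t_flat[region]) + 0.5

    def test_smoke_calibration_on_null_data(self):
        """Sanity: the conjunction seldom fires when there is no signal."""
        rejections = 0
        for seed in range(10):
            cfg = lr.GeneratorConfig(
                seed=900 + seed, n_participants=4, n_events=16,
                grid_shape=(5, 5, 5), signal_center=None,
            )
            study = lr.simulate_study(cfg)
            sls = lr.study_searchlights(study, lr.VIVIDNESS_MODEL)
            stat = lr.infer_conjunction(sls, n_perm=40, seed=seed)
            rejections += bool(stat.sig_mask.any())
        assert rejections <= 3


class TestRoiTests:
    def test_bonferroni_denominator_and_signal_roi(self, small_study, small_pairs):
        shape = small_study.cfg.grid_shape
        region = small_study.ground_truth.signal_mask(shape)
        corner = np.zeros(shape, dtype=bool)
        corner[:2, :2, :2] = True  # pure-noise ROI away from the signal
        rois = {"signal": region, "corner": corner}
        data = [
            (small_study.betas[pid], small_pairs[pid]) for pid in small_study.events
        ]
        model = ModelSpec(("Hamm",))
        res = roi_tests(rois, data, [model], n_perm=200, seed=0)
        # 2 ROIs x 1 model x 1 non-intercept term
        assert np.allclose(res["corrected_alpha"], 0.05 / 2)
        sig_row = res[(res.roi == "signal") & (res.term == "Hamm")].iloc[0]
        noise_row = res[(res.roi == "corner") & (res.term == "Hamm")].iloc[0]
        assert sig_row.significant
        assert sig_row.t > noise_row.t
        assert not noise_row.significant

    def test_identical_rois_give_identical_statistics(self, small_study, small_pairs):
        region = small_study.ground_truth.signal_mask(small_study.cfg.grid_shape)
        data = [
            (small_study.betas[pid], small_pairs[pid]) for pid in small_study.events
        ]
        res = roi_tests(
            {"a": region, "b": region.copy()}, data,
            [ModelSpec(("Hamm",))], n_perm=50, seed=1,
        )
        ta = res[res.roi == "a"].iloc[0]
        tb = res[res.roi == "b"].iloc[0]
        assert ta.t == tb.t and ta.p_perm == tb.p_perm

    def test_empty_roi_rejected(self, small_study, small_pairs):
        empty = np.zeros(small_study.cfg.grid_shape, dtype=bool)
        data = [
            (small_study.betas[pid], small_pairs[pid]) for pid in small_study.events
        ]
        with pytest.raises(ValueError, match="empty ROI"):
            roi_tests({"empty": empty}, data, [ModelSpec(("Hamm",))], n_perm=5, seed=0)
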