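import numpy as np
import pandas as pd
import pytest

import lifelog_rsa as lr
from lifelog_rsa.searchlight_rsa import (
    ModelSpec,
    SubjectSearchlight,
    fit_pair_glm,
    sphere_neighborhoods,
    sphere_offsets,
)


def synthetic_pair_table(n_pairs=200, seed=0, n_trials=None):
    """A pair table with random covariates, all pairs included."""
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = int(np.ceil((1 + np.sqrt(1 + 8 * n_pairs)) / 2))
    iu = np.triu_indices(n_trials, 1)
    take = rng.choice(len(iu[0]), size=n_pairs, replace=False)
    return pd.DataFrame(
        {
            "i": iu[0][take],
            "j": iu[1][take],
            "hamm": rng.integers(0, 16, n_pairs).astype(float),
            "vis_sim": rng.uniform(0, 2, n_pairs),
            "log10_scanner": rng.uniform(0.5, 3.5, n_pairs),
            "vivid_code": rng.choice([0.0, 0.5, 1.0], n_pairs),
            "space_m": rng.uniform(100, 30_000, n_pairs),
            "time_s": rng.uniform(15.6 * 3600, 30 * 86_400, n_pairs),
            "included": True,
            "exclusion_reason": None,
        }
    )


class TestSphereGeometry:
    def test_radius_below_voxel_size_gives_singletons(self):
        mask = np.ones((3, 3, 3), dtype=bool)
        spheres = sphere_neighborhoods(mask, 1.0, 2.5)
        assert all(len(v) == 1 for v in spheres.values())

    def test_interior_sphere_count_matches_lattice_enumeration(self):
        # independent brute force over integer offsets
        count = sum(
            1
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if 2.5 * np.sqrt(i * i + j * j + k * k) <= 7.5
        )
        assert count == 123
        assert len(sphere_offsets(7.5, 2.5)) == count
        mask = np.ones((9, 9, 9), dtype=bool)
        spheres = sphere_neighborhoods(mask, 7.5, 2.5)
        assert len(spheres[(4, 4, 4)]) == 123

    def test_boundary_spheres_strictly_smaller(self):
        mask = np.ones((9, 9, 9), dtype=bool)
        spheres = sphere_neighborhoods(mask, 7.5, 2.5)
        assert len(spheres[(0, 0, 0)]) < 123
        assert len(spheres[(4, 4, 0)]) < 123

    def test_membership_is_symmetric_on_full_mask(self):
        mask = np.ones((5, 5, 5), dtype=bool)
        spheres = sphere_neighborhoods(mask, 5.0, 2.5)
        member = {
            c: {tuple(v) for v in vox.tolist()} for c, vox in spheres.items()
        }
        for u, vox in member.items():
            for v in vox:
                assert u in member[v]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            sphere_neighborhoods(np.zeros((3, 3, 3), dtype=bool), 7.5, 2.5)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            sphere_offsets(0.0, 2.5)


class TestModelSpec:
    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            ModelSpec(("Hamm", "Hamm:Vivid"))

    def test_unknown_term_rejected(self):
        with pytest.raises(ValueError, match="unknown term"):
            ModelSpec(("Hamm", "Caffeine"))

    def test_design_matrix_column_order_is_spec_order(self):
        pairs = synthetic_pair_table(50)
        spec = lr.VIVIDNESS_MODEL
        X = spec.design_matrix(pairs)
        inc = pairs[pairs["included"]]
        assert np.allclose(X[:, 0], 1.0)
        k = spec.names.index("Hamm:Vivid")
        assert np.allclose(
            X[:, k], inc["hamm"].to_numpy() * inc["vivid_code"].to_numpy()
        )


class TestFitPairGlm:
    def test_exact_recovery_content_model(self):
        pairs = synthetic_pair_table(300, seed=1)
        X = lr.CONTENT_MODEL.design_matrix(pairs)
        y = X @ np.array([0.2, 0.3, -0.1, 0.05])
        fit = fit_pair_glm(y, pairs, lr.CONTENT_MODEL)
        assert np.allclose(fit.coef, [0.2, 0.3, -0.1, 0.05], atol=1e-8)
        assert np.allclose(fit.residuals, 0.0, atol=1e-8)

    def test_exact_recovery_interaction_model(self):
        pairs = synthetic_pair_table(300, seed=2)
        truth = np.array([0.1, 0.3, 0.2, -0.12, -0.1, 0.05])
        X = lr.VIVIDNESS_MODEL.design_matrix(pairs)
        fit = fit_pair_glm(X @ truth, pairs, lr.VIVIDNESS_MODEL)
        assert np.allclose(fit.coef, truth, atol=1e-8)

    def test_pure_noise_slope_within_three_se(self):
        pairs = synthetic_pair_table(1000, seed=3)
        rng = np.random.default_rng(3)
        y = rng.normal(size=1000)
        fit = fit_pair_glm(y, pairs, lr.CONTENT_MODEL)
        X = fit.X
        sigma2 = fit.residuals @ fit.residuals / (len(y) - X.shape[1])
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X).diagonal())
        k = fit.spec.names.index("Hamm")
        assert abs(fit.coef[k]) < 3 * se[k]

    def test_matches_statsmodels_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        pairs = synthetic_pair_table(150, seed=4)
        rng = np.random.default_rng(4)
        y = rng.normal(size=150)
        fit = fit_pair_glm(y, pairs, lr.VIVIDNESS_MODEL)
        res = sm.OLS(y, fit.X).fit()
        assert np.allclose(fit.coef, res.params, atol=1e-10)

    def test_normal_equations_oracle(self):
        pairs = synthetic_pair_table(120, seed=5)
        rng = np.random.default_rng(5)
        y = rng.normal(size=120)
        fit = fit_pair_glm(y, pairs, lr.CONTENT_MODEL)
        X = fit.X
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(fit.coef, ref, atol=1e-10)

    def test_rank_deficient_design_names_terms(self):
        pairs = synthetic_pair_table(100, seed=6)
        pairs["vis_sim"] = pairs["hamm"]  # perfectly collinear
        with pytest.raises(ValueError, match="collinear"):
            fit_pair_glm(np.zeros(100), pairs, lr.CONTENT_MODEL)

    def test_too_few_pairs_rejected(self):
        pairs = synthetic_pair_table(4, seed=7)
        with pytest.raises(ValueError, match="at least"):
            fit_pair_glm(np.zeros(4), pairs, lr.CONTENT_MODEL)


class TestSearchlightMap:
    def test_signal_region_carries_the_hamm_effect(self):
        # grid large enough that many spheres cannot touch the signal region
        cfg = lr.GeneratorConfig(
            seed=31, n_participants=1, n_events=60,
            grid_shape=(12, 12, 12), signal_center=(6, 6, 6),
        )
        study = lr.simulate_study(cfg)
        pairs = lr.build_study_pairs(study)
        maps = lr.searchlight_map(
            study.betas["sub01"], pairs["sub01"], lr.CONTENT_MODEL
        )
        region = study.ground_truth.signal_mask(cfg.grid_shape)
        hamm = maps["Hamm"]
        idx = np.indices(cfg.grid_shape)
        dist = np.sqrt(((idx - np.array([6, 6, 6])[:, None, None, None]) ** 2).sum(0))
        no_overlap = dist > 6  # sphere radius + region radius in voxels
        assert np.nanmean(hamm[region]) > 0.05
        assert np.nanmean(hamm[region]) > 10 * abs(np.nanmean(hamm[no_overlap]))

    def test_constant_data_yields_undefined_fits(self, small_pairs):
        pairs = small_pairs["sub01"]
        n_trials = int(max(pairs["i"].max(), pairs["j"].max())) + 1
        betas = lr.BetaVolume(
            data=np.ones((6, 6, 6, n_trials)),
            voxel_size_mm=2.5,
            mask=np.ones((6, 6, 6), dtype=bool),
        )
        maps = lr.searchlight_map(betas, pairs, lr.CONTENT_MODEL)
        assert np.isnan(maps["Hamm"]).all()

    def test_equivariance_under_consistent_trial_relabeling(self, small_study):
        """Reordering trials and pairs together leaves the maps unchanged."""
        pid = "sub02"
        events = small_study.events[pid]
        feats = small_study.features[pid]
        betas = small_study.betas[pid]
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(events))
        ev2 = [events[k] for k in perm]
        fe2 = [feats[k] for k in perm]
        b2 = lr.BetaVolume(
            data=betas.data[..., perm],
            voxel_size_mm=betas.voxel_size_mm,
            mask=betas.mask,
        )
        m1 = lr.searchlight_map(betas, lr.build_pairs(events, feats), lr.CONTENT_MODEL)
        m2 = lr.searchlight_map(b2, lr.build_pairs(ev2, fe2), lr.CONTENT_MODEL)
        assert np.allclose(m1["Hamm"], m2["Hamm"], equal_nan=True, atol=1e-4)

    def test_zscore_per_sphere_mean_zero_sd_one(self, small_study, small_pairs):
        sl = SubjectSearchlight(
            small_study.betas["sub01"], small_pairs["sub01"], lr.CONTENT_MODEL
        )
        Z = sl.distance_matrix()
        assert np.allclose(Z.mean(axis=1), 0.0, atol=1e-4)
        assert np.allclose(Z.std(axis=1), 1.0, atol=1e-4)

    def test_engine_agrees_with_direct_per_sphere_fit(self, small_study, small_pairs):
        from lifelog_rsa.pair_builder import neural_distances

        pid = "sub03"
        sl = SubjectSearchlight(
            small_study.betas[pid], small_pairs[pid], lr.CONTENT_MODEL
        )
        coefs = sl.coef_matrix()
        spheres = sphere_neighborhoods(
            small_study.betas[pid].mask, 7.5, small_study.betas[pid].voxel_size_mm
        )
        for ci in (0, len(sl.centers) // 2):
            center = tuple(sl.centers[ci])
            nd = neural_distances(
                small_study.betas[pid], spheres[center], small_pairs[pid]
            )
            fit = fit_pair_glm(nd, small_pairs[pid], lr.CONTENT_MODEL)
            assert np.allclose(fit.coef, coefs[:, ci], atol=2e-4)

    def test_interaction_signs_on_attenuated_data(self, region_fits):
        b_hamm = [f["Hamm"] for f in region_fits.values()]
        b_int = [f["Hamm:Vivid"] for f in region_fits.values()]
        assert np.mean(b_hamm) > 0
        assert np.mean(b_int) < 0

    def test_nifti_round_trip(self, small_study, small_pairs, tmp_path):
        pid = "sub01"
        bv = small_study.betas[pid]
        bv.to_nifti(tmp_path / "b.nii", tmp_path / "m.nii")
        back = lr.BetaVolume.from_nifti(tmp_path / "b.nii", tmp_path / "m.nii")
        assert np.allclose(back.data, bv.data)
        assert np.array_equal(back.mask, bv.mask)
        maps = lr.searchlight_map(bv, small_pairs[pid], lr.CONTENT_MODEL)
        written = maps.to_nifti(tmp_path, prefix="sub01")
        assert all(p.exists() for p in written)
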