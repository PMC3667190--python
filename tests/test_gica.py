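"""Order estimation, Infomax separation, stability clustering, GICA3."""

import numpy as np
import pytest

from natisc.gica import (
    _cluster_runs,
    _preprocess_subject,
    back_reconstruct,
    component_tmaps,
    estimate_order,
    fit_group_ica,
    load_model,
    save_model,
)
from natisc.prep import GroupDataset, Mask, SubjectData

from conftest import make_group


def orthogonal_sparse_sources(rng, n_src=2, v=600, sup=80):
    """Supergaussian (Laplace) maps on disjoint supports, zero-mean within
    each support, hence exactly uncorrelated."""
    maps = np.zeros((n_src, v))
    for c in range(n_src):
        block = slice(c * sup, (c + 1) * sup)
        load = rng.laplace(size=sup)
        maps[c, block] = load - load.mean()
    return maps


def noiseless_group(rng, n_sub=3, n_src=2, v=600, t=150):
    maps = orthogonal_sparse_sources(rng, n_src, v)
    bolds = [maps.T @ rng.standard_normal((n_src, t)) for _ in range(n_sub)]
    return make_group(bolds, shape=(10, 10, v // 100)), maps


class TestEstimateOrder:
    def test_noiseless_rank_recovery(self, rng):
        g, _ = noiseless_group(rng, n_src=5, v=800)
        assert estimate_order(g).k_mdl == 5

    @pytest.mark.parametrize("seed", range(5))
    def test_rank5_with_weak_noise(self, seed):
        rng = np.random.default_rng(seed)
        maps = orthogonal_sparse_sources(rng, 5, 800, 80)
        # SNR >= 10 at support voxels
        bolds = []
        for _ in range(2):
            clean = maps.T @ rng.standard_normal((5, 200))
            noise = rng.standard_normal((800, 200)) * 0.2
            bolds.append(clean + noise)
        est = estimate_order(make_group(bolds, shape=(10, 10, 8)))
        assert est.k_mdl == 5

    def test_curve_argmin_matches_per_subject_k(self, rng):
        g, _ = noiseless_group(rng, n_src=3)
        est = estimate_order(g)
        for i in range(len(g.subjects)):
            assert est.per_subject_k[i] == np.argmin(est.criterion_curves[i])

    def test_degenerate_covariance_rejected(self):
        g = make_group([np.zeros((10, 20))])
        with pytest.raises(ValueError):
            estimate_order(g)


class TestFitGroupICA:
    def test_noiseless_two_sources_fully_recovered(self, rng):
        g, maps = noiseless_group(rng)
        model = fit_group_ica(
            g, k=2, n_runs=5, seed=1, max_iter=200, zscore_voxels=False
        )
        corr = np.abs(np.corrcoef(maps, model.aggregate_maps)[:2, 2:])
        assert (corr.max(axis=1) > 0.99).all()
        assert (model.stability_iq > 0.99).all()
        assert model.retained.all()

    def test_unstable_components_not_retained(self, rng):
        # k larger than the true source count: surplus components are
        # noise-driven and must fall below the stability threshold
        maps = orthogonal_sparse_sources(rng, 2, 600, 80)
        bolds = [
            maps.T @ rng.standard_normal((2, 150))
            + 0.5 * rng.standard_normal((600, 150))
            for _ in range(3)
        ]
        g = make_group(bolds, shape=(10, 10, 6))
        model = fit_group_ica(g, k=6, n_runs=4, seed=2, max_iter=150)
        assert np.array_equal(model.retained, model.stability_iq >= 0.9)
        assert model.retained.sum() < 6

    def test_iq_within_unit_interval(self, rng):
        g, _ = noiseless_group(rng)
        model = fit_group_ica(g, k=2, n_runs=3, seed=0, max_iter=100)
        assert np.all(model.stability_iq >= 0.0)
        assert np.all(model.stability_iq <= 1.0)

    def test_cluster_runs_invariant_to_run_order(self, rng):
        # 4 underlying components observed in 3 runs with small jitter
        base = rng.standard_normal((4, 300))
        sources = np.vstack(
            [base + 0.05 * rng.standard_normal(base.shape) for _ in range(3)]
        )
        cents, iq, _ = _cluster_runs(sources, 4)
        perm = rng.permutation(12)
        cents_p, iq_p, _ = _cluster_runs(sources[perm], 4)
        assert np.allclose(np.sort(iq), np.sort(iq_p), atol=1e-12)
        # centrotypes identify the same underlying components
        assert {tuple(np.round(sources[c], 9)) for c in cents} == {
            tuple(np.round(sources[perm][c], 9)) for c in cents_p
        }

    def test_aggregate_sign_has_positive_skew(self, rng):
        from scipy.stats import skew

        g, _ = noiseless_group(rng)
        model = fit_group_ica(g, k=2, n_runs=3, seed=5, max_iter=150,
                              zscore_voxels=False)
        assert (skew(model.aggregate_maps, axis=1) >= 0).all()

    def test_bad_arguments_rejected(self, rng):
        g, _ = noiseless_group(rng)
        with pytest.raises(ValueError):
            fit_group_ica(g, k=2, n_runs=1, seed=0)
        with pytest.raises(ValueError):
            fit_group_ica(g, k=10_000, n_runs=2, seed=0)

    def test_fastica_oracle_agrees(self, rng):
        # independent oracle: a different ICA contrast recovers the same maps
        from sklearn.decomposition import FastICA

        g, maps = noiseless_group(rng)
        model = fit_group_ica(g, k=2, n_runs=4, seed=3, max_iter=200,
                              zscore_voxels=False)
        X = np.vstack([_preprocess_subject(s.bold, False) for s in g.subjects])
        fica = FastICA(n_components=2, random_state=0)
        oracle_maps = fica.fit(X.T).transform(X.T).T  # components x voxels
        corr = np.abs(np.corrcoef(oracle_maps, model.aggregate_maps)[:2, 2:])
        assert (corr.max(axis=1) > 0.99).all()


class TestBackReconstruct:
    def test_single_subject_map_equals_aggregate(self, rng):
        g, _ = noiseless_group(rng, n_sub=1)
        model = fit_group_ica(g, k=2, n_runs=3, seed=1, max_iter=150,
                              zscore_voxels=False)
        assert np.allclose(model.subject_maps[0], model.aggregate_maps, atol=1e-8)

    def test_gica3_mean_identity_and_reconstruction(self, rng):
        g, _ = noiseless_group(rng, n_sub=4)
        model = fit_group_ica(g, k=2, n_runs=3, seed=2, max_iter=150,
                              zscore_voxels=False)
        mean_map = model.subject_maps.mean(axis=0)
        assert np.abs(mean_map - model.aggregate_maps).max() < 1e-6
        for i, s in enumerate(g.subjects):
            d = _preprocess_subject(s.bold, False)
            rec = model.subject_timecourses[i].T @ model.subject_maps[i]
            rel = np.linalg.norm(rec - d) / np.linalg.norm(d)
            assert rel < 1e-6

    def test_missing_reduction_state_rejected(self, rng):
        g, _ = noiseless_group(rng)
        model = fit_group_ica(g, k=2, n_runs=3, seed=1, max_iter=100)
        model.reduction = {}
        with pytest.raises(ValueError):
            back_reconstruct(model, g)


class TestComponentTmaps:
    def test_matches_scalar_formula(self):
        maps = np.array(
            [[[1.0, 0.0]], [[2.0, 0.0]], [[3.0, 0.0]]]
        )  # 3 subjects, 1 comp, 2 voxels
        t, df = component_tmaps(maps)
        expected = 2.0 / (1.0 / np.sqrt(3))
        assert t[0, 0] == pytest.approx(expected, abs=1e-12)
        assert df == 2

    def test_identical_maps_capped(self):
        maps = np.tile(np.array([[[1.0, -1.0, 0.0]]]), (4, 1, 1))
        t, _ = component_tmaps(maps)
        assert t[0, 0] == 1e6 and t[0, 1] == -1e6 and t[0, 2] == 0.0

    def test_df_is_subjects_minus_one(self, rng):
        t, df = component_tmaps(rng.standard_normal((13, 2, 5)))
        assert df == 12


class TestModelIO:
    def test_bundle_roundtrip(self, rng, tmp_path):
        g, _ = noiseless_group(rng)
        model = fit_group_ica(g, k=2, n_runs=3, seed=1, max_iter=100)
        save_model(model, tmp_path / "model")
        back = load_model(tmp_path / "model")
        assert np.allclose(back.aggregate_maps, model.aggregate_maps)
        assert np.allclose(back.subject_timecourses, model.subject_timecourses)
        assert np.array_equal(back.retained, model.retained)
        maps, tcs = back_reconstruct(back, g)
        assert np.allclose(maps, model.subject_maps, atol=1e-8)
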