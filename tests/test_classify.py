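"""Extrinsic/intrinsic sorting, FNC, and stimulus regression of ICs."""

import numpy as np
import pytest

from natisc.classify import (
    classification_table,
    fnc,
    regress_on_stimuli,
    sort_extrinsic,
)
from natisc.gica import GroupICAModel
from natisc.isc import ISCResult
from natisc.prep import Mask
from natisc.stimreg import Regressor


def build_model(tmaps, mask, tcs=None, retained=None, n_sub=13, t_len=100):
    """Hand-built model for classification tests."""
    k, v = tmaps.shape
    if tcs is None:
        tcs = np.random.default_rng(0).standard_normal((n_sub, k, t_len))
    retained = np.ones(k, dtype=bool) if retained is None else retained
    return GroupICAModel(
        order_k=k,
        aggregate_maps=tmaps.copy(),
        subject_maps=np.tile(tmaps, (n_sub, 1, 1)),
        subject_timecourses=tcs,
        stability_iq=np.ones(k),
        retained=retained,
        group_tmaps=tmaps,
        tmap_df=n_sub - 1,
        mask=mask,
        reduction={"dummy": True},
    )


def build_isc(mask_sig, mask):
    n_vox = mask_sig.size
    return ISCResult(
        pair_z=np.zeros((3, n_vox)),
        pair_index=[(0, 1), (0, 2), (1, 2)],
        group_t=np.where(mask_sig, 10.0, 0.0),
        df=77,
        mask_sig=mask_sig,
        clusters=[],
        mask=mask,
    )


@pytest.fixture
def geometry():
    mask = Mask.full((40, 5, 2))
    isc_mask = np.zeros(400, dtype=bool)
    isc_mask[:100] = True  # contiguous block in Fortran order
    return mask, isc_mask


class TestSortExtrinsic:
    def test_ic_equal_to_mask_is_extrinsic(self, geometry):
        mask, isc_mask = geometry
        tmap = np.where(isc_mask, 10.0, 0.0)[None, :]
        model = build_model(tmap, mask)
        cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                             fwe_method="fixed_t", t_fixed=5.0, extent=10,
                             thresholded_template=True)
        assert cls.spatial_r[0] == pytest.approx(1.0)
        assert cls.overlap_pct[0] == pytest.approx(100.0)
        assert cls.is_extrinsic[0]

    def test_disjoint_ic_is_intrinsic(self, geometry):
        mask, isc_mask = geometry
        tmap = np.zeros((1, 400))
        tmap[0, 200:260] = 10.0
        model = build_model(tmap, mask)
        cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                             fwe_method="fixed_t", t_fixed=5.0, extent=10)
        assert cls.overlap_pct[0] == pytest.approx(0.0)
        assert not cls.is_extrinsic[0]

    def test_overlap_conjunction_rule(self, geometry):
        # same positive spatial correlation regime, different overlaps:
        # 70% overlap passes the >50% arm, 40% does not
        mask, isc_mask = geometry
        # strong t inside the ISC mask, just-suprathreshold t outside, so
        # both ICs correlate r > 0.3 with the mask and only overlap differs
        tmaps = np.zeros((2, 400))
        tmaps[0, 30:100] = 30.0  # 70 of 100 suprathreshold voxels in mask
        tmaps[0, 100:130] = 6.0
        tmaps[1, 60:100] = 30.0  # 40 of 100 in mask
        tmaps[1, 100:160] = 6.0
        model = build_model(tmaps, mask)
        cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                             fwe_method="fixed_t", t_fixed=5.0, extent=10)
        assert cls.overlap_pct[0] == pytest.approx(70.0)
        assert cls.overlap_pct[1] == pytest.approx(40.0)
        assert cls.spatial_r[0] > 0.3 and cls.spatial_r[1] > 0.3
        assert cls.is_extrinsic[0] and not cls.is_extrinsic[1]

    def test_empty_thresholded_ic_forced_intrinsic(self, geometry):
        mask, isc_mask = geometry
        tmaps = np.zeros((1, 400))  # nothing survives thresholding
        model = build_model(tmaps, mask)
        with pytest.warns(UserWarning, match="forced intrinsic"):
            cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                                 fwe_method="fixed_t", t_fixed=5.0, extent=10)
        assert not cls.is_extrinsic[0]
        assert np.isnan(cls.overlap_pct[0])

    def test_ranking_descends_in_spatial_r(self, geometry):
        mask, isc_mask = geometry
        tmaps = np.zeros((3, 400))
        tmaps[0, 200:260] = 10.0
        tmaps[1, :100] = 10.0
        tmaps[2, 50:150] = 10.0
        model = build_model(tmaps, mask)
        cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                             fwe_method="fixed_t", t_fixed=5.0, extent=10)
        r = cls.spatial_r[cls.ranking]
        assert np.all(np.diff(r) <= 1e-12)

    def test_relabeling_permutes_outputs_consistently(self, geometry):
        mask, isc_mask = geometry
        rng = np.random.default_rng(1)
        tmaps = np.where(
            rng.random((3, 400)) > 0.8, 10.0, 0.0
        )
        model = build_model(tmaps, mask)
        isc_res = build_isc(isc_mask, mask)
        cls = sort_extrinsic(model, isc_res, fwe_method="fixed_t",
                             t_fixed=5.0, extent=1)
        perm = np.array([2, 0, 1])
        model_p = build_model(tmaps[perm], mask)
        cls_p = sort_extrinsic(model_p, isc_res, fwe_method="fixed_t",
                               t_fixed=5.0, extent=1)
        assert np.allclose(cls_p.spatial_r, cls.spatial_r[perm], equal_nan=True)
        assert np.array_equal(cls_p.is_extrinsic, cls.is_extrinsic[perm])

    def test_empty_isc_mask_rejected(self, geometry):
        mask, _ = geometry
        model = build_model(np.ones((1, 400)), mask)
        with pytest.raises(ValueError):
            sort_extrinsic(model, build_isc(np.zeros(400, dtype=bool), mask))


class TestFNC:
    def _coupled_model(self, geometry, rho=0.6, n_sub=13, t_len=200, k=4):
        mask, isc_mask = geometry
        rng = np.random.default_rng(2)
        tcs = rng.standard_normal((n_sub, k, t_len))
        for s in range(n_sub):  # couple component 2 to component 0
            x = tcs[s, 0]
            n = tcs[s, 2] - (tcs[s, 2] @ x) / (x @ x) * x
            n = (n - n.mean()) / n.std()
            xz = (x - x.mean()) / x.std()
            tcs[s, 2] = rho * xz + np.sqrt(1 - rho**2) * n
        tmaps = np.zeros((k, 400))
        tmaps[0, :60] = 10.0
        tmaps[1, 60:100] = 10.0  # second extrinsic
        tmaps[2, 200:260] = 10.0
        tmaps[3, 300:360] = 10.0
        model = build_model(tmaps, mask, tcs=tcs, n_sub=n_sub, t_len=t_len)
        cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                             fwe_method="fixed_t", t_fixed=5.0, extent=10)
        return model, cls

    def test_pair_count_and_df(self, geometry):
        model, cls = self._coupled_model(geometry)
        res = fnc(model, cls)
        assert cls.is_extrinsic.sum() == 2
        assert res.n_tests == 2 * 2
        assert res.df == 12
        # no component is ever tested against itself
        assert set(res.extrinsic_idx).isdisjoint(set(res.other_idx))

    def test_coupled_pair_detected(self, geometry):
        model, cls = self._coupled_model(geometry, rho=0.6)
        res = fnc(model, cls)
        a = list(res.extrinsic_idx).index(0)
        b = list(res.other_idx).index(2)
        assert res.sig[a, b]
        assert res.mean_r[a, b] == pytest.approx(0.6, abs=0.1)
        # uncoupled pair not significant
        b0 = list(res.other_idx).index(3)
        assert not res.sig[a, b0]

    def test_bonferroni_divisor_is_pair_product(self, geometry):
        model, cls = self._coupled_model(geometry)
        res = fnc(model, cls)
        n_ext = int(cls.is_extrinsic.sum())
        n_ret = int(model.retained.sum())
        assert res.n_tests == n_ext * (n_ret - n_ext)

    def test_too_few_extrinsic_rejected(self, geometry):
        mask, isc_mask = geometry
        model = build_model(np.zeros((2, 400)), mask)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                                 fwe_method="fixed_t", t_fixed=5.0, extent=10)
        with pytest.raises(ValueError):
            fnc(model, cls)


class TestRegressOnStimuli:
    def _regs(self, rng, t_len=451):
        speech = rng.standard_normal(t_len)
        non = rng.standard_normal(t_len)
        return (
            Regressor(speech, 0.4, "speech"),
            Regressor(non, 0.4, "non_speech"),
        )

    def test_ic_equal_to_speech_regressor(self, geometry):
        mask, _ = geometry
        rng = np.random.default_rng(3)
        speech, non = self._regs(rng)
        tcs = np.tile(speech.values, (5, 1, 1))  # 5 subjects, 1 IC
        model = build_model(np.ones((1, 400)), mask, tcs=tcs, n_sub=5,
                            t_len=451)
        res = regress_on_stimuli(model, [speech, non])
        assert res.betas[:, 0, 0] == pytest.approx(1.0, abs=1e-8)
        assert abs(res.betas[:, 0, 1]).max() < 1e-8
        assert res.mean_partial_r[0, 0] > 0.999
        assert res.labels[0] == "speech"
        assert res.df == 4

    def test_mixture_recovery(self, geometry):
        mask, _ = geometry
        rng = np.random.default_rng(4)
        speech, non = self._regs(rng)
        n_sub = 13
        tcs = np.empty((n_sub, 1, 451))
        for s in range(n_sub):
            tcs[s, 0] = (
                0.7 * speech.values + 0.3 * non.values
                + 0.3 * rng.standard_normal(451)
            )
        model = build_model(np.ones((1, 400)), mask, tcs=tcs, n_sub=n_sub,
                            t_len=451)
        res = regress_on_stimuli(model, [speech, non])
        assert res.betas[:, 0, 0].mean() == pytest.approx(0.7, abs=0.1)
        assert res.betas[:, 0, 1].mean() == pytest.approx(0.3, abs=0.1)
        assert res.labels[0] == "both"
        assert res.group_t.shape == (1, 2)

    def test_collinear_regressors_rejected(self, geometry):
        mask, _ = geometry
        rng = np.random.default_rng(5)
        x = rng.standard_normal(100)
        model = build_model(np.ones((1, 400)), mask, n_sub=3, t_len=100)
        with pytest.raises(ValueError):
            regress_on_stimuli(
                model,
                [Regressor(x, 0.4, "speech"), Regressor(x * 2, 0.4, "non_speech")],
            )

    def test_classification_table_columns(self, geometry):
        mask, isc_mask = geometry
        rng = np.random.default_rng(6)
        tmaps = np.zeros((2, 400))
        tmaps[0, :100] = 10.0
        tmaps[1, 200:260] = 10.0
        model = build_model(tmaps, mask, n_sub=5, t_len=451)
        cls = sort_extrinsic(model, build_isc(isc_mask, mask),
                             fwe_method="fixed_t", t_fixed=5.0, extent=10)
        cls.regression = regress_on_stimuli(model, list(self._regs(rng)))
        table = classification_table(model, cls)
        assert len(table) == 2
        for col in ("spatial_r", "overlap_pct", "extrinsic", "iq",
                    "beta_speech", "partial_r_non_speech", "stimulus_label"):
            assert col in table.columns
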