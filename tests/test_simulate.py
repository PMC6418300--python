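"""Synthetic twin-data generator: determinism, closed-form moment fidelity,
Likert discretization, and moderation structure."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import twinpath as tp
from twinpath.data import DZ, MZ
from twinpath.simulate import (DEFAULT_THRESHOLDS, default_item_params,
                               discretize_likert, midus_like_config)


def _group_cov(data, group):
    y = data.phenotypes(group)
    ok = ~np.isnan(y).any(axis=1)
    return np.cov(y[ok].T)


class TestUnivariate:
    def test_seed_determinism(self):
        cfg = tp.SimConfig(n_mz=50, n_dz=50, seed=4, missing_rate=0.1,
                           likert=DEFAULT_THRESHOLDS,
                           parameters=tp.UnivariateACEParams(0.3, 0.4, 0.8))
        d1, d2 = tp.simulate(cfg), tp.simulate(cfg)
        pd.testing.assert_frame_equal(d1.frame, d2.frame)

    def test_pure_e_gives_zero_correlation(self):
        cfg = tp.SimConfig(n_mz=4000, n_dz=4000,
                           parameters=tp.UnivariateACEParams(0.0, 0.0, 1.0),
                           seed=1)
        desc = tp.descriptives(tp.simulate(cfg))
        assert abs(desc.table.loc["scale", "r_mz"]) < 3 / np.sqrt(4000)
        assert abs(desc.table.loc["scale", "r_dz"]) < 3 / np.sqrt(4000)

    def test_closed_form_twin_correlations(self):
        # a^2=0.5, c^2=0.25, e^2=0.25 -> r_MZ=0.75, r_DZ=0.50
        params = tp.UnivariateACEParams(a=np.sqrt(0.5), c=np.sqrt(0.25),
                                        e=np.sqrt(0.25))
        ds = tp.simulate(tp.SimConfig(n_mz=10000, n_dz=10000,
                                      parameters=params, seed=3))
        desc = tp.descriptives(ds)
        for g, r in (("mz", 0.75), ("dz", 0.50)):
            mc_se = (1 - r ** 2) / np.sqrt(10000)
            assert abs(desc.table.loc["scale", f"r_{g}"] - r) < 3 * mc_se

    def test_mz_exceeds_dz_with_genetic_variance(self):
        params = tp.UnivariateACEParams(a=0.6, c=0.3, e=0.74)
        desc = tp.descriptives(tp.simulate(tp.SimConfig(
            n_mz=10000, n_dz=10000, parameters=params, seed=8)))
        assert desc.table.loc["scale", "r_mz"] > desc.table.loc["scale", "r_dz"]


class TestCommonPathway:
    def test_zero_loadings_give_independent_items(self):
        pr = default_item_params()
        pr.loadings = np.zeros_like(pr.loadings)
        ds = tp.simulate(tp.SimConfig(n_mz=3000, n_dz=0, model="cpm",
                                      parameters=pr, seed=2))
        c = np.corrcoef(ds.phenotypes(MZ)[:, :6].T)
        off = c[np.triu_indices(6, 1)]
        assert np.max(np.abs(off)) < 4 / np.sqrt(3000)

    def test_pure_e_factor_has_no_cross_twin_covariance(self):
        pr = tp.CPMParams(loadings=np.full((4, 1), 0.7),
                          a_f=[0.0], c_f=[0.0], e_f=[1.0],
                          a_s=np.zeros(4), c_s=np.zeros(4),
                          e_s=np.full(4, 0.5), b0=np.zeros(4))
        ds = tp.simulate(tp.SimConfig(n_mz=20000, n_dz=0, model="cpm",
                                      parameters=pr, seed=6))
        cov = _group_cov(ds, MZ)
        cross = cov[:4, 4:]
        assert np.max(np.abs(cross)) < 0.04

    def test_moment_fidelity(self):
        pr = default_item_params()
        ds = tp.simulate(tp.SimConfig(n_mz=20000, n_dz=20000, model="cpm",
                                      parameters=pr, seed=10))
        for g in (MZ, DZ):
            expected = tp.cpm_moments(pr, g).cov
            got = _group_cov(ds, g)
            assert np.max(np.abs(got - expected)) < 4 * 1.5 / np.sqrt(20000)

    def test_paper_scale_smoke(self):
        ds = tp.simulate(midus_like_config(seed=0))
        assert (ds.n_mz + ds.n_dz) > 700
        desc = tp.descriptives(ds)
        assert set(desc.table.columns) >= {"r_mz", "r_dz", "mz_mean_t1"}
        # four-point items with low-to-moderate twin correlations
        assert ds.frame["item1_t1"].dropna().isin([1, 2, 3, 4]).all()
        assert 0.0 < desc.avg_r["MZ"] < 0.45


class TestIndependentPathway:
    def test_all_common_loadings_zero(self):
        pr = tp.IPMParams(a_load=np.zeros((4, 1)), c_load=np.zeros((4, 1)),
                          e_load=np.zeros((4, 1)), a_s=np.full(4, 0.3),
                          c_s=np.full(4, 0.3), e_s=np.full(4, 0.6),
                          b0=np.zeros(4))
        ds = tp.simulate(tp.SimConfig(n_mz=3000, n_dz=0, model="ipm",
                                      parameters=pr, seed=3))
        c = np.corrcoef(ds.phenotypes(MZ)[:, :4].T)
        assert np.max(np.abs(c[np.triu_indices(4, 1)])) < 4 / np.sqrt(3000)

    def test_a_only_mz_cross_equals_within_common(self):
        load = np.array([[0.7], [0.6], [0.5], [0.4]])
        pr = tp.IPMParams(a_load=load, c_load=np.zeros((4, 1)),
                          e_load=np.zeros((4, 1)), a_s=np.zeros(4),
                          c_s=np.zeros(4), e_s=np.full(4, 0.5),
                          b0=np.zeros(4))
        m = tp.ipm_moments(pr, MZ)
        within_common = load @ load.T
        assert np.allclose(m.cov[:4, 4:], within_common)
        ds = tp.simulate(tp.SimConfig(n_mz=20000, n_dz=0, model="ipm",
                                      parameters=pr, seed=4))
        got = _group_cov(ds, MZ)[:4, 4:]
        assert np.max(np.abs(got - within_common)) < 0.04

    def test_cpm_nesting_identity_in_simulation(self):
        cpm = default_item_params()
        ipm = tp.ipm_params_from_cpm(cpm)
        d1 = tp.simulate(tp.SimConfig(n_mz=15000, n_dz=15000, model="cpm",
                                      parameters=cpm, seed=12))
        d2 = tp.simulate(tp.SimConfig(n_mz=15000, n_dz=15000, model="ipm",
                                      parameters=ipm, seed=13))
        for g in (MZ, DZ):
            assert np.max(np.abs(_group_cov(d1, g) - _group_cov(d2, g))) < 0.06


class TestModerated:
    def test_null_moderation_reduces_to_ace(self):
        pr = tp.ModeratedACEParams(a0=0.5, a1=0.0, c0=0.5, c1=0.0,
                                   e0=np.sqrt(0.5), e1=0.0)
        ds = tp.simulate(tp.SimConfig(n_mz=10000, n_dz=10000,
                                      model="moderated_ace", parameters=pr,
                                      seed=5))
        desc = tp.descriptives(ds)
        # implied r_MZ = 0.5, r_DZ = 0.375, total variance 1.0
        assert abs(desc.table.loc["scale", "r_mz"] - 0.5) < 0.03
        assert abs(desc.table.loc["scale", "r_dz"] - 0.375) < 0.03
        assert abs(np.nanvar(ds.phenotypes()) - 1.0) < 0.04

    def test_variance_moderation(self):
        # Var(x | M) = (a0+a1 M)^2 + c^2 + e^2
        pr = tp.ModeratedACEParams(a0=0.5, a1=0.3, c0=0.4, c1=0.0,
                                   e0=0.6, e1=0.0)
        ds = tp.simulate(tp.SimConfig(n_mz=60000, n_dz=0,
                                      model="moderated_ace", parameters=pr,
                                      seed=6))
        m = ds.moderator_values(MZ)
        y = ds.phenotypes(MZ)
        for m0 in (-1.0, 1.0):
            sel = np.abs(m - m0) < 0.15
            vals = y[sel].ravel()
            expected = (0.5 + 0.3 * m0) ** 2 + 0.4 ** 2 + 0.6 ** 2
            assert np.nanvar(vals) == pytest.approx(expected, rel=0.12)

    def test_mean_moderation_slope(self):
        pr = tp.ModeratedACEParams(a0=0.3, a1=0.0, c0=0.4, c1=0.0,
                                   e0=0.8, e1=0.0, bM=1.0)
        ds = tp.simulate(tp.SimConfig(n_mz=5000, n_dz=5000,
                                      model="moderated_ace", parameters=pr,
                                      seed=7))
        m = ds.moderator_values()
        y = ds.phenotypes()[:, 0]
        slope = np.polyfit(m, y, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


class TestLikert:
    def test_quartile_thresholds(self):
        from scipy.stats import norm
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200000)
        cats = discretize_likert(x, norm.ppf([0.25, 0.5, 0.75]))
        props = np.bincount(cats.astype(int))[1:] / x.size
        assert np.allclose(props, 0.25, atol=0.01)

    def test_boundaries(self):
        thr = [-1.0, 0.0, 1.0]
        assert discretize_likert(np.array([-5.0]), thr)[0] == 1
        assert discretize_likert(np.array([5.0]), thr)[0] == 4
        assert np.isnan(discretize_likert(np.array([np.nan]), thr)[0])

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_order_preserved(self, x, y):
        lo, hi = min(x, y), max(x, y)
        cats = discretize_likert(np.array([lo, hi]), [-0.9, 0.3, 1.3])
        assert cats[0] <= cats[1]

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError):
            discretize_likert(np.zeros(3), [0.5, 0.2, 1.0])
        with pytest.raises(ValueError):
            tp.SimConfig(likert=[0.5, 0.2, 1.0])

    def test_missingness_structure(self):
        cfg = midus_like_config(seed=1, missing_rate=0.2)
        ds = tp.simulate(cfg)
        y = ds.phenotypes()
        p = ds.p
        t1_missing = np.isnan(y[:, :p]).all(axis=1)
        t2_missing = np.isnan(y[:, p:]).all(axis=1)
        assert t1_missing.any() or t2_missing.any()
        assert not (t1_missing & t2_missing).any()
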