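"""Moment builders, parameter/constraint accounting, and standardization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import twinpath as tp
from twinpath.data import DZ, MZ
from twinpath.simulate import default_item_params

paths = st.floats(-1.5, 1.5, allow_nan=False)


class TestUnivariateMoments:
    def test_pure_e_identity_covariance(self):
        pr = tp.UnivariateACEParams(a=0.0, c=0.0, e=1.0)
        for g in (MZ, DZ):
            m = tp.univariate_ace_moments(pr, g)
            assert np.allclose(m.cov, np.eye(2))

    def test_published_path_arithmetic(self):
        # a=0.30, c=0.41, e=0.86 (scale-score solution)
        pr = tp.UnivariateACEParams(a=0.30, c=0.41, e=0.86)
        m_mz = tp.univariate_ace_moments(pr, MZ)
        m_dz = tp.univariate_ace_moments(pr, DZ)
        assert m_mz.cov[0, 0] == pytest.approx(0.9977)
        assert m_mz.cov[0, 1] == pytest.approx(0.2581)
        assert m_dz.cov[0, 1] == pytest.approx(0.2131)

    @settings(deadline=None, max_examples=50)
    @given(paths, paths, paths)
    def test_mz_dz_gap_is_half_a_squared(self, a, c, e):
        pr = tp.UnivariateACEParams(a=a, c=c, e=e)
        gap = tp.univariate_ace_moments(pr, MZ).cov[0, 1] \
            - tp.univariate_ace_moments(pr, DZ).cov[0, 1]
        assert gap == pytest.approx(0.5 * a * a, abs=1e-12)


class TestModeratedMoments:
    def test_reduces_to_unmoderated(self):
        pr = tp.ModeratedACEParams(a0=0.3, a1=0.0, c0=0.4, c1=0.0,
                                   e0=0.8, e1=0.0, b0=1.0)
        base = tp.UnivariateACEParams(a=0.3, c=0.4, e=0.8, b0=1.0)
        for m0 in (-2.0, 0.0, 1.7):
            for g in (MZ, DZ):
                got = tp.moderated_ace_moments(pr, g, m0)
                ref = tp.univariate_ace_moments(base, g)
                assert np.allclose(got.cov, ref.cov)
                assert np.allclose(got.mean, ref.mean)

    def test_moderated_a_contribution(self):
        pr = tp.ModeratedACEParams(a0=0.5, a1=0.3, c0=0.0, c1=0.0,
                                   e0=0.6, e1=0.0)
        m = tp.moderated_ace_moments(pr, MZ, M=1.0)
        assert m.cov[0, 1] == pytest.approx(0.64)  # (0.5 + 0.3)^2


class TestCPMMoments:
    def test_pure_e_factor_no_cross_twin(self):
        pr = tp.CPMParams(loadings=[[0.8], [0.6]], a_f=[0.0], c_f=[0.0],
                          e_f=[1.0], a_s=[0, 0], c_s=[0, 0], e_s=[0, 0],
                          b0=[0, 0])
        for g in (MZ, DZ):
            assert np.allclose(tp.cpm_moments(pr, g).cov[:2, 2:], 0.0)

    def test_single_a_factor_cross_item_covariance(self):
        pr = tp.CPMParams(loadings=[[0.8], [0.6]], a_f=[1.0], c_f=[0.0],
                          e_f=[0.0], a_s=[0, 0], c_s=[0, 0], e_s=[0.5, 0.5],
                          b0=[0, 0])
        m = tp.cpm_moments(pr, MZ)
        assert m.cov[0, 3] == pytest.approx(0.48)  # 0.8 * 0.6
        m_dz = tp.cpm_moments(pr, DZ)
        assert m_dz.cov[0, 3] == pytest.approx(0.24)

    def test_within_twin_block_zygosity_invariant(self):
        pr = default_item_params()
        mz, dz = tp.cpm_moments(pr, MZ).cov, tp.cpm_moments(pr, DZ).cov
        assert np.allclose(mz[:6, :6], dz[:6, :6])
        assert np.allclose(mz[6:, 6:], mz[:6, :6])

    def test_constraint_violation_rejected(self):
        pr = default_item_params()
        pr.a_f = pr.a_f + 0.2
        with pytest.raises(ValueError, match="constraint"):
            tp.cpm_moments(pr, MZ)

    def test_symmetry(self):
        for g in (MZ, DZ):
            cov = tp.cpm_moments(default_item_params(), g).cov
            assert np.array_equal(cov, cov.T)


class TestIPMMoments:
    def test_cpm_nesting_identity_exact(self):
        cpm = default_item_params()
        ipm = tp.ipm_params_from_cpm(cpm)
        for g in (MZ, DZ):
            a = tp.cpm_moments(cpm, g)
            b = tp.ipm_moments(ipm, g)
            assert np.max(np.abs(a.cov - b.cov)) < 1e-12
            assert np.allclose(a.mean, b.mean)

    def test_e_loadings_only_cross_is_specific(self):
        pr = tp.IPMParams(a_load=np.zeros((3, 1)), c_load=np.zeros((3, 1)),
                          e_load=np.full((3, 1), 0.7),
                          a_s=[0.3, 0.3, 0.3], c_s=[0.2, 0.2, 0.2],
                          e_s=[0.5, 0.5, 0.5], b0=np.zeros(3))
        m = tp.ipm_moments(pr, MZ)
        expected_cross = np.diag([0.3 ** 2 + 0.2 ** 2] * 3)
        assert np.allclose(m.cov[:3, 3:], expected_cross)

    def test_ra_enters_only_a_terms(self):
        pr = tp.IPMParams(a_load=np.full((3, 1), 0.5),
                          c_load=np.full((3, 1), 0.4),
                          e_load=np.full((3, 1), 0.3),
                          a_s=np.zeros(3), c_s=np.zeros(3),
                          e_s=np.full(3, 0.5), b0=np.zeros(3))
        gap = tp.ipm_moments(pr, MZ).cov[:3, 3:] \
            - tp.ipm_moments(pr, DZ).cov[:3, 3:]
        assert np.allclose(gap, 0.5 * 0.25)  # half the A common part


class TestDirectVarCov:
    def test_scalar_case_equals_univariate(self):
        pr = tp.DirectVarCovParams(A=[[0.09]], C=[[0.16]], E=[[0.75]],
                                   b0=[0.2])
        uni = tp.UnivariateACEParams(a=0.3, c=0.4, e=np.sqrt(0.75), b0=0.2)
        for g in (MZ, DZ):
            assert np.allclose(tp.direct_varcov_moments(pr, g).cov,
                               tp.univariate_ace_moments(uni, g).cov)

    def test_indefinite_component_is_representable(self):
        # A has a negative eigenvalue; C/E compensate so the total is PD —
        # the unconstrained baseline evaluates fine
        a = np.array([[0.05, 0.30], [0.30, 0.05]])   # eigenvalues -0.25, 0.35
        c = np.array([[0.30, 0.00], [0.00, 0.30]])
        e = np.array([[0.65, -0.10], [-0.10, 0.65]])
        pr = tp.DirectVarCovParams(A=a, C=c, E=e, b0=[0.0, 0.0])
        assert np.min(np.linalg.eigvalsh(a)) < 0
        for g in (MZ, DZ):
            cov = tp.direct_varcov_moments(pr, g).cov
            assert np.min(np.linalg.eigvalsh(cov)) > 0

    def test_asymmetric_component_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            tp.DirectVarCovParams(A=[[0.1, 0.3], [0.0, 0.1]],
                                  C=np.eye(2) * 0.1, E=np.eye(2) * 0.5,
                                  b0=[0, 0])


class TestParameterAccounting:
    def test_ep_ledger(self, tiny_item_dataset):
        d6 = tiny_item_dataset
        scores = tp.scale_scores(d6)
        assert tp.count_parameters(tp.UnivariateACE(scores)) == (4, 0)
        assert tp.count_parameters(tp.SaturatedUnivariate(scores)) == (10, 0)
        assert tp.count_parameters(tp.DirectVarCov(d6)) == (69, 0)
        assert tp.count_parameters(tp.CommonPathway(d6, 1)) == (33, 1)
        assert tp.count_parameters(tp.CommonPathway(d6, 2)) == (42, 2)
        assert tp.count_parameters(tp.CommonPathway(d6, 3)) == (51, 3)
        assert tp.count_parameters(tp.IndependentPathway(d6, 1)) == (42, 0)
        assert tp.count_parameters(tp.IndependentPathway(d6, 2)) == (60, 0)
        assert tp.count_parameters(tp.CommonPathway(d6, 3, drop="C")) == (42, 3)
        assert tp.count_parameters(tp.CommonPathway(d6, 3, drop="A")) == (42, 3)

    def test_internal_dimensions_match_names(self, tiny_item_dataset):
        for model in (tp.CommonPathway(tiny_item_dataset, 2),
                      tp.IndependentPathway(tiny_item_dataset, 2),
                      tp.DirectVarCov(tiny_item_dataset)):
            assert len(model.internal_names) == model.start_internal().size


class TestStandardization:
    def _fit_like(self, model, x):
        from twinpath.fiml import TwinModelResults
        return TwinModelResults(model, x, 0.0, "converged", 1)

    def test_equal_paths_give_thirds(self, ace_dataset):
        ds, _ = ace_dataset
        model = tp.UnivariateACE(ds)
        fit = self._fit_like(model, np.array([0.0, 0.5, 0.5, 0.5]))
        assert np.allclose(tp.standardize_components(fit), 1 / 3)

    def test_published_share_arithmetic(self, ace_dataset):
        ds, _ = ace_dataset
        model = tp.UnivariateACE(ds)
        fit = self._fit_like(model, np.array([0.0, 0.30, 0.41, 0.86]))
        shares = tp.standardize_components(fit)
        assert shares["A"] == pytest.approx(0.090, abs=5e-4)
        assert shares["C"] == pytest.approx(0.168, abs=5e-4)
        assert shares["E"] == pytest.approx(0.741, abs=5e-4)

    def test_scale_invariance(self, ace_dataset):
        ds, _ = ace_dataset
        model = tp.UnivariateACE(ds)
        s1 = tp.standardize_components(
            self._fit_like(model, np.array([0.0, 0.3, 0.4, 0.8])))
        s2 = tp.standardize_components(
            self._fit_like(model, np.array([0.0, 0.6, 0.8, 1.6])))
        assert np.allclose(s1, s2)

    def test_zero_variance_flagged(self, ace_dataset):
        ds, _ = ace_dataset
        model = tp.UnivariateACE(ds)
        with pytest.raises(ValueError, match="undefined"):
            tp.standardize_components(
                self._fit_like(model, np.array([0.0, 0.0, 0.0, 0.0])))


class TestEncodeRoundTrip:
    def test_cpm_encode_unpack(self, tiny_item_dataset):
        model = tp.CommonPathway(tiny_item_dataset, n_factors=3)
        pr = default_item_params()
        x = model.encode(pr)
        back = model._unpack(x)
        assert np.allclose(back.loadings, pr.loadings)
        assert np.allclose(np.abs(back.a_f), pr.a_f, atol=1e-12)
        assert np.allclose(np.abs(back.e_f), pr.e_f, atol=1e-12)
        # deviances agree between the builder and the internal path
        for g in (MZ, DZ):
            assert np.allclose(model.moments(x, g).cov,
                               tp.cpm_moments(pr, g).cov, atol=1e-12)

    def test_ipm_encode_unpack(self, tiny_item_dataset):
        model = tp.IndependentPathway(tiny_item_dataset, n_factors=3)
        pr = tp.ipm_params_from_cpm(default_item_params())
        x = model.encode(pr)
        back = model._unpack(x)
        for g in (MZ, DZ):
            assert np.allclose(model.moments(x, g).cov,
                               tp.ipm_moments(pr, g).cov, atol=1e-12)
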