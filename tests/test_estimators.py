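import numpy as np
import pytest
from scipy import stats

import twistpg as tw
from conftest import make_data, random_dataset


def group_mean_oracles(data):
    """Closed-form group-mean expressions for all five estimators (no covariates)."""
    G, T, Y = data.G, data.T, data.Y
    g1t1 = Y[(G == 1) & (T == 1)].mean()
    g0t1 = Y[(G == 0) & (T == 1)].mean()
    g1t0 = Y[(G == 1) & (T == 0)].mean()
    g0t0 = Y[(G == 0) & (T == 0)].mean()
    gmte1 = g1t1 - g0t1
    gmte0 = g1t0 - g0t0
    mr = (Y[G == 1].mean() - Y[G == 0].mean()) / T[G == 1].mean()
    cat = (Y[T == 1].mean() - Y[T == 0].mean()) / G[T == 1].mean()
    return {"GMTE1": gmte1, "GMTE0": gmte0, "RGMTE": gmte1 - gmte0, "MR": mr, "CAT": cat}


class TestWorkedExamples:
    def test_gmte1_treated_only_is_carrier_contrast(self):
        data = make_data(G=[1, 1, 0, 0], T=[1, 1, 1, 1], Y=[1.5, 2.5, 3.0, 3.0])
        est = tw.gmte1(data)
        assert est.beta == pytest.approx(-1.0)

    def test_constant_outcome_gives_zero_effect(self):
        data = make_data(G=[1, 1, 0, 0, 1, 0], T=[1, 1, 1, 1, 0, 0], Y=np.full(6, 7.0))
        assert tw.gmte1(data).beta == pytest.approx(0.0, abs=1e-12)

    def test_gmte0_is_untreated_carrier_contrast(self):
        data = make_data(G=[1, 1, 0, 0, 1, 0, 1, 0], T=[0, 0, 0, 0, 1, 1, 1, 1],
                         Y=[1.1, 1.3, 1.0, 1.0, 9.0, 8.0, 7.0, 6.0])
        assert tw.gmte0(data).beta == pytest.approx(0.2)

    def test_mr_is_wald_ratio(self):
        G = np.repeat([1.0, 0.0], 10)
        T = np.concatenate([np.repeat([1.0, 0.0], [4, 6]), np.repeat([1.0, 0.0], [5, 5])])
        Y = -0.2 * G
        est = tw.mr(make_data(G, T, Y))
        assert est.beta == pytest.approx(-0.5)

    def test_cat_rescales_as_treated_difference(self):
        data = make_data(G=[1, 1, 0, 0, 1, 1, 0, 0], T=[1, 1, 1, 1, 0, 0, 0, 0],
                         Y=[4.0, 4.0, 4.0, 4.0, 3.0, 3.0, 3.0, 3.0])
        assert tw.cat(data).beta == pytest.approx(2.0)

    def test_cat_with_all_treated_carriers_is_unscaled_difference(self):
        # E[G|T=1] = 1, so CAT equals the raw treated-untreated contrast
        data = make_data(G=[1, 1, 1, 1, 0, 1, 0, 1], T=[1, 1, 1, 1, 0, 0, 0, 0],
                         Y=[4.0, 4.0, 4.0, 4.0, 3.0, 3.0, 3.0, 3.0])
        assert tw.cat(data).beta == pytest.approx(1.0)


class TestClosedFormEquivalence:
    def test_all_estimators_match_group_mean_oracles(self, rng):
        for _ in range(10):
            data = random_dataset(rng, n=rng.integers(40, 90))
            oracle = group_mean_oracles(data)
            fits = tw.fit_all(data)
            for label, expected in oracle.items():
                assert fits[label].beta == pytest.approx(expected, rel=1e-8), label

    def test_p_values_match_two_sided_normal_test(self, rng):
        data = random_dataset(rng, with_covariate=True)
        for est in tw.fit_all(data).values():
            expected = 2 * stats.norm.sf(abs(est.beta / est.se))
            assert abs(est.p - expected) < 1e-9


class TestRgmteIdentity:
    def test_difference_and_regression_agree_exactly_without_covariates(self, rng):
        for _ in range(10):
            data = random_dataset(rng)
            diff = tw.rgmte(data, method="difference")
            reg = tw.rgmte(data, method="regression")
            assert reg.beta == pytest.approx(diff.beta, rel=1e-8)

    def test_forms_agree_statistically_with_pooled_covariates(self, rng):
        # with a pooled additive covariate the two forms differ by O(1/n),
        # far inside the estimate's own standard error
        for _ in range(5):
            data = random_dataset(rng, n=400, with_covariate=True)
            diff = tw.rgmte(data, method="difference")
            reg = tw.rgmte(data, method="regression")
            assert abs(diff.beta - reg.beta) < 0.25 * reg.se

    def test_difference_se_adds_in_quadrature(self, rng):
        data = random_dataset(rng)
        e1, e0 = tw.gmte1(data), tw.gmte0(data)
        diff = tw.rgmte(data, method="difference")
        assert diff.beta == pytest.approx(e1.beta - e0.beta)
        assert diff.se == pytest.approx(np.hypot(e1.se, e0.se))
        assert diff.se >= e1.se


class TestErrorHandling:
    def test_missing_genotype_level_among_treated(self):
        data = make_data(G=[1, 1, 0, 0, 0, 0], T=[0, 0, 1, 1, 0, 0], Y=np.arange(6.0))
        with pytest.raises(tw.SingularDesignError):
            tw.gmte1(data)

    def test_tiny_stratum_rejected_not_nan(self):
        data = make_data(G=[1, 0, 0, 1, 0, 1], T=[1, 1, 1, 0, 0, 0], Y=np.arange(6.0))
        with pytest.raises(tw.SingularDesignError):
            tw.gmte1(data)  # only one treated carrier

    def test_weak_instrument_when_no_treated_carriers(self):
        data = make_data(G=[1, 1, 0, 0, 0, 0], T=[0, 0, 1, 1, 0, 0], Y=np.arange(6.0))
        with pytest.raises(tw.WeakInstrumentError):
            tw.mr(data)

    def test_few_treated_carriers_warn_without_truncation(self, rng):
        data = random_dataset(rng, n=40, p_g=0.3, p_t=0.3)
        assert data.df["T_star"].sum() < 10
        with pytest.warns(UserWarning, match="treated carriers"):
            est = tw.mr(data)
        assert np.isfinite(est.beta)

    def test_gmte0_requires_untreated_rows(self):
        data = make_data(G=[1, 0, 1, 0], T=[1, 1, 1, 1], Y=np.arange(4.0))
        with pytest.raises(tw.SingularDesignError):
            tw.gmte0(data)

    def test_unknown_estimator_label(self, rng):
        data = random_dataset(rng)
        with pytest.raises(tw.ValidationError):
            tw.fit_single(data, "ATE")

    def test_alpha_outside_unit_interval(self):
        with pytest.raises(tw.ValidationError):
            tw.EstimandSpec(alpha=1.5)


class TestMetadata:
    def test_assumption_strings_attached(self, rng):
        fits = tw.fit_all(random_dataset(rng))
        assert "PG1" in fits["RGMTE"].assumptions
        assert "Hom" in fits["CAT"].assumptions
        assert "zero" in fits["GMTE0"].assumptions

    def test_scale_is_mean_difference_for_continuous(self, rng):
        fits = tw.fit_all(random_dataset(rng))
        assert {e.scale for e in fits.values()} == {"mean_difference"}

    def test_robust_standard_errors_differ_but_estimate_matches(self, rng):
        data = random_dataset(rng, n=300, with_covariate=True)
        plain = tw.gmte1(data)
        robust = tw.gmte1(data, tw.EstimandSpec(robust=True))
        assert robust.beta == pytest.approx(plain.beta)
        assert robust.se != plain.se
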