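"""Estimator algebra: associations, delta-method differences, interactions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sibige import (
    AssocEstimate,
    associations_by_sibship,
    estimate_difference,
    fit_association,
    fit_sibling_interaction,
    group_differences,
    heterogeneity_z,
    scale_sibling_ige,
)

from conftest import COVARIATES


def _toy_cohort(n=200, seed=0):
    rng = np.random.default_rng(seed)
    pgs = rng.normal(size=n)
    return pd.DataFrame(
        {
            "pgs_ea": pgs,
            "ea": 2.0 * pgs,
            "singleton": [True] * (n // 2) + [False] * (n - n // 2),
            "sex": rng.integers(0, 2, n),
            "birth_year": rng.integers(1940, 1970, n),
        }
    )


class TestFitAssociation:
    def test_exact_linear_phenotype(self):
        est = fit_association(_toy_cohort(), "ea", "singleton", covariates=[])
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.0, abs=1e-8)

    def test_empty_stratum_rejected(self):
        cohort = _toy_cohort()
        cohort["singleton"] = True
        with pytest.raises(ValueError, match="empty"):
            fit_association(cohort, "ea", "non-singleton", covariates=[])

    def test_collinear_design_names_column(self):
        cohort = _toy_cohort()
        cohort["dup"] = cohort["sex"]
        with pytest.raises(ValueError, match="dup"):
            fit_association(
                cohort, "ea", "singleton", covariates=["sex", "dup"]
            )

    def test_singleton_slope_matches_analytic_expectation(self, ige_cohort):
        # beta_S = k_I + 0.5 k_M + 0.5 k_P = 0.6 for the fixture generator
        est = fit_association(
            ige_cohort, "ea", "singleton", covariates=COVARIATES
        )
        assert est.beta == pytest.approx(0.6, abs=5 * est.se)


class TestEstimateDifference:
    def test_identical_estimates_give_null(self):
        a = AssocEstimate(0.5, 0.01, 1000, "non-singleton", "ea")
        b = AssocEstimate(0.5, 0.01, 1000, "singleton", "ea")
        d = estimate_difference(a, b, reference="a")
        assert d.delta == 0.0
        assert d.p == pytest.approx(1.0)
        assert d.attenuation_pct == 0.0

    def test_closed_form_se_and_ci(self):
        d = estimate_difference((0.26, 0.010), (0.23, 0.010), reference=None)
        assert d.delta == pytest.approx(0.03)
        assert d.se_delta == pytest.approx(np.sqrt(2) * 0.010)
        assert d.ci95[0] == pytest.approx(0.03 - 1.96 * 0.0141421, abs=1e-4)
        assert d.ci95[1] == pytest.approx(0.03 + 1.96 * 0.0141421, abs=1e-4)

    def test_attenuation_is_fixed_denominator_rescaling(self):
        d = estimate_difference((0.26, 0.010), (0.23, 0.010), reference="a")
        assert d.attenuation_pct == pytest.approx(100 * 0.03 / 0.26)
        assert d.attenuation_ci95[0] == pytest.approx(
            100 * d.ci95[0] / 0.26
        )
        assert d.attenuation_ci95[1] == pytest.approx(
            100 * d.ci95[1] / 0.26
        )

    def test_zero_reference_flags_attenuation_undefined(self):
        d = estimate_difference((0.0, 0.01), (0.1, 0.01), reference="a")
        assert d.attenuation_pct is None

    def test_mismatched_traits_rejected(self):
        a = AssocEstimate(0.5, 0.01, 1000, "non-singleton", "ea")
        b = AssocEstimate(0.5, 0.01, 1000, "singleton", "height")
        with pytest.raises(ValueError, match="traits differ"):
            estimate_difference(a, b)

    @settings(deadline=None, max_examples=50)
    @given(
        se_a=st.floats(1e-6, 10), se_b=st.floats(1e-6, 10),
        beta_a=st.floats(-5, 5), beta_b=st.floats(-5, 5),
    )
    def test_se_closed_form_holds_everywhere(self, se_a, se_b, beta_a, beta_b):
        d = estimate_difference((beta_a, se_a), (beta_b, se_b), reference=None)
        assert d.se_delta == pytest.approx(np.hypot(se_a, se_b), rel=1e-12)


class TestScaleSiblingIGE:
    def test_exact_doubling(self):
        est = scale_sibling_ige(0.012, se=0.003)
        assert est.k_S_hat == 0.024
        assert est.se == 0.006
        lo, hi = est.ci95
        assert lo == pytest.approx(2 * (0.012 - 1.96 * 0.003), abs=1e-5)
        assert hi == pytest.approx(2 * (0.012 + 1.96 * 0.003), abs=1e-5)

    def test_zero_maps_to_zero(self):
        assert scale_sibling_ige(0.0, se=0.001).k_S_hat == 0.0

    def test_infinite_se_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            scale_sibling_ige(0.1, se=np.inf)

    @settings(deadline=None, max_examples=50)
    @given(point=st.floats(-1, 1), se=st.floats(0, 1))
    def test_doubling_property(self, point, se):
        est = scale_sibling_ige(point, se=se)
        assert est.k_S_hat == 2 * point
        assert est.se == 2 * se


class TestSiblingInteraction:
    def test_quadratic_degenerate_without_spread(self):
        cohort = _toy_cohort()
        cohort["n_siblings"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            fit_sibling_interaction(cohort, "ea", model="quadratic")

    def test_null_interaction_when_no_sibling_effect(self, null_cohort):
        est = fit_sibling_interaction(
            null_cohort, "ea", "linear", covariates=COVARIATES
        )
        assert est.beta_NxPGS == pytest.approx(0.0, abs=5 * est.se_NxPGS)

    def test_recovers_half_k_s_increment(self, ige_cohort):
        # generator: all-sibling IGE k_S = 0.2 -> increment 0.5*k_S = 0.1
        est = fit_sibling_interaction(
            ige_cohort, "ea", "linear", "6+_removed", covariates=COVARIATES
        )
        assert est.beta_NxPGS == pytest.approx(0.1, abs=5 * est.se_NxPGS)
        ige = scale_sibling_ige(est)
        assert ige.k_S_hat == pytest.approx(0.2, abs=10 * est.se_NxPGS)

    def test_exclusion_drops_large_sibships(self, ige_cohort):
        full = fit_sibling_interaction(ige_cohort, "ea", "linear", "none")
        trimmed = fit_sibling_interaction(
            ige_cohort, "ea", "linear", "6+_removed"
        )
        assert trimmed.n < full.n


class TestHeterogeneityZ:
    def test_equal_estimates(self):
        out = heterogeneity_z((0.025, 0.0059), (0.025, 0.02))
        assert out["z"] == 0.0
        assert out["p"] == pytest.approx(1.0)

    def test_closed_form(self):
        out = heterogeneity_z((1.0, 1.0), (0.0, 1.0))
        assert out["z"] == pytest.approx(0.7071, abs=1e-4)
        assert out["p"] == pytest.approx(0.4795, abs=1e-4)

    def test_degenerate_ses_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_z((1.0, 0.0), (0.0, 0.0))


class TestGroupDifferences:
    def _cohort(self, shift=0.0, n=2000, seed=1):
        rng = np.random.default_rng(seed)
        singleton = np.repeat([True, False], n // 2)
        height = rng.normal(170, 5, n) + shift * (~singleton)
        return pd.DataFrame(
            {
                "singleton": singleton,
                "firstborn": ~singleton,
                "height": height,
                "sex": rng.integers(0, 2, n),
                "birth_year": rng.integers(1940, 1970, n),
            }
        )

    def test_identical_groups_show_no_difference(self):
        table = group_differences(self._cohort(0.0), ["height"], adjustment="none")
        row = table.iloc[0]
        assert abs(row["difference"]) < 5 * row["se"]

    def test_constructed_shift_recovered_with_adjustment(self):
        cohort = self._cohort(0.0)
        cohort.loc[~cohort["singleton"], "height"] += 1.0
        table = group_differences(cohort, ["height"], adjustment="sex+age")
        assert table.iloc[0]["difference"] == pytest.approx(1.0, abs=0.6)

    def test_binary_variable_uses_two_proportion_se(self):
        cohort = self._cohort(0.0)
        table = group_differences(cohort, ["sex"], adjustment="none")
        ga = cohort[cohort["singleton"]]["sex"]
        gb = cohort[~cohort["singleton"]]["sex"]
        expected_se = np.sqrt(
            ga.var(ddof=1) / len(ga) + gb.var(ddof=1) / len(gb)
        )
        assert table.iloc[0]["se"] == pytest.approx(expected_se, rel=1e-9)

    def test_unknown_variable_rejected(self):
        with pytest.raises(ValueError, match="unknown variable"):
            group_differences(self._cohort(), ["weight"])


class TestAssociationsBySibship:
    def test_singleton_only_cohort_populates_category_zero(self):
        cohort = _toy_cohort()
        cohort["sibship_category"] = "0"
        cohort["n_siblings"] = 0.0
        ests, diff = associations_by_sibship(cohort, "ea", covariates=[])
        assert ests[0] is not None
        assert all(e is None for e in ests[1:])
        assert diff is None

    def test_null_cohort_categories_are_homogeneous(self, null_cohort):
        ests, diff = associations_by_sibship(
            null_cohort, "ea", covariates=COVARIATES
        )
        betas = [e.beta for e in ests if e is not None and e.n > 500]
        assert max(betas) - min(betas) < 0.1
        assert diff.p > 0.001

    def test_linear_generator_shows_increasing_betas(self, ige_cohort):
        ests, _ = associations_by_sibship(
            ige_cohort, "ea", covariates=COVARIATES
        )
        betas = [e.beta for e in ests[:5] if e is not None]
        assert all(b2 > b1 for b1, b2 in zip(betas, betas[1:]))
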