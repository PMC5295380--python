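"""Closed-form tranche calculus: thresholds, tails, values, yields."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from megafund import (
    AnalyticParams,
    ParameterError,
    UnfairParams,
    equity_default_prob,
    equity_threshold,
    equity_value_and_yield,
    senior_default_prob,
    senior_threshold,
    senior_value_and_yield,
    table_report,
    unfair_equity,
    unfair_senior,
)


def make_params(**kwargs):
    defaults = dict(
        n_assets=150,
        n_lemons=0,
        n_spvs=1,
        spv_size=150,
        success_prob=0.05,
        success_value=12.3,
        investment_per_program=0.2,
        senior_share=0.5,
        senior_rate=0.05,
        horizon_years=10.0,
    )
    defaults.update(kwargs)
    return AnalyticParams(**defaults)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_lemons=-1),
            dict(n_lemons=151),
            dict(n_spvs=0),
            dict(spv_size=0),
            dict(spv_size=151),
            dict(success_prob=1.5),
            dict(senior_share=0.0),
            dict(senior_share=1.0),
            dict(success_value=-1.0),
            dict(horizon_years=0.5),
            dict(n_spvs=2, spv_size=52),  # M*D < N
        ],
    )
    def test_invalid_params_rejected(self, bad):
        with pytest.raises(ParameterError):
            make_params(**bad)

    def test_nonintegral_nonlemon_count_strict_vs_relaxed(self):
        # D*(N-n)/N = 52*140/150 is not an integer
        with pytest.raises(ParameterError):
            make_params(n_lemons=10, n_spvs=5, spv_size=52)
        p = make_params(n_lemons=10, n_spvs=5, spv_size=52, strict=False)
        assert p.n_nonlemons_per_spv == round(52 * 140 / 150)

    def test_unfair_lemon_slot_conservation_enforced(self):
        base = make_params(n_lemons=75, success_prob=0.10, n_spvs=6, spv_size=52)
        with pytest.raises(ParameterError):
            UnfairParams(
                base=base,
                n_clean_spvs=3,
                n_toxic_spvs=3,
                lemons_per_clean_spv=10,
                lemons_per_toxic_spv=43,
            )


class TestSeniorThreshold:
    def test_threshold_is_one_when_promise_equals_one_success(self):
        # r=0 and B = D*I*s makes the pre-ceiling value exactly 1
        p = make_params(senior_rate=0.0, success_value=150 * 0.2 * 0.5)
        assert senior_threshold(p) == 1

    def test_threshold_monotone_in_rate_size_and_shares(self):
        base = make_params()
        k0 = senior_threshold(base)
        assert senior_threshold(make_params(senior_rate=0.2)) >= k0
        assert senior_threshold(make_params(senior_share=0.8)) >= k0
        assert senior_threshold(make_params(investment_per_program=0.4)) >= k0
        assert senior_threshold(make_params(success_value=25.0)) <= k0


class TestSeniorDefault:
    def test_all_lemons_default_is_certain(self):
        p = make_params(n_lemons=150, success_prob=0.10)
        assert senior_default_prob(p) == 1.0

    def test_small_tail_matches_exhaustive_enumeration(self):
        # NL=5, p=0.5, K=3: enumerate all 2^5 equally likely outcomes.
        # Engineer K=3: pre-ceiling = (D*I*s/B)(1+r)^T with r=0 -> D*I*s/B
        p = make_params(
            n_assets=10,
            n_lemons=5,
            spv_size=10,
            success_prob=0.5,
            senior_rate=0.0,
            investment_per_program=1.0,
            senior_share=0.5,
            success_value=2.0,  # 10*1*0.5/2 = 2.5 -> K = 3
        )
        assert senior_threshold(p) == 3
        count = sum(
            1
            for bits in itertools.product([0, 1], repeat=5)
            if sum(bits) < 3
        )
        assert senior_default_prob(p) == pytest.approx(count / 32, abs=1e-12)

    def test_default_monotone_in_success_prob_and_lemons(self):
        ds = [
            senior_default_prob(make_params(n_lemons=75, success_prob=q))
            for q in (0.05, 0.10, 0.20, 0.40)
        ]
        assert all(a >= b for a, b in zip(ds, ds[1:]))
        dn = [
            senior_default_prob(make_params(n_lemons=n, success_prob=0.10))
            for n in (0, 30, 75, 120)
        ]
        assert all(a <= b for a, b in zip(dn, dn[1:]))

    def test_large_spv_tail_is_stable(self):
        p = make_params(
            n_assets=10_000, n_lemons=0, spv_size=10_000, success_prob=0.05
        )
        d = senior_default_prob(p)
        assert 0.0 <= d <= 1.0 and np.isfinite(d)


class TestSeniorYield:
    def test_yield_equals_coupon_without_default(self):
        # every program succeeds and one success covers the promise
        p = make_params(success_prob=1.0, success_value=1e4, senior_rate=0.07)
        res = senior_value_and_yield(p)
        assert res.default_prob == pytest.approx(0.0, abs=1e-15)
        assert res.annual_yield == pytest.approx(0.07, abs=1e-12)

    @pytest.mark.parametrize("n_spvs", [5, 25, 75])
    def test_senior_results_invariant_in_spv_count(self, n_spvs):
        ref = senior_value_and_yield(
            make_params(n_lemons=75, success_prob=0.10, n_spvs=3, spv_size=52)
        )
        res = senior_value_and_yield(
            make_params(n_lemons=75, success_prob=0.10, n_spvs=n_spvs, spv_size=52)
        )
        assert res.default_prob == pytest.approx(ref.default_prob, rel=1e-12)
        assert res.annual_yield == pytest.approx(ref.annual_yield, rel=1e-12)


class TestEquity:
    def test_single_spv_conservation_identity(self):
        p = make_params(n_lemons=75, success_prob=0.10, senior_rate=0.085)
        senior = senior_value_and_yield(p)
        equity = equity_value_and_yield(p, senior)
        gross = 75 * 0.10 * 12.3
        assert senior.expected_value + equity.expected_value == pytest.approx(
            gross, rel=1e-12
        )

    def test_estimate_matches_exact_single_spv_threshold(self):
        # For M=1 the fund-level estimate is the exact threshold: the
        # minimal k with k*B >= I_senior*(1+r)^T + I_equities.
        p = make_params(n_lemons=75, success_prob=0.10, senior_rate=0.085)
        promise = 150 * 0.2 * 0.5 * 1.085**10
        exact = math.ceil((promise + 150 * 0.2 * 0.5) / 12.3)
        assert equity_threshold(p) == exact

    def test_all_lemons_wipes_out_equity(self):
        p = make_params(n_lemons=150, success_prob=0.10)
        res = equity_value_and_yield(p)
        assert res.wiped_out
        assert res.expected_value == 0.0
        assert res.annual_yield == -1.0

    @given(
        n=st.integers(min_value=10, max_value=400),
        lemon_frac=st.floats(min_value=0.0, max_value=0.9),
        p=st.floats(min_value=0.01, max_value=0.9),
        r=st.floats(min_value=0.0, max_value=0.3),
        s=st.floats(min_value=0.1, max_value=0.9),
    )
    def test_conservation_property_single_spv(self, n, lemon_frac, p, r, s):
        n_lemons = int(n * lemon_frac)
        params = make_params(
            n_assets=n,
            n_lemons=n_lemons,
            spv_size=n,
            success_prob=p,
            senior_rate=r,
            senior_share=s,
        )
        senior = senior_value_and_yield(params)
        equity = equity_value_and_yield(params, senior)
        gross = (n - n_lemons) * p * 12.3
        if equity.wiped_out:
            assert senior.expected_value >= gross - 1e-9
        else:
            assert senior.expected_value + equity.expected_value == pytest.approx(
                gross, rel=1e-10, abs=1e-10
            )


class TestUnfair:
    @pytest.fixture()
    def unfair(self):
        base = make_params(n_lemons=75, success_prob=0.10, n_spvs=6, spv_size=52, senior_rate=0.168)
        return UnfairParams(
            base=base,
            n_clean_spvs=3,
            n_toxic_spvs=3,
            lemons_per_clean_spv=9,
            lemons_per_toxic_spv=43,
        )

    def test_degenerate_split_equals_reliable_fund(self):
        # d1 = d2 = n*D/N makes both sub-funds identical to the reliable fund
        base = make_params(n_lemons=75, success_prob=0.10, n_spvs=6, spv_size=52, senior_rate=0.168)
        even = 75 * 52 // 150
        degenerate = UnfairParams(
            base=base,
            n_clean_spvs=3,
            n_toxic_spvs=3,
            lemons_per_clean_spv=even,
            lemons_per_toxic_spv=even,
        )
        res = unfair_senior(degenerate)
        assert res.default_prob == pytest.approx(senior_default_prob(base), rel=1e-12)
        ref = senior_value_and_yield(base)
        assert res.annual_yield == pytest.approx(ref.annual_yield, rel=1e-12)

    def test_all_clean_limit_equals_reliable_equity(self, unfair):
        assert unfair_equity(unfair).default_prob == pytest.approx(
            equity_default_prob(unfair.base), rel=1e-12
        )

    def test_toxic_concentration_raises_overall_default(self, unfair):
        base_d = senior_default_prob(unfair.base)
        assert unfair_senior(unfair).default_prob > base_d


class TestTableReport:
    def test_report_shape_and_determinism(self, table2_cases):
        report = table_report(table2_cases)
        assert len(report) == 12
        again = table_report(table2_cases)
        assert report.equals(again)

    def test_empty_case_list(self):
        report = table_report({})
        assert len(report) == 0
        assert "senior_d_pct" in report.columns

    def test_duplicate_case_rows_identical(self, table2_cases):
        params = table2_cases["reliable_5"]
        report = table_report([("a", params), ("b", params)])
        assert (
            report.drop(columns="case").iloc[0].tolist()
            == report.drop(columns="case").iloc[1].tolist()
        )
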