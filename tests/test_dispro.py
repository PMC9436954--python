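"""ROR, adjusted ROR, information component and flag rules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.core import ContingencyTable, ReportSet
from pvsignal.dispro import (
    RorResult,
    SeparationError,
    adjusted_ror,
    crude_ror,
    ic_credible_bounds,
    information_component,
    signal_flag_ic,
    signal_flag_ror,
)

from conftest import make_report


class TestCrudeRor:
    def test_cross_product_by_hand(self):
        res = crude_ror(ContingencyTable(10, 20, 5, 40))
        assert res.estimate == pytest.approx(4.0)
        assert res.ci_low < 4.0 < res.ci_high

    @pytest.mark.parametrize("k", [1, 7, 100])
    def test_symmetric_tables_give_unity(self, k):
        assert crude_ror(ContingencyTable(k, k, k, k)).estimate == pytest.approx(1.0)

    def test_haldane_anscombe_on_zero_cell(self):
        res = crude_ror(ContingencyTable(0, 10, 10, 100))
        assert res.estimate == pytest.approx((0.5 * 100.5) / (10.5 * 10.5))

    def test_all_zero_table_undefined(self):
        with pytest.raises(ValueError, match="all-zero"):
            crude_ror(ContingencyTable(0, 0, 0, 0))

    def test_monotone_in_n11(self):
        estimates = [
            crude_ror(ContingencyTable(n11, 30, 20, 50)).estimate
            for n11 in range(1, 15)
        ]
        assert all(a < b for a, b in zip(estimates, estimates[1:]))


def _two_arm_reports(rng, n, p_exposed, p_outcome_exposed, p_outcome_unexposed,
                     confounded=False):
    """Report-level stream with an optional seriousness confounder."""
    reports = []
    for i in range(n):
        serious = rng.random() < 0.4
        p_exp = p_exposed + (0.3 if confounded and serious else 0.0)
        exposed = rng.random() < p_exp
        p_out = p_outcome_exposed if exposed else p_outcome_unexposed
        if confounded and serious:
            p_out += 0.2
        outcome = rng.random() < min(p_out, 0.95)
        events = (("aeX", 1),) if outcome else (("aeOther", 2),)
        drug = "drugA" if exposed else "drugB"
        reports.append(
            make_report(f"c{i}", year=2010 + int(rng.random() * 3),
                        drugs=((drug, "suspected"),), events=events,
                        serious=serious)
        )
    return ReportSet(reports, study_drug="drugA", comparator_drugs=["drugB"])


class TestAdjustedRor:
    def test_no_covariates_equals_crude(self):
        rng = np.random.default_rng(0)
        rs = _two_arm_reports(rng, 600, 0.5, 0.3, 0.15)
        from pvsignal.core import contingency_table

        crude = crude_ror(contingency_table(rs, "drugA", "aeX"))
        adj = adjusted_ror(rs, "drugA", "aeX", covariates=[])
        assert adj.estimate == pytest.approx(crude.estimate, abs=1e-6)
        assert adj.ci_low == pytest.approx(crude.ci_low, abs=1e-4)
        assert adj.ci_high == pytest.approx(crude.ci_high, abs=1e-4)
        assert adj.adjusted is False

    def test_null_confounder_leaves_estimate(self):
        rng = np.random.default_rng(1)
        rs = _two_arm_reports(rng, 4000, 0.5, 0.3, 0.15)
        crude = adjusted_ror(rs, "drugA", "aeX", covariates=[])
        adj = adjusted_ror(rs, "drugA", "aeX", covariates=["gender"])
        assert adj.estimate == pytest.approx(crude.estimate, rel=0.05)
        assert adj.covariates_used == ("gender",)

    def test_confounder_adjustment_moves_toward_conditional_or(self):
        # seriousness raises both exposure and outcome probability, so the
        # crude ROR overstates the within-stratum odds ratio
        closer = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            rs = _two_arm_reports(rng, 4000, 0.35, 0.25, 0.12, confounded=True)
            crude = adjusted_ror(rs, "drugA", "aeX", covariates=[])
            adj = adjusted_ror(rs, "drugA", "aeX", covariates=["serious"])
            conditional = _conditional_or(rs)
            closer += int(
                abs(np.log(adj.estimate) - np.log(conditional))
                < abs(np.log(crude.estimate) - np.log(conditional))
            )
        assert closer >= 4

    def test_constant_outcome_rejected(self):
        rs = ReportSet(
            [make_report(f"c{i}", drugs=(("drugA", "suspected"),)) for i in range(4)],
            study_drug="drugA",
        )
        with pytest.raises(ValueError, match="does not vary"):
            adjusted_ror(rs, "drugA", "aeX", covariates=[])

    def test_separation_surfaced_with_cells(self):
        # exposure perfectly predicts the outcome
        reports = [
            make_report(f"a{i}", drugs=(("drugA", "suspected"),),
                        events=(("aeX", 1),))
            for i in range(12)
        ] + [
            make_report(f"b{i}", drugs=(("drugB", "suspected"),),
                        events=(("aeOther", 2),))
            for i in range(12)
        ]
        rs = ReportSet(reports, study_drug="drugA", comparator_drugs=["drugB"])
        with pytest.raises(SeparationError, match="n11"):
            adjusted_ror(rs, "drugA", "aeX", covariates=[])


def _conditional_or(rs) -> float:
    """Mantel-Haenszel odds ratio across the seriousness strata."""
    num = den = 0.0
    for stratum in (True, False):
        sub = [r for r in rs.reports if r.serious is stratum]
        n = len(sub)
        a = sum("drugA" in r.suspected_drugs and "aeX" in r.ae_terms for r in sub)
        b = sum("drugA" in r.suspected_drugs and "aeX" not in r.ae_terms for r in sub)
        c = sum("drugA" not in r.suspected_drugs and "aeX" in r.ae_terms for r in sub)
        d = n - a - b - c
        num += a * d / n
        den += b * c / n
    return num / den


class TestInformationComponent:
    def test_zero_at_exact_independence(self):
        assert information_component(ContingencyTable(10, 90, 90, 810)) == pytest.approx(0.0)

    def test_worked_table_equals_one(self):
        assert information_component(ContingencyTable(20, 80, 80, 820)) == pytest.approx(1.0)

    def test_scale_invariance(self):
        a = information_component(ContingencyTable(7, 13, 21, 59))
        b = information_component(ContingencyTable(14, 26, 42, 118))
        assert a == pytest.approx(b)

    def test_undefined_without_joint_reports(self):
        with pytest.raises(ValueError, match="n11"):
            information_component(ContingencyTable(0, 10, 10, 100))

    @given(
        st.tuples(st.integers(1, 12), st.integers(0, 12),
                  st.integers(0, 12), st.integers(0, 12))
    )
    @settings(max_examples=300, deadline=None)
    def test_sign_matches_margin_inequality(self, cells):
        ct = ContingencyTable(*cells)
        ic = information_component(ct)
        lhs = ct.n11 * ct.N
        rhs = (ct.n11 + ct.n10) * (ct.n11 + ct.n01)
        if lhs > rhs:
            assert ic > 0
        elif lhs < rhs:
            assert ic < 0
        else:
            assert ic == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_n11(self):
        values = [
            information_component(ContingencyTable(n11, 30, 20, 50))
            for n11 in range(1, 15)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestIcCredibleBounds:
    def test_seeded_determinism(self):
        ct = ContingencyTable(12, 40, 33, 500)
        a = ic_credible_bounds(ct, seed=9)
        b = ic_credible_bounds(ct, seed=9)
        assert (a.ic025, a.ic05) == (b.ic025, b.ic05)

    def test_quantile_ordering(self):
        for seed in range(10):
            res = ic_credible_bounds(ContingencyTable(8, 30, 25, 200), seed=seed)
            assert res.ic025 <= res.ic05 <= res.ic

    def test_independent_table_lower_bound_below_zero(self):
        for seed in range(10):
            res = ic_credible_bounds(ContingencyTable(10, 90, 90, 810), seed=seed)
            assert res.ic025 < 0

    def test_concentration_with_cell_scaling(self):
        small = ic_credible_bounds(ContingencyTable(5, 20, 15, 100), seed=1)
        big = ic_credible_bounds(ContingencyTable(500, 2000, 1500, 10000), seed=1)
        assert (big.ic05 - big.ic025) < (small.ic05 - small.ic025)
        # bounds approach the plug-in IC as information accumulates
        assert abs(big.ic025 - big.ic) < abs(small.ic025 - small.ic)

    def test_posterior_concentrates_on_plug_in(self):
        base = (2, 8, 8, 82)
        scaled = ContingencyTable(*(c * 10_000 for c in base))
        res = ic_credible_bounds(scaled, n_samples=20_000, seed=2)
        posterior_mean_proxy = (res.ic025 + res.ic05) / 2
        assert posterior_mean_proxy == pytest.approx(res.ic, abs=0.05)

    def test_normal_backend_agrees_with_monte_carlo_on_large_table(self):
        # the classical variance formula is slightly conservative, so the
        # backends agree loosely, with the normal bound sitting lower
        ct = ContingencyTable(200, 800, 700, 9000)
        mc = ic_credible_bounds(ct, seed=3)
        approx = ic_credible_bounds(ct, backend="normal")
        assert approx.ic025 == pytest.approx(mc.ic025, abs=0.15)
        assert approx.ic025 <= mc.ic025 + 0.01
        assert approx.ic025 < approx.ic05 < mc.ic

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            ic_credible_bounds(ContingencyTable(1, 1, 1, 1), levels=(1.5,))

    def test_low_sample_count_warns(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="pvsignal"):
            ic_credible_bounds(ContingencyTable(1, 1, 1, 1), n_samples=100)
        assert any("n_samples" in m for m in caplog.messages)

    def test_null_coverage_of_lower_bound(self):
        # independent tables with fixed margins: ic025 should rarely exceed 0
        rng = np.random.default_rng(42)
        n, px, py = 600, 0.2, 0.15
        exceed = 0
        trials = 300
        for i in range(trials):
            x = rng.random(n) < px
            y = rng.random(n) < py
            ct = ContingencyTable(
                int((x & y).sum()), int((x & ~y).sum()),
                int((~x & y).sum()), int((~x & ~y).sum()),
            )
            res = ic_credible_bounds(ct, n_samples=4000, seed=i)
            exceed += int(res.ic025 > 0)
        assert exceed / trials <= 0.06


class TestFlags:
    @pytest.mark.parametrize(
        "ror025, expected", [(2.79, True), (0.64, False), (1.0, False)]
    )
    def test_ror_rule_is_strict(self, ror025, expected):
        res = RorResult(estimate=max(ror025, 1.01) + 1, ci_low=ror025,
                        ci_high=99.0, adjusted=True)
        assert signal_flag_ror(res) is expected

    @pytest.mark.parametrize(
        "bound, expected", [(0.62, True), (-0.33, False), (0.0, False)]
    )
    def test_ic_rule_is_strict(self, bound, expected):
        assert signal_flag_ic(bound) is expected

    def test_nan_bound_never_flags(self):
        assert signal_flag_ic(float("nan")) is False
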