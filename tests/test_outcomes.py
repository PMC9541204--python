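"""Valuation: discounting, half-cycle correction, incremental metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sunbedban import ArmResult, discount_factor, evaluate, incremental, value_trace
from sunbedban.markov import THICK_TUNNEL_FIRST, THIN, run_cohort
from sunbedban.outcomes import combine_results, results_table

from conftest import build_tables


class TestDiscountFactor:
    @pytest.mark.parametrize(
        "cycle,rate,expected",
        [(0, 0.035, 1.0), (5, 0.0, 1.0), (1, 0.035, 1 / 1.035)],
    )
    def test_values(self, cycle, rate, expected):
        assert discount_factor(cycle, rate) == pytest.approx(expected)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(1, -0.01)


class TestValueTrace:
    def test_riskless_cohort_matches_norm_sum(self, params, tables):
        """With every risk at zero, QALYs equal the discounted,
        half-cycle-corrected sum of the age norms for the whole cohort."""
        t = build_tables(params, norm=tables.eq5d_norm["female"])
        trace = run_cohort("female", "status_quo", t, params)
        result = value_trace(trace, "female", t, params)
        disc = discount_factor(np.arange(params.n_cycles + 1), params.discount_rate)
        u = tables.eq5d_norm["female"][: params.n_cycles + 1] * disc
        per_person = float(np.sum(0.5 * (u[:-1] + u[1:])))
        scale = params.cohort_n * (1 - params.prop_male)
        assert result.total_cost == 0.0
        assert result.total_qalys == pytest.approx(per_person * scale, rel=1e-12)

    def test_thick_diagnosis_cost_undiscounted_at_cycle_zero(self, params, tables):
        trace = run_cohort("female", "status_quo", tables, params)
        unit = trace.__class__(
            sex="female",
            arm="status_quo",
            ages=trace.ages,
            occupancy=np.zeros_like(trace.occupancy),
            thin_incidence=np.zeros_like(trace.thin_incidence),
            thick_incidence=np.eye(1, params.n_cycles)[0],
            kc_incidence=np.zeros_like(trace.kc_incidence),
            melanoma_deaths=np.zeros_like(trace.melanoma_deaths),
            kc_rate=np.zeros_like(trace.kc_rate),
        )
        result = value_trace(unit, "female", tables, params, scale=1.0)
        assert result.total_cost == pytest.approx(3182.0)

    def test_larger_decrement_only_when_melanoma_and_kc_coincide(self, params):
        """A thick-melanoma cycle with a certain KC takes the 0.837
        multiplier, not 0.837 x 0.93."""
        t = build_tables(params, norm=1.0)
        n = params.n_cycles
        occupancy = np.zeros((n + 1, 16))
        occupancy[:, THICK_TUNNEL_FIRST] = 1.0
        trace_kwargs = dict(
            sex="female",
            arm="status_quo",
            ages=t.ages,
            occupancy=occupancy,
            thin_incidence=np.zeros(n),
            thick_incidence=np.zeros(n),
            kc_incidence=np.zeros(n),
            melanoma_deaths=np.zeros(n),
        )
        from sunbedban.markov import CohortTrace

        with_kc = value_trace(
            CohortTrace(**trace_kwargs, kc_rate=np.ones(n)),
            "female", t, params, scale=1.0,
        )
        without_kc = value_trace(
            CohortTrace(**trace_kwargs, kc_rate=np.zeros(n)),
            "female", t, params, scale=1.0,
        )
        # KC exposure changes nothing in a state already carrying the larger
        # melanoma decrement, except the final cycle which draws no KC
        assert with_kc.total_qalys == pytest.approx(without_kc.total_qalys, rel=1e-12)

    def test_kc_decrement_applies_in_lesion_free_state(self, params):
        t = build_tables(params, norm=1.0)
        n = params.n_cycles
        occupancy = np.zeros((n + 1, 16))
        occupancy[:, 0] = 1.0
        from sunbedban.markov import CohortTrace

        kwargs = dict(
            sex="female", arm="status_quo", ages=t.ages, occupancy=occupancy,
            thin_incidence=np.zeros(n), thick_incidence=np.zeros(n),
            kc_incidence=np.zeros(n), melanoma_deaths=np.zeros(n),
        )
        with_kc = value_trace(CohortTrace(**kwargs, kc_rate=np.full(n, 0.5)),
                              "female", t, params, scale=1.0)
        plain = value_trace(CohortTrace(**kwargs, kc_rate=np.zeros(n)),
                            "female", t, params, scale=1.0)
        assert with_kc.total_qalys < plain.total_qalys


class TestIncremental:
    def test_published_dominance_arithmetic(self):
        """The printed incremental row yields dominance with NHB ~ 530 QALYs."""
        comparator = ArmResult(41_618_865, 13_619_953, 0, 0, 0)
        intervention = ArmResult(41_618_865 - 657_858, 13_619_953 + 497, 0, 0, 0)
        inc = incremental(intervention, comparator, 20_000)
        assert inc.dominant and inc.icer is None
        assert inc.nhb == pytest.approx(529.9, abs=0.05)
        assert round(inc.nhb) == 530

    def test_plain_icer(self):
        inc = incremental(ArmResult(10_000, 2, 0, 0, 0), ArmResult(0, 0, 0, 0, 0), 20_000)
        assert inc.icer == pytest.approx(5000)
        assert not inc.dominant

    def test_zero_qaly_difference_undefined(self):
        inc = incremental(ArmResult(500, 1, 0, 0, 0), ArmResult(0, 1, 0, 0, 0), 20_000)
        assert inc.icer is None and not inc.dominant and not inc.dominated

    @given(
        dc=st.floats(-1e7, 1e7),
        dq=st.floats(-1e4, 1e4),
        threshold=st.floats(1e3, 1e5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_nmb_equals_threshold_times_nhb(self, dc, dq, threshold):
        inc = incremental(
            ArmResult(1e6 + dc, 2e4 + max(dq, -1e4), 0, 0, 0),
            ArmResult(1e6, 2e4, 0, 0, 0),
            threshold,
        )
        assert inc.nmb == pytest.approx(threshold * inc.nhb, rel=1e-6, abs=1e-6)


class TestArmArithmetic:
    def test_identical_arms_yield_zero_increments(self, params, tables):
        """No ban effect and no campaign cost: the strategies coincide."""
        null = params.model_copy(
            update={"cost_campaign": 0.0, "post_ban_use": 1.0, "uptake_rate_initial": 0.0}
        )
        result = evaluate(null, tables)
        assert result.incremental.delta_cost == pytest.approx(0.0, abs=1e-6)
        assert result.incremental.delta_qalys == pytest.approx(0.0, abs=1e-9)

    def test_campaign_cost_linearity(self, params, tables):
        base = evaluate(params, tables).incremental
        bumped = evaluate(
            params.model_copy(update={"cost_campaign": params.cost_campaign + 123_456}),
            tables,
        ).incremental
        assert bumped.delta_cost - base.delta_cost == pytest.approx(123_456, abs=1e-4)
        assert base.nmb - bumped.nmb == pytest.approx(123_456, abs=1e-4)

    def test_results_table_contains_footnote_metrics(self, params, tables):
        result = evaluate(params, tables)
        table = results_table(result.status_quo, result.ban, result.incremental)
        rows = set(table["estimate"])
        assert {"net_health_benefit_qalys", "incremental_net_benefit_gbp"} <= rows
        combined = combine_results([result.status_quo], campaign_cost=10.0)
        assert combined.total_cost == pytest.approx(result.status_quo.total_cost + 10.0)
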