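"""Strategy summaries, ICER arithmetic, dominance frontier, WTP decisions.

The frontier is checked against a brute-force oracle: a strategy belongs
to the efficient frontier iff it yields the most QALYs among strategies
within some budget, and lies on the upper-left convex hull of the
cost-effect cloud.
"""

import itertools

import numpy as np
import pytest

import sibscreen as sb
from sibscreen.cea import CEAEntry, DominantComparatorError, UndefinedICERError


def make_summary(label, cost, qalys, perspective):
    return sb.StrategySummary(
        strategy=sb.Strategy(label) if label in ("status_quo", "treat_all")
        else sb.Strategy(label, 0.8, 0.9),
        perspective=perspective,
        expected_cost=cost,
        expected_qalys=qalys,
        id_prevalence=0.04,
    )


def brute_force_frontier(points):
    """Indices of non-dominated points on the efficient (convex-hull) frontier."""
    n = len(points)
    strong = set()
    for i, (ci, ei) in enumerate(points):
        for j, (cj, ej) in enumerate(points):
            if i == j:
                continue
            if cj <= ci and ej >= ei and (cj < ci or ej > ei):
                strong.add(i)
                break
            if j < i and cj == ci and ej == ei:
                strong.add(i)
                break
    surviving = [i for i in range(n) if i not in strong]
    # extended dominance: a point off the upper-left convex hull is beaten by
    # the exact mixture of two others achieving its QALYs at no more cost
    extended = set()
    for i in surviving:
        ci, ei = points[i]
        for a, b in itertools.combinations([j for j in surviving if j != i], 2):
            (ca, ea), (cb, eb) = points[a], points[b]
            lo, hi = sorted(((ca, ea), (cb, eb)), key=lambda p: p[1])
            if not lo[1] <= ei <= hi[1] or lo[1] == hi[1]:
                continue
            lam = (hi[1] - ei) / (hi[1] - lo[1])
            cm = lam * lo[0] + (1 - lam) * hi[0]
            if cm <= ci:
                extended.add(i)
                break
    return [i for i in surviving if i not in extended]


class TestSummaries:
    def test_summary_decomposes_into_mixture_and_payoffs(
        self, base_params, life_table, societal, strategies
    ):
        s = strategies["test_treat_6"]
        summary = sb.summarize_strategy(s, base_params, life_table, societal)
        mix = sb.outcome_mixture(s, base_params)
        cost = sb.expected_upfront_cost(s, base_params, societal)
        qalys = 0.0
        for cls in ("non_asd", "asd_only", "asd_id"):
            payoff = sb.markov_payoff(cls, base_params, life_table, societal)
            cost += mix.fraction(cls) * payoff.discounted_cost
            qalys += mix.fraction(cls) * payoff.discounted_qalys
        assert summary.expected_cost == pytest.approx(cost, rel=1e-12)
        assert summary.expected_qalys == pytest.approx(qalys, rel=1e-12)

    def test_no_disease_equalises_effectiveness(self, base_params, life_table, societal):
        p = base_params.replace(prevalence_asd=0.0)
        summaries = sb.summarize_all(p, life_table, societal)
        qalys = {s.label: s.expected_qalys for s in summaries}
        assert len(set(qalys.values())) == 1
        costs = {s.label: s.expected_cost for s in summaries}
        assert costs["status_quo"] == 0.0
        assert costs["treat_all"] == pytest.approx(p.cost_ei)

    def test_qaly_ordering_matches_reported_ranking(self, base_params, life_table, societal):
        summaries = {s.label: s for s in sb.summarize_all(base_params, life_table, societal)}
        assert (
            summaries["status_quo"].expected_qalys
            < summaries["test_treat_6"].expected_qalys
            < summaries["test_treat_12"].expected_qalys
            < summaries["treat_all"].expected_qalys
        )

    def test_perspective_cost_ordering(self, base_params, life_table, config):
        for label in ("status_quo", "test_treat_6", "test_treat_12", "treat_all"):
            costs = [
                next(
                    s
                    for s in sb.summarize_all(base_params, life_table, config.perspective(persp))
                    if s.label == label
                ).expected_cost
                for persp in ("societal", "health_care", "educational")
            ]
            assert costs[0] >= costs[1] >= costs[2]


class TestIcer:
    def test_reported_societal_cells(self, societal):
        # lifetime cost / QALY cells as printed for the 6-month strategy vs
        # the status quo; display-rounded inputs give 49,331.9
        low = make_summary("status_quo", 294586.0, 27.0084, societal)
        high = make_summary("test_treat_6", 296949.0, 27.0563, societal)
        value = sb.icer(high, low)
        assert value == pytest.approx(49331.9, abs=0.5)
        assert abs(value - 49331.0) < 5.0

    def test_zero_incremental_cost(self, societal):
        a = make_summary("status_quo", 1000.0, 10.0, societal)
        b = make_summary("treat_all", 1000.0, 11.0, societal)
        assert sb.icer(b, a) == 0.0

    def test_identical_summaries_undefined(self, societal):
        a = make_summary("status_quo", 1000.0, 10.0, societal)
        with pytest.raises(UndefinedICERError):
            sb.icer(a, a)

    def test_dominant_comparator_flagged(self, societal):
        a = make_summary("status_quo", 1000.0, 10.0, societal)
        b = make_summary("treat_all", 900.0, 11.0, societal)
        with pytest.raises(DominantComparatorError):
            sb.icer(b, a)

    def test_mixed_perspectives_rejected(self, config):
        a = make_summary("status_quo", 1000.0, 10.0, config.perspective("societal"))
        b = make_summary("treat_all", 2000.0, 11.0, config.perspective("educational"))
        with pytest.raises(sb.ValidationError, match="perspective"):
            sb.icer(b, a)


class TestFrontier:
    def test_constructed_strong_dominance(self, societal):
        a = make_summary("status_quo", 100.0, 10.0, societal)
        b = make_summary("treat_all", 200.0, 9.0, societal)
        result = sb.frontier([a, b])
        assert result.entry("treat_all").dominance == "strong"
        assert result.entry("status_quo").dominance == "none"

    def test_constructed_extended_dominance(self, societal):
        a = make_summary("status_quo", 0.0, 10.0, societal)
        b = make_summary("test_treat_6", 1000.0, 10.1, societal)  # ICER 10,000
        c = make_summary("treat_all", 1100.0, 10.3, societal)  # ICER vs a ~3,667
        result = sb.frontier([a, b, c])
        assert result.entry("test_treat_6").dominance == "extended"

    def test_base_case_has_no_dominated_strategy(self, base_params, life_table, societal):
        result = sb.frontier(sb.summarize_all(base_params, life_table, societal))
        assert all(e.dominance == "none" for e in result.entries)

    def test_frontier_icers_strictly_increase(self, base_params, life_table, societal):
        result = sb.frontier(sb.summarize_all(base_params, life_table, societal))
        icers = [e.icer for e in result.nondominated if e.icer is not None]
        assert all(a < b for a, b in zip(icers, icers[1:]))

    def test_matches_brute_force_on_random_sets(self, societal):
        rng = np.random.default_rng(2718)
        for _ in range(300):
            points = list(zip(rng.uniform(0, 1e5, 4), rng.uniform(20, 30, 4)))
            labels = ["status_quo", "test_treat_6", "test_treat_12", "treat_all"]
            summaries = [
                make_summary(lbl, c, e, societal) for lbl, (c, e) in zip(labels, points)
            ]
            result = sb.frontier(summaries)
            got = sorted(e.label for e in result.nondominated)
            expected = sorted(labels[i] for i in brute_force_frontier(points))
            assert got == expected, points

    def test_invariant_to_input_order_and_duplicates(self, societal):
        a = make_summary("status_quo", 0.0, 10.0, societal)
        b = make_summary("test_treat_6", 5000.0, 10.05, societal)
        dominated = make_summary("treat_all", 9000.0, 9.5, societal)
        reference = {e.label: e.dominance for e in sb.frontier([a, b, dominated]).entries}
        for perm in itertools.permutations([a, b, dominated]):
            got = {e.label: e.dominance for e in sb.frontier(list(perm)).entries}
            assert got == reference
        with_dup = sb.frontier([a, b, dominated, dominated])
        assert {e.label for e in with_dup.nondominated} == {"status_quo", "test_treat_6"}


class TestCommonBaseline:
    def test_reported_12_month_cells(self, societal):
        base = make_summary("status_quo", 294586.0, 27.0084, societal)
        twelve = make_summary("test_treat_12", 303294.0, 27.0598, societal)
        got = sb.common_baseline_icers([base, twelve], base)
        # rounded printed inputs give 169,416; the published 169,435 used
        # unrounded internals
        assert got["test_treat_12"] == pytest.approx(169416.34, abs=0.5)
        assert abs(got["test_treat_12"] - 169435.0) < 25.0

    def test_baseline_skipped(self, societal):
        base = make_summary("status_quo", 100.0, 10.0, societal)
        other = make_summary("treat_all", 200.0, 11.0, societal)
        assert "status_quo" not in sb.common_baseline_icers([base, other], base)

    def test_cheapest_frontier_step_below_common_baseline_of_later(self, societal):
        rng = np.random.default_rng(31415)
        labels = ["status_quo", "test_treat_6", "test_treat_12", "treat_all"]
        for _ in range(200):
            costs = np.sort(rng.uniform(0, 1e5, 4))
            effects = np.sort(rng.uniform(20, 30, 4))
            summaries = [
                make_summary(lbl, c, e, societal)
                for lbl, c, e in zip(labels, costs, effects)
            ]
            result = sb.frontier(summaries)
            nd = result.nondominated
            if len(nd) < 2:
                continue
            first_step = nd[1]
            assert first_step.icer <= first_step.common_baseline_icer + 1e-9 or len(nd) == 2


class TestOptimalStrategy:
    def test_zero_wtp_picks_least_costly(self, base_params, life_table, societal):
        result = sb.frontier(sb.summarize_all(base_params, life_table, societal))
        assert sb.optimal_strategy(result, 0.0).label == "status_quo"

    def test_unbounded_wtp_picks_most_effective(self, base_params, life_table, societal):
        result = sb.frontier(sb.summarize_all(base_params, life_table, societal))
        assert sb.optimal_strategy(result, np.inf).label == "treat_all"

    @pytest.mark.parametrize("wtp", [50000.0, 100000.0])
    def test_reported_thresholds_select_6_month_screening(
        self, base_params, life_table, societal, wtp
    ):
        result = sb.frontier(sb.summarize_all(base_params, life_table, societal))
        assert sb.optimal_strategy(result, wtp).label == "test_treat_6"

    def test_maximises_net_monetary_benefit(self, societal):
        rng = np.random.default_rng(97)
        labels = ["status_quo", "test_treat_6", "test_treat_12", "treat_all"]
        for _ in range(200):
            summaries = [
                make_summary(lbl, c, e, societal)
                for lbl, c, e in zip(labels, rng.uniform(0, 1e5, 4), rng.uniform(20, 30, 4))
            ]
            result = sb.frontier(summaries)
            for wtp in (0.0, 25000.0, 75000.0, 1e6):
                chosen = sb.optimal_strategy(result, wtp)
                nmbs = {
                    e.label: sb.net_monetary_benefit(e.summary, wtp)
                    for e in result.nondominated
                }
                assert nmbs[chosen.label] == pytest.approx(max(nmbs.values()), abs=1e-6)


class TestResultsTable:
    def test_reported_rounding(self, base_params, life_table, societal):
        table = sb.results_table(sb.frontier(sb.summarize_all(base_params, life_table, societal)))
        sq = table[table.strategy == "status_quo"].iloc[0]
        assert sq.id_prevalence == 0.0421
        assert sq.id_relative_risk == 1.0
        assert float(sq.lifetime_cost) == int(sq.lifetime_cost)
        assert list(table.strategy) == [
            "status_quo",
            "test_treat_6",
            "test_treat_12",
            "treat_all",
        ]
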