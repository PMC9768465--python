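"""Distribution summaries: quartiles, cumulative curves, bootstrap, Spearman."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corrlit import (
    GeneratorConfig,
    Location,
    RecordSet,
    SigLabel,
    StatRecord,
    bootstrap_median_ci,
    cumulative_percentiles_by_max_df,
    generate_records,
    percentile_summary,
    rolling_group_medians,
    spearman_r_vs_df_by_year,
    stratified_summary,
)


def records_from(abs_r_df_pairs, **kwargs):
    return RecordSet(
        records=[
            StatRecord(record_id=f"rec{i}", r=r, df=df, **kwargs)
            for i, (r, df) in enumerate(abs_r_df_pairs)
        ]
    )


class TestPercentileSummary:
    def test_hand_interpolation(self):
        # positions 1 + (n-1)p = 1.5, 2, 2.5 over [0.1, 0.2, 0.3]
        summary = percentile_summary([0.1, 0.2, 0.3])
        assert (summary.q25, summary.q50, summary.q75) == pytest.approx((0.15, 0.20, 0.25))

    def test_constant_input(self):
        summary = percentile_summary([0.4] * 10)
        assert (summary.q25, summary.q50, summary.q75) == (0.4, 0.4, 0.4)

    def test_empty_gives_marker_not_nan(self):
        summary = percentile_summary([])
        assert summary.is_empty
        assert summary.q50 is None

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40), st.randoms())
    def test_order_invariance(self, values, rnd):
        base = percentile_summary(values)
        shuffled = list(values)
        rnd.shuffle(shuffled)
        assert percentile_summary(shuffled) == base


class TestCumulativeCurve:
    def test_single_df_equals_overall(self):
        rs = records_from([(0.1, 20), (0.3, 20), (0.5, 20)])
        curve = cumulative_percentiles_by_max_df(rs)
        assert len(curve) == 1
        overall = percentile_summary([0.1, 0.3, 0.5])
        assert curve.rows[0] == (20, 3, overall.q25, overall.q50, overall.q75)

    def test_last_row_equals_overall_summary(self, small_literature):
        record_set, _ = small_literature
        curve = cumulative_percentiles_by_max_df(record_set)
        overall = percentile_summary(record_set.abs_r_values())
        df_max, n, q25, q50, q75 = curve.rows[-1]
        assert n == len(record_set)  # every generated record carries df
        assert (q25, q50, q75) == pytest.approx((overall.q25, overall.q50, overall.q75))

    def test_agrees_with_brute_force_oracle(self, small_literature):
        record_set, _ = small_literature
        curve = cumulative_percentiles_by_max_df(record_set)
        pairs = [(rec.effective_df(), rec.abs_r) for rec in record_set]
        for df_max, n, q25, q50, q75 in curve.rows[:: max(1, len(curve) // 15)]:
            included = sorted(r for d, r in pairs if d <= df_max)
            assert n == len(included)
            expect = np.quantile(included, [0.25, 0.5, 0.75])
            assert (q25, q50, q75) == pytest.approx(tuple(expect))

    def test_df_strictly_increasing_and_counts_nondecreasing(self, small_literature):
        curve = cumulative_percentiles_by_max_df(small_literature[0])
        dfs = [row[0] for row in curve.rows]
        ns = [row[1] for row in curve.rows]
        assert dfs == sorted(set(dfs))
        assert ns == sorted(ns)

    def test_records_without_df_excluded(self):
        rs = RecordSet(records=[StatRecord(record_id="a", r=0.5)])
        assert len(cumulative_percentiles_by_max_df(rs)) == 0


class TestRollingGroupMedians:
    def test_single_block(self):
        rs = records_from([(0.1 * i % 0.9 + 0.05, 10 + i) for i in range(10)])
        points = rolling_group_medians(rs, group_size=10)
        assert len(points) == 1
        assert points[0][1] == pytest.approx(np.median(rs.abs_r_values()))

    def test_partition_arithmetic(self):
        rs = records_from([(0.2, 10 + i) for i in range(25)])
        assert len(rolling_group_medians(rs, group_size=10)) == 3

    def test_medians_decline_on_significance_selected_data(self):
        cfg = GeneratorConfig(n_studies=150, seed=31)
        record_set, _ = generate_records(cfg)
        selected = RecordSet(
            records=[r for r in record_set if r.sig_label is SigLabel.SIGNIFICANT]
        )
        points = rolling_group_medians(selected, group_size=len(selected) // 4)
        assert points[-1][1] < points[0][1]


class TestBootstrapMedianCI:
    def test_constant_data_zero_width(self):
        ci = bootstrap_median_ci([0.3] * 20, reps=2000, seed=1)
        assert ci.estimate == 0.3
        assert ci.upper - ci.lower == pytest.approx(0.0, abs=1e-12)

    def test_deterministic_given_seed(self):
        values = list(np.random.default_rng(0).normal(size=50))
        a = bootstrap_median_ci(values, reps=3000, seed=42)
        b = bootstrap_median_ci(values, reps=3000, seed=42)
        assert (a.lower, a.upper) == (b.lower, b.upper)

    def test_interval_brackets_estimate_for_symmetric_data(self):
        values = list(np.random.default_rng(1).normal(size=200))
        ci = bootstrap_median_ci(values, reps=5000, seed=2)
        assert ci.lower < ci.estimate < ci.upper

    def test_width_shrinks_like_root_n(self):
        # widths averaged over replicate samples: one sample's width is noisy
        rng = np.random.default_rng(3)
        widths = {}
        for n in (100, 400, 1600):
            ws = [
                (ci := bootstrap_median_ci(rng.normal(size=n), reps=2000, seed=4 + i)).upper
                - ci.lower
                for i in range(25)
            ]
            widths[n] = np.mean(ws)
        assert widths[100] / widths[400] == pytest.approx(2.0, rel=0.15)
        assert widths[400] / widths[1600] == pytest.approx(2.0, rel=0.15)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            bootstrap_median_ci([0.1], reps=1000)


class TestSpearmanByYear:
    def test_perfectly_decreasing_gives_minus_one(self):
        rs = records_from(
            [(0.9 - 0.05 * i, 10 + i) for i in range(15)], year=2010
        )
        (assoc,) = spearman_r_vs_df_by_year(rs)
        assert assoc.rho == pytest.approx(-1.0)

    def test_rank_invariance_under_monotone_df_transform(self):
        rng = np.random.default_rng(5)
        pairs = [(float(r), int(d)) for r, d in zip(rng.uniform(0, 1, 30), rng.integers(5, 500, 30))]
        rs1 = records_from(pairs, year=2015)
        rs2 = records_from([(r, d * 10 + 3) for r, d in pairs], year=2015)
        (a1,) = spearman_r_vs_df_by_year(rs1)
        (a2,) = spearman_r_vs_df_by_year(rs2)
        assert a1.rho == pytest.approx(a2.rho)

    def test_independent_data_null_distribution(self):
        # |rho| < 0.12 in >= 95% of simulations at n=300
        rng = np.random.default_rng(6)
        hits = 0
        sims = 200
        for _ in range(sims):
            rs = records_from(
                [(float(r), int(d)) for r, d in zip(rng.uniform(0, 1, 300), rng.integers(5, 2000, 300))],
                year=2012,
            )
            (assoc,) = spearman_r_vs_df_by_year(rs)
            hits += abs(assoc.rho) < 0.12
        assert hits / sims >= 0.95

    def test_small_years_emitted_without_rho(self):
        rs = records_from([(0.2, 10), (0.4, 30)], year=2011)
        (assoc,) = spearman_r_vs_df_by_year(rs)
        assert assoc.rho is None
        assert assoc.n_records_with_df == 2

    def test_ci_brackets_rho(self, small_literature):
        for assoc in spearman_r_vs_df_by_year(small_literature[0]):
            if assoc.rho is not None:
                assert assoc.ci_lower <= assoc.rho <= assoc.ci_upper


class TestStratifiedSummary:
    def test_trivial_stratification_equals_overall(self, small_literature):
        record_set, _ = small_literature
        summary = stratified_summary(record_set, ())
        assert list(summary) == ["all"]
        assert summary["all"]["abs_r"] == percentile_summary(record_set.abs_r_values(), "all")

    def test_counts_partition_record_set(self, small_literature):
        record_set, _ = small_literature
        summary = stratified_summary(record_set, ("sig_label", "location"))
        assert sum(block["n_records"] for block in summary.values()) == len(record_set)

    def test_emphasis_bias_raises_text_median(self):
        cfg = GeneratorConfig(n_studies=120, text_emphasis_odds=20.0, seed=17)
        record_set, _ = generate_records(cfg)
        summary = stratified_summary(record_set, ("location",))
        assert summary["location=TEXT"]["abs_r"].q50 > summary["location=TABLE"]["abs_r"].q50

    def test_unknown_stratum_field_rejected(self, small_literature):
        with pytest.raises(ValueError):
            stratified_summary(small_literature[0], ("nope",))
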