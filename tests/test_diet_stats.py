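import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rflp_diet.diet_stats import (
    DevianceRecord,
    PairedSample,
    SampleRecord,
    SpeciesTraits,
    build_paired_samples,
    faecal_deviance_table,
    mean_species_per_sample,
    paired_match_rates,
    pearson_chi_squared,
    proportion_summary,
    relative_difference,
    round_half_up,
    simple_linear_regression,
)


def record(i, stype="faecal", sex="female", amplified=True, identified=False,
           species=(), occasion=1, grasshopper=None, sequenced=False):
    return SampleRecord(
        f"s{i:04d}", grasshopper or f"g{i:04d}", "m01", occasion, stype, sex,
        amplified, identified, frozenset(species), sequenced,
    )


def success_failure_records(n_success, n_total, **kw):
    return [record(i, amplified=i < n_success, **kw) for i in range(n_total)]


class TestSampleRecord:
    def test_identified_requires_amplified(self):
        with pytest.raises(ValueError, match="identified"):
            record(1, amplified=False, identified=True)

    def test_species_requires_identified(self):
        with pytest.raises(ValueError, match="species"):
            record(1, identified=False, species={"A"})

    def test_bad_enum_values(self):
        with pytest.raises(ValueError):
            record(1, stype="gut")
        with pytest.raises(ValueError):
            record(1, sex="unknown")


class TestProportionSummary:
    def test_overall_66_percent(self):
        df = proportion_summary(success_failure_records(531, 801), "overall")
        (row,) = df.itertuples()
        assert (row.n_success, row.n_total) == (531, 801)
        assert round_half_up(100 * row.proportion) == 66

    def test_zero_of_ten(self):
        df = proportion_summary(success_failure_records(0, 10), "overall")
        (row,) = df.itertuples()
        assert row.proportion == 0.0
        assert row.ci_low == 0.0

    def test_wilson_interval_50_of_100(self):
        df = proportion_summary(success_failure_records(50, 100), "overall")
        (row,) = df.itertuples()
        # hand-computed Wilson bounds at z = 1.959964
        assert row.ci_low == pytest.approx(0.40383, abs=1e-4)
        assert row.ci_high == pytest.approx(0.59617, abs=1e-4)

    def test_grouping_and_empty_group_flagged(self):
        records = [record(i, stype="faecal", sex="female") for i in range(5)]
        df = proportion_summary(records, "both")
        assert len(df) == 4
        empty = df[(df.sample_type == "regurgitate")]
        assert empty.flagged.all()
        assert empty.proportion.isna().all()
        full = df[(df.sample_type == "faecal") & (df.sex == "female")]
        assert full.iloc[0].n_total == 5

    def test_callable_predicate(self):
        records = [record(i, identified=i % 2 == 0) for i in range(10)]
        df = proportion_summary(records, "overall", success=lambda r: r.identified)
        assert df.iloc[0].n_success == 5

    def test_wilson_ci_contains_estimate_and_stays_in_unit_interval(self):
        for n_succ, n_tot in [(0, 7), (3, 7), (7, 7), (1, 200)]:
            df = proportion_summary(success_failure_records(n_succ, n_tot), "overall")
            row = df.iloc[0]
            assert 0 <= row.ci_low <= row.proportion <= row.ci_high <= 1

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            proportion_summary([], "overall")


class TestRelativeDifference:
    @pytest.mark.parametrize("pa,pb,expect", [
        (0.773, 0.630, 23),
        (0.801, 0.431, 86),
        (0.630, 0.431, 46),
        (0.901, 0.829, 9),
    ])
    def test_printed_group_means(self, pa, pb, expect):
        assert relative_difference(pa, pb).rounded == expect

    def test_identity_is_zero(self):
        for x in (0.1, 0.5, 0.99):
            assert relative_difference(x, x).rounded == 0

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(0.5, 0.0)


class TestPairedMatchRates:
    @staticmethod
    def build_pairs(n_exact, n_partial_only, n_disjoint):
        pairs = []
        for i in range(n_exact):
            pairs.append(PairedSample(f"g{i}", 1, {"A"}, {"A"}))
        for i in range(n_partial_only):
            pairs.append(PairedSample(f"h{i}", 1, {"A", "B"}, {"B", "C"}))
        for i in range(n_disjoint):
            pairs.append(PairedSample(f"k{i}", 1, {"A"}, {"B"}))
        return pairs

    def test_study_counts(self):
        rates = paired_match_rates(self.build_pairs(56, 44, 36))
        assert (rates.n_pairs, rates.exact_count, rates.partial_count) == (136, 56, 100)
        assert (rates.exact_pct, rates.partial_pct) == (41, 74)

    def test_all_identical(self):
        rates = paired_match_rates(self.build_pairs(10, 0, 0))
        assert (rates.exact_pct, rates.partial_pct) == (100, 100)

    def test_overlap_is_partial_not_exact(self):
        rates = paired_match_rates([PairedSample("g", 1, {"A", "B"}, {"B", "C"})])
        assert (rates.exact_count, rates.partial_count) == (0, 1)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            PairedSample("g", 1, set(), {"A"})

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.tuples(st.sets(st.sampled_from("ABCD"), min_size=1),
                  st.sets(st.sampled_from("ABCD"), min_size=1)),
        min_size=1, max_size=30,
    ))
    def test_exact_le_partial_le_n(self, raw):
        pairs = [PairedSample(f"g{i}", 1, f, r) for i, (f, r) in enumerate(raw)]
        rates = paired_match_rates(pairs)
        assert rates.exact_count <= rates.partial_count <= rates.n_pairs


class TestBuildPairedSamples:
    def test_pairs_require_both_types_identified(self):
        records = [
            record(1, stype="faecal", identified=True, species={"A"},
                   grasshopper="g1", occasion=1),
            record(2, stype="regurgitate", identified=True, species={"A", "B"},
                   grasshopper="g1", occasion=1),
            record(3, stype="faecal", identified=True, species={"C"},
                   grasshopper="g2", occasion=1),  # no regurgitate partner
            record(4, stype="regurgitate", identified=True, species={"C"},
                   grasshopper="g3", occasion=2),  # no faecal partner
        ]
        (pair,) = build_paired_samples(records)
        assert pair.grasshopper_id == "g1"
        assert pair.faecal_set == {"A"}
        assert pair.regurgitate_set == {"A", "B"}


class TestMeanSpeciesPerSample:
    def test_study_distribution(self):
        assert mean_species_per_sample({1: 335, 2: 133, 3: 31, 4: 1}) == 1.40

    def test_all_singletons(self):
        assert mean_species_per_sample({1: 17}) == 1.00

    def test_symmetric(self):
        assert mean_species_per_sample({2: 5, 4: 5}) == 3.00

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_species_per_sample({})

    def test_zero_count_key_rejected(self):
        with pytest.raises(ValueError):
            mean_species_per_sample({0: 5})


class TestFaecalDevianceTable:
    @staticmethod
    def records_for(species_events):
        """species_events: {species: (n_faecal, n_regurgitate)}"""
        records = []
        i = 0
        for sid, (nf, nr) in species_events.items():
            for _ in range(nf):
                records.append(record(i, stype="faecal", identified=True, species={sid}))
                i += 1
            for _ in range(nr):
                records.append(record(i, stype="regurgitate", identified=True, species={sid}))
                i += 1
        return records

    def test_deviance_arithmetic(self):
        (row,) = faecal_deviance_table(self.records_for({"A": (8, 2)}), 0.66)
        assert row.observed_prop == pytest.approx(0.8)
        assert row.deviance == pytest.approx(0.14)
        assert row.ci_low <= row.observed_prop <= row.ci_high

    def test_min_samples_filter(self):
        rows = faecal_deviance_table(self.records_for({"A": (2, 2), "B": (4, 2)}), 0.66)
        assert [r.species_id for r in rows] == ["B"]

    def test_zero_deviance_at_expectation(self):
        (row,) = faecal_deviance_table(self.records_for({"A": (33, 17)}), 0.66)
        assert row.deviance == pytest.approx(0.0)

    def test_one_event_per_sample_species_pair(self):
        # two species in one sample give one event each
        records = [record(0, stype="faecal", identified=True, species={"A", "B"})]
        records += self.records_for({"A": (2, 2), "B": (2, 2)})
        rows = faecal_deviance_table(records, 0.66, min_samples=5)
        assert {r.species_id: r.n_total_ids for r in rows} == {"A": 5, "B": 5}


class TestPearsonChiSquared:
    def test_independence_is_zero(self):
        res = pearson_chi_squared([[10, 10], [10, 10]])
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 1

    def test_2x2_closed_form(self):
        res = pearson_chi_squared([[20, 10], [10, 20]])
        assert res.statistic == pytest.approx(6.667, abs=1e-3)
        assert res.df == 1

    def test_diagonal(self):
        res = pearson_chi_squared([[5, 0], [0, 5]])
        assert res.statistic == pytest.approx(10.0)
        assert res.df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi_squared([[0, 0], [5, 5]])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            pearson_chi_squared([[1, 2]])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 50, size=(3, 4))
        base = pearson_chi_squared(table).statistic
        assert pearson_chi_squared(table[::-1]).statistic == pytest.approx(base)
        assert pearson_chi_squared(table[:, ::-1]).statistic == pytest.approx(base)
        assert pearson_chi_squared(table.T).statistic == pytest.approx(base)


class TestSimpleLinearRegression:
    def test_exact_fit(self):
        fit = simple_linear_regression([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)

    def test_insufficient_n(self):
        with pytest.raises(ValueError, match="3"):
            simple_linear_regression([1, 0], [0, 1])

    def test_normal_equations_example(self):
        fit = simple_linear_regression([0, 2, 1, 3], [0, 1, 2, 3])
        assert fit.slope == pytest.approx(0.8)
        assert fit.intercept == pytest.approx(0.3)
        assert fit.n == 4

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            simple_linear_regression([1, 2, 3], [5, 5, 5])

    def test_t_statistic_definition(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=20)
        y = 2 * x + rng.normal(size=20)
        fit = simple_linear_regression(y, x)
        # recompute t from first principles
        xc = x - x.mean()
        slope = (xc @ y) / (xc @ xc)
        resid = y - (slope * x + (y.mean() - slope * x.mean()))
        se = math.sqrt((resid @ resid) / 18 / (xc @ xc))
        assert fit.slope_t == pytest.approx(slope / se)
        assert 0 <= fit.slope_p <= 1


class TestCoverageProperty:
    def test_wilson_coverage_on_synthetic_groups(self):
        # grouped estimates should cover the truth about 95% of the time
        rng = np.random.default_rng(42)
        probs = {("faecal", "female"): 0.773, ("regurgitate", "female"): 0.630,
                 ("faecal", "male"): 0.801, ("regurgitate", "male"): 0.431}
        n_per_group = 150
        hits = total = 0
        for _ in range(250):
            records = []
            i = 0
            for (stype, sex), p in probs.items():
                for _ in range(n_per_group):
                    records.append(record(i, stype=stype, sex=sex,
                                          amplified=bool(rng.random() < p)))
                    i += 1
            df = proportion_summary(records, "both")
            for row in df.itertuples():
                truth = probs[(row.sample_type, row.sex)]
                hits += row.ci_low <= truth <= row.ci_high
                total += 1
        assert hits / total >= 0.93
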