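"""Carrier-state categorization, Fisher tests, scans, cross-disorder, burden."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

from cnvassoc.association import (
    anova_scan,
    burden_analysis,
    categorize_states,
    cross_disorder_test,
    fisher_exact_carriers,
    fisher_locus_test,
    match_implicated_locus,
    mean_calls_per_sample,
)
from cnvassoc.types import (
    Ancestry,
    CNVCall,
    CNVRegion,
    Diagnosis,
    Direction,
    ImplicatedLocus,
    SampleRecord,
    SampleState,
    State,
    Tail,
)


def _samples(n, dx=Diagnosis.HC, prefix="s"):
    return [SampleRecord(f"{prefix}{i}", dx, Ancestry.EA, "b1", 0.1) for i in range(n)]


def _call(sid, start=100, end=199, cn=1, chrom="1"):
    return CNVCall(sid, chrom, start, end, cn, 10)


def _states(case_carriers, control_carriers, cases, controls, state=State.DELETION):
    out = [SampleState(s.sample_id, "r", state) for s in cases[:case_carriers]]
    out += [SampleState(s.sample_id, "r", state) for s in controls[:control_carriers]]
    return out


class TestCategorizeStates:
    def test_copy_number_trichotomy_and_default_normal(self):
        samples = _samples(3)
        cnvr = CNVRegion("r", "1", 100, 199,
                         member_calls=[_call("s0", cn=0), _call("s1", cn=4)])
        states = {s.sample_id: s.state for s in categorize_states(cnvr, samples)}
        assert states == {"s0": State.DELETION, "s1": State.DUPLICATION, "s2": State.NORMAL}

    def test_larger_overlap_wins_for_mixed_carriers(self):
        samples = _samples(1)
        cnvr = CNVRegion("r", "1", 1, 1000, member_calls=[
            _call("s0", start=1, end=800, cn=1),      # deletion over 80%
            _call("s0", start=900, end=1000, cn=3),   # duplication over 10%
        ])
        (s,) = categorize_states(cnvr, samples)
        assert s.state is State.DELETION

    def test_tie_goes_to_deletion(self):
        samples = _samples(1)
        cnvr = CNVRegion("r", "1", 1, 200, member_calls=[
            _call("s0", start=1, end=100, cn=3),
            _call("s0", start=101, end=200, cn=1),
        ])
        (s,) = categorize_states(cnvr, samples)
        assert s.state is State.DELETION

    def test_hand_assignment_on_six_sample_fixture(self):
        samples = _samples(6)
        cnvr = CNVRegion("r", "1", 100, 199, member_calls=[
            _call("s0", cn=0), _call("s1", cn=1), _call("s2", cn=3),
            _call("s3", cn=4),
        ])
        got = [int(s.state) for s in categorize_states(cnvr, samples)]
        assert got == [-1, -1, 1, 1, 0, 0]


class TestMatchImplicatedLocus:
    def _locus(self, start=0, end=999):
        return ImplicatedLocus("L", "1", max(start, 1), end, State.DELETION)

    def test_exactly_half_coverage_matches(self):
        locus = ImplicatedLocus("L", "1", 1, 1000, State.DELETION)
        cnvr = CNVRegion("r", "1", 501, 1500, member_calls=[_call("x", 501, 1500)])
        assert match_implicated_locus(locus, [cnvr]) is cnvr

    def test_no_overlapping_cnvr_returns_none(self):
        locus = ImplicatedLocus("L", "1", 1, 1000, State.DELETION)
        cnvr = CNVRegion("r", "2", 1, 1000, member_calls=[])
        assert match_implicated_locus(locus, [cnvr]) is None

    def test_best_match_equals_exhaustive_scan(self):
        rng = np.random.default_rng(0)
        locus = ImplicatedLocus("L", "1", 10_000, 20_000, State.DELETION)
        cnvrs = []
        for i in range(100):
            s = int(rng.integers(1, 30_000))
            cnvrs.append(CNVRegion(f"r{i}", "1", s, s + int(rng.integers(100, 15_000)), member_calls=[]))
        got = match_implicated_locus(locus, cnvrs)
        best, best_ov = None, -1
        for r in cnvrs:
            ov = min(r.end, locus.end) - max(r.start, locus.start) + 1
            if ov > 0 and ov / locus.length >= 0.5 and ov > best_ov:
                best, best_ov = r, ov
        assert got is best


class TestFisherExact:
    def test_published_scale_examples(self):
        # 16/2416 deletion carriers vs 0/2393, one-tailed
        p = fisher_exact_carriers(16, 0, 2416, 2393, "greater")
        assert f"{p:.2E}" == "1.61E-05"
        # 9/2416 duplication carriers vs 0/2393
        p = fisher_exact_carriers(9, 0, 2416, 2393, "greater")
        assert f"{p:.2E}" == "2.02E-03"

    def test_equals_exact_rational_enumeration(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n1, n2 = int(rng.integers(10, 500)), int(rng.integers(10, 500))
            K = int(rng.integers(1, 25))
            a = int(rng.integers(0, min(K, n1) + 1))
            b = K - a
            if b > n2:
                continue
            denom = sum(
                comb(n1, k) * comb(n2, K - k)
                for k in range(max(0, K - n2), min(K, n1) + 1)
            )
            exact_greater = Fraction(
                sum(
                    comb(n1, k) * comb(n2, K - k)
                    for k in range(a, min(K, n1) + 1)
                ),
                denom,
            )
            assert fisher_exact_carriers(a, b, n1, n2, "greater") == pytest.approx(
                float(exact_greater), rel=1e-14
            )

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n1, n2 = int(rng.integers(20, 300)), int(rng.integers(20, 300))
            a, b = int(rng.integers(0, 12)), int(rng.integers(0, 12))
            table = [[a, n1 - a], [b, n2 - b]]
            for alt, mine in (("greater", "greater"), ("two-sided", "two-sided")):
                _, p_ref = stats.fisher_exact(table, alternative=alt)
                assert fisher_exact_carriers(a, b, n1, n2, mine) == pytest.approx(
                    p_ref, rel=1e-8
                )

    def test_no_case_carriers_gives_p_one_for_enrichment(self):
        assert fisher_exact_carriers(0, 3, 100, 100, "greater") == 1.0

    def test_swap_rows_and_columns_leaves_p_invariant(self):
        # swapping both rows and columns maps (a, b | n1, n2) to (n1-a, n2-b)
        p1 = fisher_exact_carriers(4, 1, 50, 60, "two-sided")
        p2 = fisher_exact_carriers(50 - 4, 60 - 1, 50, 60, "two-sided")
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_two_tailed_at_least_one_tailed(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = int(rng.integers(0, 10)), int(rng.integers(0, 10))
            p1 = fisher_exact_carriers(a, b, 100, 120, "greater")
            p_less = fisher_exact_carriers(a, b, 100, 120, "less")
            p2 = fisher_exact_carriers(a, b, 100, 120, "two-sided")
            assert p2 >= min(p1, p_less) - 1e-15


class TestFisherLocusTest:
    def test_full_path_reproduces_candidate_locus_p(self):
        cases = _samples(2416, Diagnosis.SZ, "sz")
        controls = _samples(2393, Diagnosis.HC, "hc")
        states = _states(16, 0, cases, controls)
        res = fisher_locus_test(states, cases, controls, Tail.ONE, State.DELETION)
        assert f"{res.p_value:.2E}" == "1.61E-05"
        assert res.direction is Direction.CASE_ENRICHED
        assert res.case_frequency == pytest.approx(16 / 2416)

    def test_degenerate_margins(self):
        cases, controls = _samples(50, Diagnosis.SZ, "c"), _samples(50, Diagnosis.HC, "h")
        res = fisher_locus_test([], cases, controls)
        assert res.p_value == 1.0 and res.direction is Direction.NONE


class TestAnovaScan:
    def test_identical_distributions_are_null(self):
        cases = _samples(100, Diagnosis.SZ, "c")
        controls = _samples(100, Diagnosis.HC, "h")
        states = _states(10, 10, cases, controls)
        res = anova_scan(states, cases, controls)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-9)

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(4)
        cases = _samples(80, Diagnosis.SZ, "c")
        controls = _samples(120, Diagnosis.HC, "h")
        states = _states(int(rng.integers(5, 30)), int(rng.integers(5, 30)), cases, controls)
        res = anova_scan(states, cases, controls)
        x = np.zeros(80)
        y = np.zeros(120)
        for s in states:
            if s.sample_id.startswith("c"):
                x[int(s.sample_id[1:])] = int(s.state)
            else:
                y[int(s.sample_id[1:])] = int(s.state)
        t, p_t = stats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t**2, rel=1e-9)
        assert res.p_value == pytest.approx(p_t, rel=1e-9)

    def test_zero_variance_everywhere_gives_p_one(self):
        cases, controls = _samples(10, Diagnosis.SZ, "c"), _samples(10, Diagnosis.HC, "h")
        res = anova_scan([], cases, controls)
        assert res.p_value == 1.0

    def test_chi_square_companion_present_when_informative(self):
        cases = _samples(100, Diagnosis.SZ, "c")
        controls = _samples(100, Diagnosis.HC, "h")
        states = _states(20, 5, cases, controls)
        res = anova_scan(states, cases, controls)
        assert "chi2_2x3_p" in res.extra


class TestCrossDisorder:
    def test_label_swap_symmetry_of_two_tailed_p(self):
        sz = _samples(100, Diagnosis.SZ, "sz")
        bd = _samples(100, Diagnosis.BD, "bd")
        states = [SampleState(s.sample_id, "r", State.DUPLICATION) for s in sz[:10]]
        states += [SampleState(s.sample_id, "r", State.DUPLICATION) for s in bd[:1]]
        p1 = cross_disorder_test(states, sz, bd, State.DUPLICATION).p_value
        p2 = cross_disorder_test(states, bd, sz, State.DUPLICATION).p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_equal_fractions_give_p_one(self):
        sz = _samples(50, Diagnosis.SZ, "sz")
        bd = _samples(50, Diagnosis.BD, "bd")
        states = [SampleState(s.sample_id, "r", State.DELETION) for s in sz[:5] + bd[:5]]
        assert cross_disorder_test(states, sz, bd, State.DELETION).p_value == 1.0

    def test_enumeration_oracle_ten_vs_one(self):
        sz = _samples(100, Diagnosis.SZ, "sz")
        bd = _samples(100, Diagnosis.BD, "bd")
        states = [SampleState(s.sample_id, "r", State.DUPLICATION) for s in sz[:10]]
        states += [SampleState(s.sample_id, "r", State.DUPLICATION) for s in bd[:1]]
        res = cross_disorder_test(states, sz, bd, State.DUPLICATION)
        # independent enumeration in exact rationals
        K, n1, n2 = 11, 100, 100
        weights = {k: comb(n1, k) * comb(n2, K - k) for k in range(0, 12)}
        w_obs = weights[10]
        expected = Fraction(sum(w for w in weights.values() if w <= w_obs),
                            sum(weights.values()))
        assert res.p_value == pytest.approx(float(expected), rel=1e-12)


class TestBurden:
    def _cohort_with_counts(self, case_counts, control_counts):
        cases = _samples(len(case_counts), Diagnosis.SZ, "c")
        controls = _samples(len(control_counts), Diagnosis.HC, "h")
        calls = []
        pos = 1
        for s, k in zip(cases + controls, list(case_counts) + list(control_counts)):
            for _ in range(k):
                calls.append(_call(s.sample_id, pos, pos + 600_000, cn=1, chrom="1"))
                pos += 700_000
        return cases, controls, calls

    def test_identical_count_vectors_are_null(self):
        cases, controls, calls = self._cohort_with_counts([2] * 15, [2] * 15)
        # singleton CNVRs in a 30-sample pool sit at frequency 1/30 > 1%,
        # so lift the rarity cap to keep them countable
        res = burden_analysis(calls, cases, controls, freq_max=0.5,
                              n_permutations=500, seed=0)
        assert res.p_value > 0.5

    def test_mean_calls_per_sample_hand_value(self):
        samples = _samples(4)
        calls = []
        pos = 1
        for s, k in zip(samples, [30, 40, 35, 45]):
            for _ in range(k):
                calls.append(_call(s.sample_id, pos, pos + 2000))
                pos += 5000
        assert mean_calls_per_sample(calls, samples) == pytest.approx(37.5)

    def test_permutation_p_reproducible_per_seed(self):
        rng = np.random.default_rng(5)
        case_counts = rng.poisson(1.5, 30)
        control_counts = rng.poisson(1.0, 30)
        cases, controls, calls = self._cohort_with_counts(case_counts, control_counts)
        r1 = burden_analysis(calls, cases, controls, freq_max=0.5,
                             n_permutations=1000, seed=7)
        r2 = burden_analysis(calls, cases, controls, freq_max=0.5,
                             n_permutations=1000, seed=7)
        assert r1.p_value == r2.p_value

    def test_detects_planted_case_excess(self):
        # +0.5 mean rare-large calls in cases; power over seeded replicates
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            case_counts = rng.poisson(1.5, 300)
            control_counts = rng.poisson(1.0, 300)
            cases, controls, calls = self._cohort_with_counts(case_counts, control_counts)
            res = burden_analysis(calls, cases, controls, n_permutations=500, seed=rep)
            hits += res.p_value < 0.05
        assert hits >= 9

    def test_too_few_samples_errors(self):
        cases, controls, calls = self._cohort_with_counts([1] * 5, [1] * 5)
        with pytest.raises(ValueError):
            burden_analysis(calls, cases, controls)
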