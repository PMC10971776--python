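"""9-mer windows, neoantigen load, median split, survival and rank tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from graphmhc.neoantigen import (
    PatientRecord,
    analyze_cohort,
    log_affinity_transform,
    logrank_test,
    median_split,
    neoantigen_load,
    nine_mer_windows,
    score_comparison,
    sigmoid_affinity_transform,
)


def window_count_oracle(L, p):
    return max(0, min(p, L - 8) - max(1, p - 8) + 1) if L >= 9 else 0


def textbook_logrank(times, events, groups):
    """Oracle: Mantel-Cox chi-square computed from first principles."""
    times = np.asarray(times, float)
    events = np.asarray(events, bool)
    groups = np.asarray(groups, bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & groups).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & groups).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2, float(stats.chi2.sf(chi2, 1))


class TestNineMerWindows:
    def test_interior_mutation_nine_windows(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"  # length 20
        wins = nine_mer_windows(seq, 10)
        assert len(wins) == 9
        assert wins[0] == seq[1:10] and wins[-1] == seq[9:18]
        assert all(len(w) == 9 for w in wins)

    def test_boundary_cases(self):
        assert nine_mer_windows("ACDEFGHIK", 5) == ["ACDEFGHIK"]
        assert nine_mer_windows("ACDEFGHIKLMNPQRSTVWY", 1) == ["ACDEFGHIK"]

    def test_short_sequence_yields_nothing(self):
        assert nine_mer_windows("ACDEF", 2) == []

    def test_position_outside_sequence_raises(self):
        with pytest.raises(ValueError):
            nine_mer_windows("ACDEFGHIK", 10)

    @given(L=st.integers(1, 30), p=st.integers(1, 30))
    @settings(max_examples=300, deadline=None)
    def test_count_formula_exhaustively(self, L, p):
        if p > L:
            return
        seq = "A" * L
        wins = nine_mer_windows(seq, p) if L >= 9 else []
        assert len(wins) == window_count_oracle(L, p)
        # every window really contains the mutated position
        if L >= 9:
            starts = range(max(1, p - 8), min(p, L - 8) + 1)
            assert all(s <= p <= s + 8 for s in starts)


class TestNeoantigenLoad:
    @pytest.fixture
    def patient(self):
        return PatientRecord(
            patient_id="PT1",
            alleles=["A1", "A2"],
            candidates=["AAAAAAAAA", "CCCCCCCCC", "WWWWWWWWW"],
        )

    def test_constant_high_scorer_counts_all_pairs(self, patient):
        mapping = {"A1": "GG", "A2": "AA"}
        load = neoantigen_load(patient, lambda m, p: 0.9, mapping)
        assert load == 6

    def test_constant_low_scorer_counts_none(self, patient):
        mapping = {"A1": "GG", "A2": "AA"}
        assert neoantigen_load(patient, lambda m, p: 0.1, mapping) == 0

    def test_planted_rule_scorer_equals_enumeration(self):
        rng = np.random.default_rng(3)
        prefs = {"A1": {2: "W", 9: "C"}, "A2": {2: "A", 9: "A"}}
        mapping = {"A1": "GG", "A2": "AA"}
        pseudo_to_allele = {v: k for k, v in mapping.items()}

        def scorer(pseudo, pep):
            allele = pseudo_to_allele[pseudo]
            match = all(pep[p - 1] == aa for p, aa in prefs[allele].items())
            return 0.95 if match else 0.05

        aas = list("ACDWY")
        candidates = ["".join(rng.choice(aas, 9)) for _ in range(40)]
        patient = PatientRecord("PT2", ["A1", "A2"], candidates)
        expected = sum(
            all(pep[p - 1] == aa for p, aa in prefs[a].items())
            for a in ("A1", "A2")
            for pep in candidates
        )
        assert neoantigen_load(patient, scorer, mapping) == expected

    def test_unmapped_allele_skipped(self, patient):
        assert neoantigen_load(patient, lambda m, p: 0.9, {"A1": "GG"}) == 3

    def test_unique_peptide_counting_toggle(self, patient):
        mapping = {"A1": "GG", "A2": "AA"}
        load = neoantigen_load(
            patient, lambda m, p: 0.9, mapping, count_unique_peptides=True
        )
        assert load == 3


class TestMedianSplit:
    def test_even_cohort(self):
        high = median_split([1, 2, 3, 4])
        assert high.tolist() == [False, False, True, True]

    def test_ties_go_low(self):
        high = median_split([1, 2, 2, 5])
        assert high.tolist() == [False, False, False, True]

    def test_degenerate_all_equal(self):
        assert not median_split([3, 3, 3]).any()

    def test_scale_invariance_under_monotone_transform(self, rng):
        loads = rng.integers(0, 50, 31)
        a = median_split(loads)
        b = median_split(np.sqrt(loads + 1.0))
        assert np.array_equal(a, b)


class TestLogrank:
    def test_matches_textbook_oracle_on_toy_table(self):
        # fixed 20-subject table with censoring and tied event times
        times = [5, 8, 12, 12, 15, 20, 22, 25, 30, 33,
                 6, 9, 9, 14, 18, 21, 28, 31, 35, 40]
        events = [1, 1, 0, 1, 1, 0, 1, 1, 1, 0,
                  1, 0, 1, 1, 1, 1, 0, 1, 0, 1]
        groups = [True] * 10 + [False] * 10
        stat, p = logrank_test(times, events, groups)
        ostat, op = textbook_logrank(times, events, groups)
        assert stat == pytest.approx(ostat, abs=1e-6)
        assert p == pytest.approx(op, abs=1e-6)

    def test_administrative_censoring_at_horizon(self):
        times = [100, 2000, 3000, 150, 2500, 90]
        events = [1, 1, 1, 1, 1, 1]
        groups = [True, True, True, False, False, False]
        stat_h, _ = logrank_test(times, events, groups, horizon_days=1825)
        stat, _ = logrank_test(times, events, groups)
        assert stat_h != stat  # horizon censors the late events

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [True, True])

    def test_power_at_hazard_ratio_three(self):
        rng = np.random.default_rng(0)
        rejections = 0
        n_sim = 120
        for _ in range(n_sim):
            groups = np.repeat([True, False], 100)
            scale = np.where(groups, 1000.0, 1000.0 / 3.0)
            times = rng.exponential(scale)
            events = times <= 1825
            times = np.minimum(times, 1825)
            _, p = logrank_test(times, events, groups)
            rejections += p < 0.05
        assert rejections / n_sim >= 0.8


class TestScoreComparison:
    def test_u_statistic_matches_pair_counting(self, rng):
        x = np.round(rng.random(50), 2)
        groups = np.array([True] * 25 + [False] * 25)
        u, _ = score_comparison(x, groups)
        a, b = x[groups], x[~groups]
        brute = sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)
        assert u == pytest.approx(brute)

    def test_identical_groups_high_p(self):
        x = np.concatenate([np.arange(20.0), np.arange(20.0)])
        groups = np.repeat([True, False], 20)
        _, p = score_comparison(x, groups)
        assert p > 0.9

    def test_shifted_normals_detected(self, rng):
        hits = 0
        for _ in range(40):
            x = np.concatenate([rng.normal(1.0, 1, 50), rng.normal(0, 1, 50)])
            _, p = score_comparison(x, np.repeat([True, False], 50))
            hits += p < 0.05
        assert hits / 40 > 0.8


class TestBaselineTransforms:
    def test_log_transform_anchors(self):
        assert log_affinity_transform(50000.0) == pytest.approx(0.0)
        assert log_affinity_transform(1.0) == pytest.approx(1.0)
        assert 0 < log_affinity_transform(500.0) < 1

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log_affinity_transform(0.0)

    def test_sigmoid_transform(self):
        assert sigmoid_affinity_transform(0.0) == pytest.approx(0.5)
        assert sigmoid_affinity_transform(50.0) < 1e-10
        assert sigmoid_affinity_transform(-50.0) > 1 - 1e-10


class TestAnalyzeCohort:
    def test_full_pipeline_on_synthetic_groups(self, rng):
        patients = []
        for k in range(40):
            high = k >= 20
            patients.append(
                PatientRecord(
                    patient_id=f"P{k}",
                    alleles=["A1"],
                    candidates=["AAAAAAAAA"],
                    survival_time=float(rng.exponential(2000 if high else 400)),
                    event=True,
                    stromal=float(rng.normal(2.0 if high else 0.0)),
                    immune=float(rng.normal(2.0 if high else 0.0)),
                    estimate=float(rng.normal(2.0 if high else 0.0)),
                )
            )
        loads = np.array([0] * 20 + [10] * 20)
        comp = analyze_cohort(patients, loads)
        assert len(comp.high_patients) == 20
        assert comp.logrank_p < 0.05
        assert set(comp.score_tests) == {"stromal", "immune", "estimate"}
        assert comp.score_tests["immune"][1] < 0.05
        assert isinstance(comp.to_dict()["score_tests"]["stromal"]["p"], float)
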