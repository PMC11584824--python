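"""Three-step trajectory algorithm: screening, directionality, confirmation,
network assembly."""

import json
from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import binomtest

import epitraj as et
from epitraj.trajectory import _FAR


def exact_binom_tail(k: int, n: int) -> float:
    """P(X >= k | n, 1/2) by integer summation (independent oracle)."""
    total = 0
    c = comb(n, k)
    for i in range(k, n + 1):
        total += c
        c = c * (n - i) // (i + 1)
    return float(Fraction(total, 2**n))


def _fu(n_exposed_events, n_rows=10):
    rows = []
    for i in range(n_rows):
        rows.append({"set_id": i, "person_id": f"e{i}", "exposed": True,
                     "start": 0.0, "stop": 100.0, "event": i < n_exposed_events})
        rows.append({"set_id": i, "person_id": f"c{i}", "exposed": False,
                     "start": 0.0, "stop": 100.0, "event": False})
    return pd.DataFrame(rows)


class TestScreening:
    def test_strictly_more_than_min_cases(self):
        fu_by = {"A": _fu(3, 5), "B": _fu(2, 5), "C": _fu(1, 5)}
        assert et.screen_diseases(fu_by, min_cases=2) == ["A"]

    def test_boundary_count_excluded(self):
        fu_by = {"A": _fu(2, 5)}
        with pytest.raises(RuntimeError, match="halted"):
            et.screen_diseases(fu_by, min_cases=2)

    def test_counts_match_manual_tally(self, small_cohort):
        from conftest import run_cohort
        cfg, *_ = small_cohort
        parts, diags, codes, emap, exposed, matched, fu = run_cohort(cfg, "I10")
        manual = int((fu.event & fu.exposed).sum())
        got = et.screen_diseases({"I10": fu}, min_cases=manual - 1)
        assert got == ["I10"]
        with pytest.raises(RuntimeError):
            et.screen_diseases({"I10": fu}, min_cases=manual)


class TestStep1:
    def test_bonferroni_rule_positive_direction_only(self):
        rng = np.random.default_rng(0)
        # disease X: exposed strongly over-represented among cases;
        # disease Y: protective (HR < 1) -> never significant
        def make(beta):
            rows = []
            for s in range(400):
                x = np.array([1.0, 0.0])
                w = np.exp(beta * x)
                case = rng.choice(2, p=w / w.sum())
                rows += [(s, f"p{s}a", True, 0.0, 10.0, case == 0),
                         (s, f"p{s}b", False, 0.0, 10.0, case == 1)]
            return pd.DataFrame(rows, columns=["set_id", "person_id", "exposed",
                                               "start", "stop", "event"])
        fu_by = {"X": make(1.5), "Y": make(-1.5)}
        out = et.step1_disease_cox(fu_by, ["X", "Y"], participants=None,
                                   adjustment=None, alpha=0.05)
        out = out.set_index("disease")
        assert out.loc["X", "bonferroni_threshold"] == pytest.approx(0.025)
        assert bool(out.loc["X", "significant"])
        assert not bool(out.loc["Y", "significant"])
        assert out.loc["Y", "p"] < 0.025  # excluded by direction, not by p

    def test_threshold_arithmetic_at_k19(self):
        assert 0.05 / 19 == pytest.approx(0.002632, abs=5e-7)
        assert not (0.004 < 0.05 / 19)


class TestEnumeratePairs:
    def test_eleven_diseases_give_110_ordered_pairs(self):
        assert len(et.enumerate_pairs([f"d{i}" for i in range(11)])) == 110

    @pytest.mark.parametrize("k,expected", [(0, 0), (1, 0), (2, 2), (4, 12)])
    def test_small_counts(self, k, expected):
        assert len(et.enumerate_pairs([f"d{i}" for i in range(k)])) == expected

    @given(st.integers(0, 30))
    def test_pair_count_identity(self, k):
        pairs = et.enumerate_pairs([f"d{i}" for i in range(k)])
        assert len(pairs) == k * (k - 1)
        assert len(set(pairs)) == len(pairs)


def _first_dates(day_a, day_b, index_day=0, end_day=9000):
    n = len(day_a)
    return pd.DataFrame({
        "index_day": [index_day] * n, "end_day": [end_day] * n,
        "day_A": day_a, "day_B": day_b,
    }, index=[f"p{i}" for i in range(n)])


class TestDirectionality:
    def test_all_d1_first_gives_half_power_n(self):
        fd = _first_dates([10] * 10, [20] * 10)
        stats = et.directionality_filter([("A", "B"), ("B", "A")], fd, min_co=5)
        s = stats[0]
        assert s.d1 == "A" and s.n_d1_first == 10
        assert s.binomial_p == pytest.approx(0.5**10, rel=1e-12)

    def test_prevalence_threshold_is_n_both(self):
        fd = _first_dates([10] * 99, [20] * 99)
        stats = et.directionality_filter([("A", "B")], fd, min_co=100)
        assert not stats[0].passed_prevalence and not stats[0].passed
        stats = et.directionality_filter([("A", "B")], fd, min_co=99)
        assert stats[0].passed

    def test_binomial_tail_matches_exact_summation(self):
        day_a = [10] * 90 + [30] * 60
        day_b = [20] * 90 + [25] * 60
        fd = _first_dates(day_a, day_b)
        stats = et.directionality_filter([("A", "B")], fd, min_co=100)
        s = stats[0]
        assert (s.n_both, s.n_d1_first) == (150, 90)
        assert s.binomial_p == pytest.approx(exact_binom_tail(90, 150), abs=1e-12)

    @pytest.mark.parametrize("k,n", [(6, 10), (55, 100), (520, 1000), (5100, 10000)])
    def test_scipy_tail_equals_integer_oracle(self, k, n):
        p_scipy = binomtest(k, n, 0.5, alternative="greater").pvalue
        assert p_scipy == pytest.approx(exact_binom_tail(k, n), abs=1e-12)

    def test_all_same_day_pairs_untestable(self):
        fd = _first_dates([10] * 120, [10] * 120)
        stats = et.directionality_filter([("A", "B")], fd, min_co=100)
        s = stats[0]
        assert s.n_same_day == 120 and np.isnan(s.binomial_p) and not s.passed

    def test_counts_partition_n_both(self):
        fd = _first_dates([10, 10, 30, 5], [20, 10, 10, _FAR])
        stats = et.directionality_filter([("A", "B")], fd, min_co=1)
        s = stats[0]
        assert s.n_both == 3
        assert s.n_d1_first + s.n_d2_first + s.n_same_day == s.n_both

    def test_null_directionality_rejects_at_alpha(self):
        """Under exchangeable order, uncorrected pass rate stays near alpha."""
        rng = np.random.default_rng(12)
        hits = 0
        n_pairs = 400
        for _ in range(n_pairs):
            n = 150
            a = rng.integers(1, 1000, n)
            b = rng.integers(1, 1000, n)
            fd = _first_dates(a, b)
            stats = et.directionality_filter([("A", "B")], fd, min_co=100,
                                             alpha=0.05)
            k, m = stats[0].n_d1_first, stats[0].n_d1_first + stats[0].n_d2_first
            # uncorrected one-sided test on the majority direction is a
            # two-sided test at level alpha
            if binomtest(k, m, 0.5, alternative="greater").pvalue < 0.025:
                hits += 1
        assert 0.01 < hits / n_pairs < 0.05  # nominal 0.025


class TestNestedCaseControl:
    def _parts(self, n):
        return pd.DataFrame({
            "person_id": [f"p{i}" for i in range(n)],
            "sex": ["female"] * n, "birth_year": [1950] * n})

    def test_future_d2_case_can_serve_as_control_now(self):
        # p1 is a case at day 100; p2 develops B later (day 500) and p3 never
        fd = pd.DataFrame({
            "index_day": [0, 0, 0], "end_day": [9000] * 3,
            "day_A": [_FAR, _FAR, _FAR], "day_B": [100, 500, _FAR],
        }, index=["p0", "p1", "p2"])
        sets = et.nested_case_control(fd, self._parts(3).set_index("person_id").reset_index(),
                                      "A", "B", m_controls=5, seed=0)
        first = sets[sets.set_id == 1]
        assert set(first[~first.case].person_id) == {"p1", "p2"}

    def test_same_day_prior_diagnosis_does_not_count(self):
        fd = pd.DataFrame({
            "index_day": [0, 0], "end_day": [9000] * 2,
            "day_A": [100, _FAR], "day_B": [100, _FAR],
        }, index=["p0", "p1"])
        sets = et.nested_case_control(fd, self._parts(2), "A", "B",
                                      m_controls=5, seed=0)
        case_row = sets[sets.case].iloc[0]
        assert case_row.prior_d1 == 0.0  # strictly-before rule

    def test_matching_respects_sex_and_birth_year(self):
        parts = pd.DataFrame({
            "person_id": ["p0", "p1", "p2", "p3"],
            "sex": ["female", "female", "male", "female"],
            "birth_year": [1950, 1951, 1950, 1960]})
        fd = pd.DataFrame({
            "index_day": [0] * 4, "end_day": [9000] * 4,
            "day_A": [_FAR] * 4, "day_B": [100, _FAR, _FAR, _FAR],
        }, index=parts.person_id.tolist())
        sets = et.nested_case_control(fd, parts, "A", "B", m_controls=5, seed=0)
        controls = set(sets[~sets.case].person_id)
        assert controls == {"p1"}  # p2 wrong sex, p3 birth year too far


class TestAssembleNetwork:
    def _edges(self, pairs, p=1e-6, or_=3.0):
        return pd.DataFrame([{"d1": a, "d2": b, "or": or_, "ci_low": or_ / 2,
                              "ci_high": or_ * 2, "p": p, "confirmed": True}
                             for a, b in pairs])

    def test_chain_layers(self):
        g = et.assemble_network(self._edges([("A", "B"), ("B", "C")]))
        assert g.nodes["A"]["layer"] == 1
        assert g.nodes["B"]["layer"] == 2
        assert g.nodes["C"]["layer"] == 3

    def test_two_cycle_resolved_by_larger_p(self):
        edges = pd.DataFrame([
            {"d1": "A", "d2": "B", "or": 3.0, "ci_low": 2, "ci_high": 4,
             "p": 1e-8, "confirmed": True},
            {"d1": "B", "d2": "A", "or": 3.0, "ci_low": 2, "ci_high": 4,
             "p": 1e-4, "confirmed": True}])
        g = et.assemble_network(edges)
        assert list(g.edges) == [("A", "B")]
        assert g.graph["deleted_edges"] == [["B", "A"]]
        assert g.nodes["A"]["layer"] == 1 and g.nodes["B"]["layer"] == 2

    def test_cycle_tie_broken_by_smaller_or(self):
        edges = pd.DataFrame([
            {"d1": "A", "d2": "B", "or": 5.0, "ci_low": 2, "ci_high": 9,
             "p": 1e-4, "confirmed": True},
            {"d1": "B", "d2": "A", "or": 3.0, "ci_low": 2, "ci_high": 4,
             "p": 1e-4, "confirmed": True}])
        g = et.assemble_network(edges)
        assert list(g.edges) == [("A", "B")]

    def test_structural_bookkeeping_23_edges_10_nodes(self):
        rng = np.random.default_rng(4)
        nodes = [f"n{i}" for i in range(10)]
        pairs = set()
        while len(pairs) < 23:
            i, j = rng.choice(10, 2, replace=False)
            if i < j:  # forward edges only: guaranteed acyclic
                pairs.add((nodes[i], nodes[j]))
        g = et.assemble_network(self._edges(sorted(pairs)))
        assert g.number_of_nodes() == 10 and g.number_of_edges() == 23

    def test_every_edge_goes_to_strictly_later_layer(self):
        rng = np.random.default_rng(7)
        nodes = [f"n{i}" for i in range(8)]
        pairs = {(nodes[i], nodes[j]) for i in range(8) for j in range(8)
                 if i != j and rng.random() < 0.3}
        g = et.assemble_network(self._edges(
            sorted(pairs), p=1e-6))
        for u, v in g.edges:
            assert g.nodes[v]["layer"] > g.nodes[u]["layer"]

    def test_empty_edge_list_gives_empty_network(self):
        g = et.assemble_network(pd.DataFrame(
            columns=["d1", "d2", "or", "ci_low", "ci_high", "p", "confirmed"]))
        assert g.number_of_nodes() == 0

    def test_export_roundtrip(self, tmp_path):
        g = et.assemble_network(self._edges([("A", "B"), ("B", "C")]))
        from epitraj.trajectory import export_network
        export_network(g, tmp_path)
        back = nx.read_graphml(tmp_path / "trajectory_network.graphml")
        assert set(back.edges) == {("A", "B"), ("B", "C")}
        doc = json.loads((tmp_path / "trajectory_network.json").read_text())
        assert {n["id"]: n["layer"] for n in doc["nodes"]} == \
            {"A": 1, "B": 2, "C": 3}
        assert len(doc["edges"]) == 2
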