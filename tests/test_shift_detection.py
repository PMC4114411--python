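"""Edit-distance matrix, backtrace, criticality and the shift driver."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adlshift.behavior_model import InvalidInputError, enumerate_paths
from adlshift.config import RunConfig
from adlshift.shift_detection import (
    CriticalityEntry,
    CriticalityMap,
    InternalConsistencyError,
    Modification,
    apply_modifications,
    backtrace_modifications,
    build_distance_matrix,
    calculate_shifts,
    criticality,
    modification_signatures,
    risk_factor,
)

from oracles import script_distance

ALPHABET = ("a", "b", "c", "d")

seqs = st.lists(st.sampled_from(ALPHABET), min_size=1, max_size=7).map(tuple)


def signatures(mods):
    return modification_signatures(mods)


class TestDistanceMatrix:
    @pytest.mark.parametrize(
        "observed, path, expected",
        [("c2", "rho11", 3), ("c2", "rho12", 1), ("c3", "rho11", 3), ("c3", "rho12", 1)],
    )
    def test_worked_modification_counts(self, observed, path, expected, request):
        D = build_distance_matrix(
            request.getfixturevalue(observed), request.getfixturevalue(path)
        )
        assert D.distance == expected

    def test_identity_distance_zero(self, c1):
        assert build_distance_matrix(c1, c1).distance == 0

    def test_boundary_cells(self, c2, rho11):
        D = build_distance_matrix(c2, rho11)
        assert D.values[0, 0] == 0
        assert list(D.values[:, 0]) == list(range(len(c2) + 1))
        assert list(D.values[0, :]) == list(range(len(rho11) + 1))

    def test_empty_input_rejected(self, c1):
        with pytest.raises(InvalidInputError):
            build_distance_matrix([], c1)

    def test_crossed_pair_reedited_still_minimal(self):
        """The transposed pair may be split by later material: 'c a' needs
        swap + insert (2 ops), not the 3 the restricted recurrence gives."""
        D = build_distance_matrix(("c", "a"), ("a", "b", "c"))
        assert D.distance == 2
        mods = backtrace_modifications(D, ("c", "a"), ("a", "b", "c"))
        assert {m.op for m in mods} == {"swap", "insert"}

    @given(s=seqs, t=seqs)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_equals_script_search_oracle(self, s, t):
        """Matrix distance equals brute-force minimum edit-script length."""
        assert build_distance_matrix(s, t).distance == script_distance(s, t, ALPHABET)

    @given(s=seqs, t=seqs)
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_triangle_like_bounds(self, s, t):
        d = build_distance_matrix(s, t).distance
        assert abs(len(s) - len(t)) <= d <= len(s) + len(t)

    def test_oracle_cross_checked_against_edlib(self):
        """Without the swap operation the script-search oracle must agree
        with an established Levenshtein implementation."""
        edlib = pytest.importorskip("edlib")
        rng = np.random.default_rng(3)
        chars = dict(zip(ALPHABET, "abcd"))
        for _ in range(40):
            s = tuple(rng.choice(ALPHABET, size=rng.integers(1, 7)))
            t = tuple(rng.choice(ALPHABET, size=rng.integers(1, 7)))
            want = edlib.align("".join(chars[x] for x in s),
                               "".join(chars[x] for x in t))["editDistance"]
            assert script_distance(s, t, ALPHABET,
                                   ops=("insert", "delete", "substitute")) == want


class TestBacktrace:
    def test_worked_set_deletions_and_insertion(self, c2, rho11):
        D = build_distance_matrix(c2, rho11)
        mods = backtrace_modifications(D, c2, rho11)
        assert signatures(mods) == signatures(
            [
                Modification("delete", ("Shower, on",), 0),
                Modification("delete", ("Shower, off",), 0),
                Modification("insert", ("Pill, on",), 0),
            ]
        )

    def test_worked_single_swap(self, c3, rho12):
        D = build_distance_matrix(c3, rho12)
        mods = backtrace_modifications(D, c3, rho12)
        assert len(mods) == 1
        assert mods[0].op == "swap"
        assert set(mods[0].actions) == {"Pill, on", "Breakfast, on"}

    def test_identity_empty_set(self, c1):
        D = build_distance_matrix(c1, c1)
        assert backtrace_modifications(D, c1, c1) == []

    @given(s=seqs, t=seqs)
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_replay_soundness_and_cardinality(self, s, t):
        """Replaying the backtraced set on the episode yields the path,
        and the set size equals the bottom-right matrix cell."""
        D = build_distance_matrix(s, t)
        mods = backtrace_modifications(D, s, t)
        assert len(mods) == D.distance
        assert apply_modifications(s, mods) == t

    def test_inconsistent_triple_rejected(self, c1, c2, rho11):
        D = build_distance_matrix(c2, rho11)
        with pytest.raises(InternalConsistencyError):
            backtrace_modifications(D, c1, rho11)
        tampered = build_distance_matrix(c2, rho11)
        tampered.values[-1, -1] += 1
        with pytest.raises(InternalConsistencyError):
            backtrace_modifications(tampered, c2, rho11)


class TestCriticality:
    def test_worked_values(self, michael_cmap):
        assert criticality([Modification("insert", ("Pill, on",), 7)], michael_cmap) == 0.2
        assert criticality(
            [Modification("swap", ("Pill, on", "Breakfast, on"), 6)], michael_cmap
        ) == 0.4

    def test_empty_set_is_noncritical(self, michael_cmap):
        assert criticality([], michael_cmap) == 1.0

    def test_aggregations(self):
        cmap = CriticalityMap(
            entries=(
                CriticalityEntry("insert", ("x",), 0.4),
                CriticalityEntry("delete", ("y",), 0.2),
            )
        )
        mods = [Modification("insert", ("x",), 0), Modification("delete", ("y",), 1)]
        assert criticality(mods, cmap, "min") == 0.2
        assert criticality(mods, cmap, "product") == pytest.approx(0.08)
        assert criticality(mods, cmap, "mean") == pytest.approx(0.3)
        with pytest.raises(InvalidInputError):
            criticality(mods, cmap, "median")

    def test_most_specific_entry_wins(self):
        cmap = CriticalityMap(
            entries=(
                CriticalityEntry("insert", None, 0.5),  # op-level wildcard
                CriticalityEntry("insert", ("Pill, on",), 0.1),
            ),
            default_value=0.9,
        )
        assert cmap.value_for(Modification("insert", ("Pill, on",), 0)) == 0.1
        assert cmap.value_for(Modification("insert", ("Tea, on",), 0)) == 0.5
        assert cmap.value_for(Modification("delete", ("Tea, on",), 0)) == 0.9

    def test_swap_operands_match_either_order(self, michael_cmap):
        assert michael_cmap.value_for(
            Modification("swap", ("Breakfast, on", "Pill, on"), 0)
        ) == 0.4

    def test_values_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            CriticalityEntry("insert", ("x",), 1.2)
        with pytest.raises(InvalidInputError):
            CriticalityMap(default_value=-0.1)


class TestRiskFactor:
    def test_zero_modifications_zero_risk(self):
        assert risk_factor(0, 0.0) == 0.0
        assert risk_factor(0, 1.0) == 0.0

    def test_default_formula_values(self):
        assert risk_factor(1, 0.2) == pytest.approx(0.8)
        assert risk_factor(3, 0.2) == pytest.approx(2.4)

    def test_noncritical_edits_carry_no_risk(self):
        for k in range(5):
            assert risk_factor(k, 1.0) == 0.0

    def test_monotone_in_count_and_severity(self):
        assert risk_factor(3, 0.5) > risk_factor(2, 0.5)
        assert risk_factor(2, 0.2) > risk_factor(2, 0.4)


class TestCalculateShifts:
    def test_matching_episode_reports_likelihood(self, michael, c1, michael_cmap):
        report = calculate_shifts([michael], c1, cmap=michael_cmap)
        assert report.matched and not report.anomalous
        best = report.best
        assert best.likelihood == 0.6
        assert best.modification_count == 0 and best.modifications == ()

    def test_pill_skipped_repaired_by_one_insertion(self, michael, c2, michael_cmap):
        report = calculate_shifts([michael], c2, cmap=michael_cmap)
        best = report.best
        assert not report.matched
        assert best.path_likelihood == 0.6  # the shower path, not the 3-edit one
        assert best.modification_count == 1
        assert best.modifications[0].op == "insert"
        assert best.modifications[0].actions == ("Pill, on",)
        assert best.criticality == 0.2
        assert best.risk_factor == pytest.approx(0.8)

    def test_pill_first_repaired_by_one_swap(self, michael, c3, michael_cmap):
        report = calculate_shifts([michael], c3, cmap=michael_cmap)
        best = report.best
        assert best.modification_count == 1  # not the 3 needed for the other path
        assert best.modifications[0].op == "swap"
        assert best.criticality == 0.4
        assert best.risk_factor == pytest.approx(0.6)

    def test_disjoint_alphabet_distance(self, michael):
        """With no action in common, each path needs max(|C|, |path|)
        modifications; the driver picks the shorter path."""
        episode = ("x1", "x2", "x3")
        report = calculate_shifts([michael], episode)
        assert report.best.modification_count == 7  # the 7-action path
        # unmapped edits default to criticality 1 (non-critical): no risk
        assert report.best.risk_factor == 0.0
        assert not report.anomalous

    def test_anomaly_uses_criticality_map(self, michael):
        severe = CriticalityMap(
            entries=tuple(
                CriticalityEntry(op, None, 0.0) for op in ("insert", "delete", "substitute", "swap")
            )
        )
        report = calculate_shifts([michael], ("x1", "x2", "x3"), cmap=severe)
        assert report.best.risk_factor == 7.0
        assert report.anomalous

    def test_enumerated_paths_close_the_loop(self, michael):
        """Every path of the chain is recognized as frequent with its own
        path likelihood and zero modifications."""
        for ep, ll in enumerate_paths(michael, 0.01, 50):
            report = calculate_shifts([michael], ep.labels)
            assert report.matched
            assert report.best.likelihood == pytest.approx(ll, abs=1e-12)
            assert report.best.modification_count == 0

    def test_phi_zero_iff_no_modifications(self, michael, c1, c2, michael_cmap):
        matched = calculate_shifts([michael], c1, cmap=michael_cmap).best
        shifted = calculate_shifts([michael], c2, cmap=michael_cmap).best
        assert matched.modification_count == 0 and matched.risk_factor == 0.0
        assert shifted.modification_count > 0 and shifted.risk_factor > 0.0

    def test_behavior_without_paths_skipped_with_warning(self, michael, c2):
        from adlshift.behavior_model import FrequentBehavior

        spinner = FrequentBehavior.from_edges(
            id="spinner", initial_probs={"a": 1.0}, edges=[("a", "a", 1.0)]
        )
        report = calculate_shifts([spinner, michael], c2)
        assert report.warnings
        by_id = {r.behavior_id: r for r in report.results}
        assert by_id["spinner"].modification_count is None
        assert by_id["michael_f1"].modification_count == 1

    def test_empty_inputs_rejected(self, michael, c1):
        with pytest.raises(InvalidInputError):
            calculate_shifts([], c1)
        with pytest.raises(InvalidInputError):
            calculate_shifts([michael], [])
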