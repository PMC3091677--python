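"""Likelihood machinery, two-point analysis, grouping, ordering, estimation."""

import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovismap import (GenotypeTable, Individual, Interval, LinkageGroup,
                     LinkageMap, MultipointEvaluator, PairStats, Pedigree,
                     TwoPointResult, assign_stragglers, curate_synteny,
                     estimate_map, flag_double_recombinants,
                     form_linkage_groups, kosambi, kosambi_inverse,
                     mask_flagged, mle_theta, multipoint_loglik, order_build,
                     orient_order, phase_meioses, refine_flips,
                     split_long_intervals, twopoint, twopoint_all)

from conftest import build_phase_known_panel


# ---------------------------------------------------------------------------
# Kosambi map function


class TestKosambi:
    def test_closed_form_values(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.25) == pytest.approx(25.0 * math.log(3.0), abs=1e-12)
        assert kosambi_inverse(50.0) == pytest.approx(0.5 * math.tanh(1.0))

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi(-0.01)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)

    @given(st.floats(min_value=0.0, max_value=0.49))
    @settings(max_examples=200, deadline=None)
    def test_round_trip(self, theta):
        assert kosambi_inverse(kosambi(theta)) == pytest.approx(theta,
                                                                abs=1e-12)


# ---------------------------------------------------------------------------
# two-point likelihood


class TestTwoPointPhaseKnown:
    def test_no_recombinants(self):
        """R = 0 of N = 10 phase-known: theta 0, LOD = 10 log10 2."""
        panel, _, _ = build_phase_known_panel(["AA"] * 10)
        r = twopoint(panel, "M0", "M1")
        assert r.theta == 0.0
        assert r.lod == pytest.approx(10 * math.log10(2.0), abs=1e-9)
        assert (r.R, r.N) == (0, 10)

    def test_half_recombinants_no_signal(self):
        panel, _, _ = build_phase_known_panel(["AA"] * 5 + ["AB"] * 5)
        r = twopoint(panel, "M0", "M1")
        assert r.theta == pytest.approx(0.5)
        assert r.lod == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("n_rec,n_tot", [(2, 20), (5, 40), (7, 10)])
    def test_theta_is_recombinant_fraction(self, n_rec, n_tot):
        strings = ["AB"] * n_rec + ["AA"] * (n_tot - n_rec)
        panel, _, _ = build_phase_known_panel(strings)
        r = twopoint(panel, "M0", "M1")
        assert r.theta == pytest.approx(min(n_rec / n_tot, 0.5), abs=1e-9)

    def test_closed_form_matches_grid_maximizer(self):
        panel, _, _ = build_phase_known_panel(["AB"] * 3 + ["AA"] * 27)
        ev = MultipointEvaluator(panel, ["M0", "M1"])
        stats = ev.pair_stats(["M0", "M1"])[(0, 1)]
        grid = np.arange(1e-4, 0.5 + 1e-9, 1e-4)
        lls = [stats.log10_lik(t) for t in grid]
        assert mle_theta(stats)[0] == pytest.approx(grid[int(np.argmax(lls))],
                                                    abs=2e-4)

    def test_no_shared_meioses_skipped(self):
        # records exist at M0 only: the pair shares no informative meioses
        panel, _, _ = build_phase_known_panel(["A"], markers=["M0", "M1"])
        assert twopoint(panel, "M0", "M1") is None


class TestTwoPointPhaseUncertain:
    def _mixture_panel(self, pattern: list[str]):
        """Founder sire (no grandparents): phase unknown, mixture likelihood.
        Pattern letters index the transmitted haplotype under the anchor."""
        inds = [Individual("sire", None, None, "male"),
                Individual("dam", None, None, "female")]
        inds += [Individual(f"kid{i}", "sire", "dam", "female")
                 for i in range(len(pattern))]
        ped = Pedigree(inds)
        t = GenotypeTable(["M0", "M1"])
        for m in ("M0", "M1"):
            t.set("sire", m, ("C", "D"))
            t.set("dam", m, ("E", "E"))
        for i, s in enumerate(pattern):
            t.set(f"kid{i}", "M0", ("C", "E"))
            t.set(f"kid{i}", "M1", ("C" if s == "A" else "D", "E"))
        return phase_meioses(ped, t)

    def test_mixture_mle_matches_grid_oracle(self):
        """Single phase-uncertain parent, r = 1 of n = 10: the MLE equals a
        brute-force 1e-4 grid maximizer of the two-phase mixture."""
        panel = self._mixture_panel(["B"] + ["A"] * 9)
        r = twopoint(panel, "M0", "M1")
        grid = np.arange(1e-4, 0.5 + 1e-9, 1e-4)

        def mixture_ll(th):  # independent oracle formula
            return math.log10(0.5 * (th * (1 - th) ** 9
                                     + th ** 9 * (1 - th)))

        best = grid[int(np.argmax([mixture_ll(t) for t in grid]))]
        assert r.theta == pytest.approx(best, abs=2e-4)

    def test_balanced_mixture_is_uninformative(self):
        panel = self._mixture_panel(["A", "B"] * 5)
        r = twopoint(panel, "M0", "M1")
        assert r.lod == pytest.approx(0.0, abs=1e-6)

    def test_phase_known_and_mixture_sum_counts(self):
        panel = self._mixture_panel(["A"] * 6)
        r = twopoint(panel, "M0", "M1")
        assert r.N == 0  # founder parent: nothing phase-known
        assert r.n_meioses == 6


class TestSexSpecificTwoPoint:
    def test_sex_split_estimates(self, small_panel):
        m1, m2 = small_panel.markers[0], small_panel.markers[1]
        r = twopoint(small_panel, m1, m2)
        assert 0.0 <= r.theta <= 0.5
        assert r.n_meioses_f + r.n_meioses_m <= r.n_meioses
        for th in (r.theta_f, r.theta_m):
            assert math.isnan(th) or 0.0 <= th <= 0.5


# ---------------------------------------------------------------------------
# grouping


def _tp(a, b, lod, n=100):
    return TwoPointResult(a, b, 0.1, 0.1, 0.1, lod, n, n // 2, n // 2,
                          int(0.1 * n), n)


class TestFormLinkageGroups:
    def test_transitive_closure(self):
        res = [_tp("a", "b", 5), _tp("b", "c", 5), _tp("a", "c", 0.1)]
        groups = form_linkage_groups(res, ["a", "b", "c"], 4.0)
        assert groups == [{"a", "b", "c"}]

    def test_threshold_is_strict(self):
        res = [_tp("a", "b", 3.9), _tp("b", "c", 3.9)]
        groups = form_linkage_groups(res, ["a", "b", "c"], 4.0)
        assert groups == [{"a"}, {"b"}, {"c"}]

    def test_empty_marker_set(self):
        assert form_linkage_groups([], [], 4.0) == []


class TestAssignStragglers:
    REF = {"a": ("chr1", 0.0), "b": ("chr1", 10.0), "c": ("chr1", 20.0),
           "x": ("chr2", 0.0), "y": ("chr2", 10.0)}

    def test_singleton_joins_reference_neighbor(self):
        partition = [{"a", "b"}, {"c"}, {"x", "y"}]
        res = [_tp("a", "b", 9), _tp("x", "y", 9), _tp("b", "c", 2.5),
               _tp("c", "x", 0.3)]
        out, log = assign_stragglers(partition, res, self.REF)
        assert {"a", "b", "c"} in out
        assert any("assigned c" in line for line in log)

    def test_singleton_with_wrong_chromosome_partner_left(self):
        partition = [{"a", "b"}, {"c"}, {"x", "y"}]
        # c's best LOD is with x on chr2: not a reference neighbour of c
        res = [_tp("a", "b", 9), _tp("x", "y", 9), _tp("c", "x", 2.5),
               _tp("b", "c", 0.2)]
        out, _log = assign_stragglers(partition, res, self.REF)
        assert {"c"} in out

    def test_no_reference_map_unchanged(self):
        partition = [{"a", "b"}, {"c"}]
        out, log = assign_stragglers(partition, [_tp("b", "c", 9)], None)
        assert out == [{"a", "b"}, {"c"}] and log == []

    def test_same_chromosome_groups_merge_on_end_lod(self):
        partition = [{"a", "b"}, {"c"}]  # both chr1; b-c strongest for both
        res = [_tp("a", "b", 9), _tp("b", "c", 3.0), _tp("a", "c", 1.0)]
        out, log = assign_stragglers(partition, res, self.REF)
        assert out == [{"a", "b", "c"}]
        assert any("merged" in line or "assigned" in line for line in log)


class TestCurateSynteny:
    def test_weak_cross_chromosome_bridge_cut(self):
        ref = TestAssignStragglers.REF
        partition = [{"a", "b", "c", "x", "y"}]
        res = [_tp("a", "b", 50), _tp("b", "c", 50), _tp("x", "y", 60),
               _tp("c", "x", 4.5)]  # weld far weaker than within-chrom links
        out, log = curate_synteny(partition, res, ref, 4.0)
        assert {"a", "b", "c"} in out and {"x", "y"} in out
        assert len(log) == 1

    def test_strong_bridge_kept(self):
        ref = TestAssignStragglers.REF
        partition = [{"a", "b", "x"}]
        res = [_tp("a", "b", 10), _tp("b", "x", 80)]  # x genuinely linked
        out, _log = curate_synteny(partition, res, ref, 4.0)
        assert out == [{"a", "b", "x"}]


# ---------------------------------------------------------------------------
# multipoint likelihood & ordering


class TestMultipointLoglik:
    def test_two_marker_consistency_with_twopoint(self):
        panel, _, _ = build_phase_known_panel(["AB"] * 2 + ["AA"] * 18)
        r = twopoint(panel, "M0", "M1")
        ev = MultipointEvaluator(panel, ["M0", "M1"])
        stats = ev.pair_stats(["M0", "M1"])[(0, 1)]
        # multipoint is the absolute profile log10 L = LOD + log10 L(0.5)
        assert multipoint_loglik(["M0", "M1"], panel) == pytest.approx(
            r.lod + stats.log10_lik_null(), abs=1e-9)

    def test_reversal_symmetry(self, small_panel, small_study):
        order = small_study.true_map.markers["chr1"]
        ll = multipoint_loglik(order, small_panel)
        assert multipoint_loglik(order[::-1], small_panel) == pytest.approx(
            ll, abs=1e-9)

    def test_true_order_beats_random_permutations(self, small_panel,
                                                  small_study):
        order = small_study.true_map.markers["chr1"]
        ev = MultipointEvaluator(small_panel, order)
        ll_true = ev.loglik(order)
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(20):
            perm = list(rng.permutation(order))
            while perm == order or perm == order[::-1]:
                perm = list(rng.permutation(order))
            wins += ll_true >= ev.loglik(perm)
        assert wins >= 19

    def test_needs_two_markers(self, small_panel):
        with pytest.raises(ValueError):
            multipoint_loglik(["only"], small_panel)


class TestOrderBuild:
    def test_three_collinear_markers(self):
        """Dense phase-known data across two intervals recovers the order."""
        rng = np.random.default_rng(1)
        strings = []
        for _ in range(120):
            o = [0]
            for th in (0.1, 0.2):
                o.append(o[-1] ^ (rng.random() < th))
            strings.append("".join("AB"[v] for v in o))
        panel, _, _ = build_phase_known_panel(strings)
        order, _ev = order_build({"M0", "M1", "M2"}, panel)
        assert order in (["M0", "M1", "M2"], ["M2", "M1", "M0"])

    def test_two_marker_group_trivial(self):
        panel, _, _ = build_phase_known_panel(["AA"] * 25)
        order, _ = order_build({"M0", "M1"}, panel)
        assert sorted(order) == ["M0", "M1"]

    def test_weak_marker_needs_ladder_zero(self):
        """A marker with a single informative meiosis is only placed once
        the LOD ladder reaches 0."""
        strings = ["AA"] * 30 + ["AAA"]
        panel, _, _ = build_phase_known_panel(strings)
        partial, _ = order_build({"M0", "M1", "M2"}, panel, lod_ladder=(3.0,))
        assert "M2" not in partial and len(partial) == 2
        full, _ = order_build({"M0", "M1", "M2"}, panel)
        assert sorted(full) == ["M0", "M1", "M2"]


class TestRefineFlips:
    def test_optimal_order_unchanged(self):
        rng = np.random.default_rng(2)
        strings = []
        for _ in range(150):
            o = [0]
            for th in (0.05, 0.25, 0.05):
                o.append(o[-1] ^ (rng.random() < th))
            strings.append("".join("AB"[v] for v in o))
        panel, _, _ = build_phase_known_panel(strings)
        truth = ["M0", "M1", "M2", "M3"]
        refined, margin = refine_flips(truth, panel, window=4)
        assert refined == truth
        assert margin >= 0

    def test_adjacent_swap_restored(self):
        rng = np.random.default_rng(3)
        strings = []
        for _ in range(200):
            o = [0]
            for th in (0.1, 0.1, 0.1):
                o.append(o[-1] ^ (rng.random() < th))
            strings.append("".join("AB"[v] for v in o))
        panel, _, _ = build_phase_known_panel(strings)
        start = ["M0", "M2", "M1", "M3"]
        refined, _ = refine_flips(start, panel, window=3)
        assert refined in (["M0", "M1", "M2", "M3"],
                           ["M3", "M2", "M1", "M0"])

    def test_full_window_equals_brute_force(self, small_panel, small_study):
        """window = group size: the refined order attains the global optimum
        over all permutations (brute-force oracle)."""
        markers = small_study.true_map.markers["chr2"][:5]
        ev = MultipointEvaluator(small_panel, markers)
        brute = max(ev.loglik(list(p)) for p in permutations(markers))
        rng = np.random.default_rng(4)
        start = list(rng.permutation(markers))
        refined, _ = refine_flips(start, small_panel, window=len(markers),
                                  evaluator=ev)
        assert ev.loglik(refined) == pytest.approx(brute, abs=1e-9)


# ---------------------------------------------------------------------------
# double recombinants


class TestFlagDoubleRecombinants:
    POS = {"M0": 0.0, "M1": 1.0, "M2": 2.0, "M3": 3.0, "M4": 4.0}

    def test_isolated_state_flagged(self):
        panel, _, _ = build_phase_known_panel(["AABAA"])
        flags = flag_double_recombinants(list(self.POS), panel, self.POS,
                                         span_cm_limit=20.0)
        assert len(flags) == 1
        assert flags[0].marker == "M2"
        assert flags[0].flank_span_cm == pytest.approx(2.0)

    def test_single_switch_not_flagged(self):
        panel, _, _ = build_phase_known_panel(["AABBB"])
        assert flag_double_recombinants(list(self.POS), panel, self.POS,
                                        20.0) == []

    def test_zero_limit_never_flags(self):
        panel, _, _ = build_phase_known_panel(["AABAA"])
        assert flag_double_recombinants(list(self.POS), panel, self.POS,
                                        0.0) == []

    def test_wide_flanks_not_flagged(self):
        panel, _, _ = build_phase_known_panel(["AABAA"])
        pos = {m: 50.0 * i for i, m in enumerate(self.POS)}
        assert flag_double_recombinants(list(self.POS), panel, pos,
                                        20.0) == []

    def test_masking_removes_offspring_call(self):
        panel, _ped, table = build_phase_known_panel(["AABAA"])
        flags = flag_double_recombinants(list(self.POS), panel, self.POS,
                                         20.0)
        masked = mask_flagged(table, flags)
        assert masked.get(flags[0].offspring, "M2") is None
        assert table.get(flags[0].offspring, "M2") is not None


# ---------------------------------------------------------------------------
# map estimation


class TestEstimateMap:
    def test_interval_closed_form(self):
        """R = 2 of N = 20 maternal meioses: theta_f = 0.1 ->
        25 ln(1.5) = 10.14 cM; no male data -> male length undefined."""
        inds = [Individual("gs", None, None, "male"),
                Individual("gd", None, None, "female"),
                Individual("dam", "gs", "gd", "female"),
                Individual("sire", None, None, "male")]
        inds += [Individual(f"kid{i}", "sire", "dam", "female")
                 for i in range(20)]
        ped = Pedigree(inds)
        t = GenotypeTable(["M0", "M1"])
        for m in ("M0", "M1"):
            t.set("gs", m, ("C", "C"))
            t.set("gd", m, ("D", "D"))
            t.set("dam", m, ("C", "D"))
            t.set("sire", m, ("E", "E"))
        for i in range(20):
            t.set(f"kid{i}", "M0", ("C", "E"))
            t.set(f"kid{i}", "M1", ("D" if i < 2 else "C", "E"))
        panel = phase_meioses(ped, t)
        lg = estimate_map(["M0", "M1"], panel)
        iv = lg.intervals[0]
        assert iv.theta_f == pytest.approx(0.1, abs=1e-9)
        assert iv.cm_f == pytest.approx(25 * math.log(1.5), abs=1e-6)
        assert iv.n_f == 20 and iv.n_m == 0
        assert iv.cm_m is None
        assert lg.length("m") == 0.0

    def test_colocated_markers_share_position(self):
        panel, _, _ = build_phase_known_panel(["AA"] * 30)
        lg = estimate_map(["M0", "M1"], panel)
        assert lg.intervals[0].theta_avg == 0.0
        assert lg.co_located_sets() == [["M0", "M1"]]
        assert lg.n_unique_positions == 1

    def test_positions_are_prefix_sums(self, small_panel, small_study):
        order = small_study.true_map.markers["chr1"]
        lg = estimate_map(order, small_panel)
        pos = lg.positions("avg")
        cum = 0.0
        for iv in lg.intervals:
            cum += iv.cm_avg if iv.cm_avg is not None else 0.0
            assert pos[iv.right] == pytest.approx(cum)

    def test_adding_marker_never_shrinks_span(self, small_panel,
                                              small_study):
        order = small_study.true_map.markers["chr1"]
        short = estimate_map(order[:-1], small_panel).length("avg")
        full = estimate_map(order, small_panel).length("avg")
        assert full >= short - 1e-6


class TestSplitLongIntervals:
    def _map(self, cms, name="LG1"):
        markers = [f"m{i}" for i in range(len(cms) + 1)]
        ivs = [Interval(markers[i], markers[i + 1], 0.2, 0.2, 0.2,
                        cm, cm, cm, 10, 5, 5) for i, cm in enumerate(cms)]
        return LinkageMap([LinkageGroup(name, markers, ivs)])

    def test_interval_above_limit_splits(self):
        out, log = split_long_intervals(self._map([10.0, 51.0, 10.0]), 50.0)
        assert [g.markers for g in out.groups] == [["m0", "m1"], ["m2", "m3"]]
        assert len(log) == 1 and "split" in log[0]

    def test_override_keeps_group(self):
        out, log = split_long_intervals(self._map([10.0, 51.0, 10.0]), 50.0,
                                        keep_together=[("m1", "m2")])
        assert len(out.groups) == 1
        assert "override" in log[0]

    def test_all_short_unchanged(self):
        lmap = self._map([10.0, 49.9])
        out, log = split_long_intervals(lmap, 50.0)
        assert out.groups == lmap.groups and log == []

    def test_undefined_interval_splits(self):
        lmap = self._map([10.0, 10.0])
        lmap.groups[0].intervals[1].cm_avg = None
        out, _ = split_long_intervals(lmap, 50.0)
        assert len(out.groups) == 2


class TestOrientOrder:
    def test_reference_orientation(self):
        ref = {"a": ("chr1", 0.0), "c": ("chr1", 30.0)}
        assert orient_order(["c", "b", "a"], ref) == ["a", "b", "c"]
        assert orient_order(["a", "b", "c"], ref) == ["a", "b", "c"]

    def test_lexicographic_fallback(self):
        assert orient_order(["z", "m", "a"], None) == ["a", "m", "z"]
        assert orient_order(["a", "m", "z"], None) == ["a", "m", "z"]


# ---------------------------------------------------------------------------
# panel-level invariants


class TestPanelInvariants:
    def test_lod_nonnegative_at_mle(self, small_panel):
        for r in twopoint_all(small_panel, small_panel.markers[:4]):
            assert r.lod >= 0.0

    @given(st.integers(min_value=0, max_value=30),
           st.integers(min_value=1, max_value=30))
    @settings(max_examples=60, deadline=None)
    def test_phase_known_mle_closed_form(self, r, extra):
        n = r + extra
        stats = PairStats(R=r, N=n)
        th, _ll = mle_theta(stats)
        assert th == pytest.approx(min(r / n, 0.5), abs=1e-9)

    def test_population_subset_partitions_panel(self, small_panel):
        pops = {t.population for t in small_panel.transmissions}
        total = sum(len(small_panel.subset_population(p).transmissions)
                    for p in pops)
        assert total == len(small_panel.transmissions)
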