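"""Gene-pair alteration patterns and node-level reports."""
import numpy as np
import pandas as pd
import pytest

from altpath import (ActivityProfile, GROUP1_ACTIVE, GROUP2_ACTIVE, NS, PATTERN1,
                     PairStateCounts, SampleGroups, assign_pattern,
                     node_activity_report, pair_state_counts, pattern_scan,
                     pattern_type)
from altpath.patterns import test_transition as transition_test
from altpath.patterns import STATES, TRANSITIONS

from _oracles import fisher_greater
from conftest import random_dataset


def _counts(c1, c2):
    full1 = {s: c1.get(s, 0) for s in STATES}
    full2 = {s: c2.get(s, 0) for s in STATES}
    return PairStateCounts("A", "B", full1, full2)


class TestPatternTypes:
    def test_partition_of_the_twelve_transitions(self):
        kinds = [pattern_type(a, b) for a, b in TRANSITIONS]
        assert len(TRANSITIONS) == 12
        assert kinds.count(2) == 8 and kinds.count(3) == 2 and kinds.count(4) == 2

    def test_concordant_and_inverse_assignments(self):
        assert pattern_type("00", "11") == 3
        assert pattern_type("01", "10") == 4
        assert pattern_type("00", "10") == 2

    def test_identical_states_rejected(self):
        with pytest.raises(ValueError):
            pattern_type("01", "01")


class TestPairStateCounts:
    def test_degenerate_pair_all_mass_on_one_state(self):
        samples = [f"s{i}" for i in range(6)]
        frame = pd.DataFrame([[1] * 6, [0] * 6], index=["A", "B"], columns=samples)
        groups = SampleGroups({s: ("g1" if i < 3 else "g2")
                               for i, s in enumerate(samples)}, "g1", "g2")
        counts = pair_state_counts(ActivityProfile(frame), "A", "B", groups)
        assert counts.group1 == {"00": 0, "01": 0, "10": 3, "11": 0}
        assert counts.group2["10"] == 3

    def test_counts_conserve_group_sizes(self, small_profile, small_groups):
        counts = pair_state_counts(small_profile, "g0", "g1", small_groups)
        assert sum(counts.group1.values()) == 6
        assert sum(counts.group2.values()) == 6

    def test_counts_match_per_sample_tally(self, small_profile, small_groups):
        counts = pair_state_counts(small_profile, "g2", "g3", small_groups)
        act = small_profile.activity
        tally = {st: 0 for st in STATES}
        for s in small_groups.group1_samples:
            tally[f"{act.loc['g2', s]}{act.loc['g3', s]}"] += 1
        assert counts.group1 == tally

    def test_missing_gene_named_in_error(self, small_profile, small_groups):
        with pytest.raises(ValueError, match="'zz'"):
            pair_state_counts(small_profile, "g0", "zz", small_groups)


class TestTransitionTest:
    def test_planted_inversion_is_significant(self):
        counts = _counts({"10": 30, "01": 5}, {"10": 5, "01": 30})
        t = transition_test(counts, "10", "01")
        assert t.p_value == pytest.approx(fisher_greater(30, 5, 5, 30), abs=1e-12)
        assert t.p_value < 0.05 and t.pattern_type == 4

    def test_symmetric_counts_never_significant(self):
        counts = _counts({"10": 10, "01": 10}, {"10": 10, "01": 10})
        for frm, to in TRANSITIONS:
            assert transition_test(counts, frm, to).p_value >= 0.5

    def test_empty_table_gives_p_one(self):
        counts = _counts({"11": 5}, {"11": 5})
        assert transition_test(counts, "00", "01").p_value == 1.0


class TestAssignPattern:
    def test_gate_skips_double_ns_pairs(self):
        counts = _counts({"10": 30, "01": 5}, {"10": 5, "01": 30})
        out = assign_pattern(counts, NS, NS)
        assert out.assigned == PATTERN1 and out.min_p is None

    def test_gate_can_be_disabled(self):
        counts = _counts({"10": 30, "01": 5}, {"10": 5, "01": 30})
        out = assign_pattern(counts, NS, NS, gate=False)
        assert out.assigned == "10->01"

    def test_minimal_p_among_significant_transitions_wins(self):
        # an inverse-dominant pair: several transitions significant, the
        # 01->10 shift overwhelmingly strongest
        counts = _counts({"00": 15, "01": 25, "11": 5}, {"00": 5, "10": 25, "11": 15})
        out = assign_pattern(counts, GROUP1_ACTIVE, NS)
        sig_keys = {(t.from_state, t.to_state) for t in out.significant}
        assert {("00", "10"), ("00", "11"), ("01", "10"), ("01", "11")} <= sig_keys
        assert out.assigned == "01->10" and out.pattern_type == 4
        assert out.min_p == min(t.p_value for t in out.significant)

    def test_no_significant_transition_falls_back_to_pattern1(self):
        counts = _counts({"00": 5, "11": 5}, {"00": 5, "11": 5})
        out = assign_pattern(counts, GROUP1_ACTIVE, NS)
        assert out.assigned == PATTERN1

    def test_reversal_symmetry_of_assignments(self):
        profile, groups = random_dataset(23, n_genes=20)
        cls = pd.DataFrame({"class": GROUP1_ACTIVE}, index=profile.gene_ids)
        for a, b in [("g000", "g001"), ("g002", "g003"), ("g004", "g005")]:
            fwd = assign_pattern(pair_state_counts(profile, a, b, groups),
                                 GROUP1_ACTIVE, GROUP1_ACTIVE)
            rev = assign_pattern(pair_state_counts(profile, a, b, groups.swapped()),
                                 GROUP1_ACTIVE, GROUP1_ACTIVE)
            fwd_sig = {(t.from_state, t.to_state): t.p_value for t in fwd.significant}
            rev_sig = {(t.to_state, t.from_state): t.p_value for t in rev.significant}
            assert fwd_sig.keys() == rev_sig.keys()
            for key in fwd_sig:
                assert fwd_sig[key] == pytest.approx(rev_sig[key], abs=1e-12)


class TestPatternScan:
    def test_empty_pair_list(self, small_profile, small_groups):
        cls = pd.DataFrame({"class": NS}, index=small_profile.gene_ids)
        assert pattern_scan(small_profile, [], cls, small_groups) == []

    def test_identical_groups_yield_pattern1_everywhere(self):
        rng = np.random.default_rng(5)
        half = rng.integers(0, 2, size=(10, 15), dtype=np.int8)
        mat = np.concatenate([half, half], axis=1)
        samples = [f"a{i}" for i in range(15)] + [f"b{i}" for i in range(15)]
        genes = [f"g{i}" for i in range(10)]
        profile = ActivityProfile(pd.DataFrame(mat, index=genes, columns=samples))
        groups = SampleGroups({s: ("g1" if s.startswith("a") else "g2")
                               for s in samples}, "g1", "g2")
        cls = pd.DataFrame({"class": GROUP1_ACTIVE}, index=genes)
        pairs = [(genes[i], genes[i + 1]) for i in range(0, 9, 2)]
        out = pattern_scan(profile, pairs, cls, groups)
        assert all(a.assigned == PATTERN1 for a in out)

    def test_planted_inversions_recovered(self):
        # 20 pairs, 5 with planted 01-dominant -> 10-dominant inversion
        rng = np.random.default_rng(1)
        n = 43
        samples = [f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)]
        groups = SampleGroups({s: ("g1" if s.startswith("a") else "g2")
                               for s in samples}, "g1", "g2")
        rows, genes = [], []
        for k in range(20):
            ga, gb = f"A{k:02d}", f"B{k:02d}"
            genes += [ga, gb]
            if k < 5:  # inversion: group1 mostly 01, group2 mostly 10
                a = np.concatenate([rng.random(n) < 0.15, rng.random(n) < 0.85])
                b = np.concatenate([rng.random(n) < 0.85, rng.random(n) < 0.15])
            else:
                a = rng.random(2 * n) < 0.5
                b = rng.random(2 * n) < 0.5
            rows += [a.astype(np.int8), b.astype(np.int8)]
        profile = ActivityProfile(pd.DataFrame(np.stack(rows), index=genes,
                                               columns=samples))
        cls = pd.DataFrame({"class": GROUP1_ACTIVE}, index=genes)
        pairs = [(f"A{k:02d}", f"B{k:02d}") for k in range(20)]
        out = {(a.gene_a, a.gene_b): a for a in pattern_scan(profile, pairs, cls, groups)}
        recovered = sum(out[(f"A{k:02d}", f"B{k:02d}")].assigned == "01->10"
                        for k in range(5))
        assert recovered >= 4

    def test_unmeasured_pairs_skipped(self, small_profile, small_groups):
        cls = pd.DataFrame({"class": NS}, index=small_profile.gene_ids)
        out = pattern_scan(small_profile, [("g0", "nope")], cls, small_groups)
        assert out == []


class TestNodeReport:
    def test_alternative_node_flagged(self):
        node_map = pd.DataFrame({
            "pathway": ["calcium"] * 7,
            "node": ["CALM"] * 7,
            "gene": [f"CALM{i}" for i in range(7)],
        })
        cls = pd.DataFrame({"class": [GROUP1_ACTIVE, GROUP1_ACTIVE, GROUP2_ACTIVE,
                                      GROUP2_ACTIVE, NS, NS, NS]},
                           index=[f"CALM{i}" for i in range(7)])
        (report,) = node_activity_report(node_map, cls)
        assert report.alternative
        assert set(report.group1_active) == {"CALM0", "CALM1"}
        assert set(report.group2_active) == {"CALM2", "CALM3"}

    def test_all_ns_node_not_flagged(self):
        node_map = pd.DataFrame({"pathway": ["p"], "node": ["N"], "gene": ["g1"]})
        cls = pd.DataFrame({"class": [NS]}, index=["g1"])
        (report,) = node_activity_report(node_map, cls)
        assert not report.alternative and report.group1_active == ()

    def test_report_equals_relational_join(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        cls = pd.DataFrame({"class": rng.choice([GROUP1_ACTIVE, GROUP2_ACTIVE, NS],
                                                size=30)}, index=genes)
        node_map = pd.DataFrame({
            "pathway": ["pw"] * 30,
            "node": [f"N{i % 5}" for i in range(30)],
            "gene": genes,
        })
        reports = {r.node: r for r in node_activity_report(node_map, cls)}
        for node, sub in node_map.groupby("node"):
            expect_g1 = sorted(g for g in sub["gene"]
                               if cls.loc[g, "class"] == GROUP1_ACTIVE)
            assert list(reports[node].group1_active) == expect_g1
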