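"""Structure learning: local scores, search behaviour, CPDAG handling."""
import math

import numpy as np
import pandas as pd
import pytest

from altpath import (ActivityProfile, Cpdag, GesConfig, bic_local_score,
                     dag_to_cpdag, ges_fit, load_network, save_network,
                     simulate_from_dag)

from _oracles import (all_three_node_dags, dag_loglik_score, dag_skeleton,
                      dag_v_structures)


def _profile(mat, genes, n=None):
    n = n or mat.shape[1]
    return ActivityProfile(pd.DataFrame(mat, index=genes,
                                        columns=[f"s{i}" for i in range(n)]))


class TestLocalScore:
    def test_degenerate_all_ones_node(self):
        prof = _profile(np.ones((2, 50), dtype=np.int8), ["A", "B"])
        score = bic_local_score("A", [], prof, penalty_discount=6.0)
        assert score == pytest.approx(-6.0 * 0.5 * math.log(50))

    def test_fair_coin_closed_form(self):
        mat = np.zeros((2, 100), dtype=np.int8)
        mat[0, :50] = 1
        prof = _profile(mat, ["A", "B"])
        score = bic_local_score("A", [], prof, penalty_discount=2.0)
        assert score == pytest.approx(100 * math.log(0.5) - 2.0 * 0.5 * math.log(100))

    def test_matches_independent_tabulation_with_parents(self):
        prof = simulate_from_dag({"A": (), "B": ("A",), "C": ("A", "B")},
                                 0.8, 300, seed=2)
        data = prof.activity.to_numpy().T
        names = list(prof.activity.index)
        parentless = {v: () for v in names}
        base = dag_loglik_score(data, names, parentless, 6.0)
        for child, parents in [("B", ("A",)), ("C", ("A", "B")), ("A", ())]:
            # decomposability: swapping one node's parent set shifts the
            # total by exactly the local-score difference
            dag = dict(parentless)
            dag[child] = parents
            delta_oracle = dag_loglik_score(data, names, dag, 6.0) - base
            delta_pkg = (bic_local_score(child, parents, prof, 6.0)
                         - bic_local_score(child, (), prof, 6.0))
            assert delta_pkg == pytest.approx(delta_oracle, rel=1e-9, abs=1e-9)

    def test_independent_parent_rarely_helps_with_high_penalty(self):
        # with PD = 6 an irrelevant parent should essentially never pay for itself
        wins = 0
        for seed in range(30):
            prof = simulate_from_dag({"A": (), "B": ()}, 0.9, 200, seed=seed)
            with_parent = bic_local_score("B", ["A"], prof, 6.0)
            without = bic_local_score("B", [], prof, 6.0)
            wins += with_parent > without
        assert wins == 0


class TestGesFit:
    def test_independent_coins_give_empty_graph(self):
        hits = 0
        for seed in range(10):
            prof = simulate_from_dag({c: () for c in "ABCD"}, 0.9, 1000, seed=seed)
            net = ges_fit(prof)
            hits += net.n_edges == 0
        assert hits >= 9

    def test_single_strong_edge_is_undirected(self):
        prof = simulate_from_dag({"A": (), "B": ("A",)}, 0.9, 1000, seed=1)
        net = ges_fit(prof)
        assert net.directed == frozenset()
        assert net.undirected == frozenset({frozenset({"A", "B"})})

    def test_collider_is_oriented(self):
        prof = simulate_from_dag({"A": (), "B": (), "C": ("A", "B")}, 0.9, 2000, seed=3)
        net = ges_fit(prof)
        assert ("A", "C") in net.directed and ("B", "C") in net.directed

    def test_chain_skeleton_without_shortcut(self):
        good = 0
        for seed in range(10):
            prof = simulate_from_dag({"A": (), "B": ("A",), "C": ("B",)},
                                     0.9, 2000, seed=seed)
            net = ges_fit(prof)
            skel = {tuple(sorted(e)) for e in net.skeleton()}
            good += skel == {("A", "B"), ("B", "C")}
        assert good >= 9

    def test_score_trace_non_decreasing(self):
        prof = simulate_from_dag({"A": (), "B": ("A",), "C": ("B",), "D": ()},
                                 0.85, 800, seed=11)
        _, trace = ges_fit(prof, return_trace=True)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_constant_gene_dropped_but_kept_as_isolated_node(self):
        prof = simulate_from_dag({"A": (), "B": ("A",)}, 0.9, 500, seed=5)
        act = prof.activity.copy()
        act.loc["Z"] = 1
        net = ges_fit(ActivityProfile(act))
        assert "Z" in net.nodes
        assert all("Z" not in e for e in net.skeleton())

    def test_three_node_class_contains_a_top_scoring_dag(self):
        # exhaustive oracle: score all 25 DAGs; the returned equivalence
        # class must contain one with the maximal penalised score
        for seed in range(8):
            parents_truth = {"A": (), "B": ("A",), "C": ("B",)} if seed % 2 else \
                            {"A": (), "B": (), "C": ("A", "B")}
            prof = simulate_from_dag(parents_truth, 0.85, 600, seed=seed)
            net = ges_fit(prof)
            names = sorted(net.nodes)
            data = prof.activity.loc[names].to_numpy().T
            scores = [(dag_loglik_score(data, names, dag, 6.0), dag)
                      for dag in all_three_node_dags(names)]
            top = max(s for s, _ in scores)
            top_dags = [d for s, d in scores if s >= top - 1e-9]
            skel = net.skeleton()
            vs = net.v_structures()
            assert any(dag_skeleton({k: set(v) for k, v in d.items()}) == skel and
                       dag_v_structures({k: set(v) for k, v in d.items()}) == vs
                       for d in top_dags)

    def test_depth_caps_parent_sets(self):
        prof = simulate_from_dag({"A": (), "B": (), "C": ("A", "B")}, 0.9, 2000, seed=3)
        net = ges_fit(prof, GesConfig(penalty_discount=6.0, depth=1))
        parents = {}
        for u, v in net.directed:
            parents.setdefault(v, set()).add(u)
        assert all(len(ps) <= 1 for ps in parents.values())

    def test_too_few_samples_rejected(self):
        prof = _profile(np.array([[0, 1], [1, 0]], dtype=np.int8), ["A", "B"])
        with pytest.raises(ValueError, match="at least 10 samples"):
            ges_fit(prof)


class TestCpdagValidation:
    def test_two_cycle_rejected(self):
        with pytest.raises(ValueError, match="2-cycle"):
            Cpdag(("A", "B"), frozenset({("A", "B"), ("B", "A")}), frozenset())

    def test_directed_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            Cpdag(("A", "B", "C"),
                  frozenset({("A", "B"), ("B", "C"), ("C", "A")}), frozenset())

    def test_dag_to_cpdag_chain_is_fully_undirected(self):
        cp = dag_to_cpdag(["A", "B", "C"], {"A": set(), "B": {"A"}, "C": {"B"}})
        assert cp.directed == frozenset()
        assert len(cp.undirected) == 2

    def test_dag_to_cpdag_keeps_collider(self):
        cp = dag_to_cpdag(["A", "B", "C"], {"A": set(), "B": set(), "C": {"A", "B"}})
        assert cp.directed == frozenset({("A", "C"), ("B", "C")})


class TestNetworkFiles:
    def test_edge_list_roundtrip(self, tmp_path):
        net = Cpdag(("A", "B", "C"), frozenset({("A", "B")}),
                    frozenset({frozenset({"B", "C"})}))
        save_network(net, tmp_path / "net.tsv")
        back = load_network(tmp_path / "net.tsv")
        assert back.directed == net.directed and back.undirected == net.undirected

    def test_single_directed_row(self, tmp_path):
        (tmp_path / "n.tsv").write_text("source\ttarget\ttype\nA\tB\tdirected\n")
        net = load_network(tmp_path / "n.tsv")
        assert net.directed == frozenset({("A", "B")})

    def test_contradictory_rows_rejected(self, tmp_path):
        (tmp_path / "n.tsv").write_text(
            "source\ttarget\ttype\nA\tB\tdirected\nB\tA\tdirected\n")
        with pytest.raises(ValueError, match="2-cycle"):
            load_network(tmp_path / "n.tsv")
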