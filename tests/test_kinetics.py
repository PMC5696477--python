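import random

import networkx as nx
import pytest

from jetcool import kinetics
from jetcool.ensemble_io import BarrierRecord
from jetcool.structure import StructuralType

T = StructuralType.from_label


class TestClassifyBarrier:
    @pytest.mark.parametrize(
        "dg, cls",
        [
            (1.5, "low"),
            (2.5, "medium"),
            (8.0, "high"),
            (2.0, "low"),  # inclusive boundary
            (2.0000001, "medium"),
            (7.9999999, "medium"),
            (0.0, "low"),
            (15.0, "high"),
        ],
    )
    def test_classes_and_boundaries(self, dg, cls):
        assert kinetics.classify_barrier(dg) == cls

    def test_negative_barrier_rejected(self):
        with pytest.raises(ValueError):
            kinetics.classify_barrier(-0.1)

    def test_configurable_thresholds(self):
        assert kinetics.classify_barrier(3.0, low_max=3.5) == "low"
        assert kinetics.classify_barrier(7.0, high_min=6.0) == "high"


class TestPredictBarrierClass:
    @pytest.mark.parametrize(
        "a, b, cls",
        [
            # backbone refolding is high
            ("A1-γ_L(F)-g+/+", "A1-γ_D(F)-g+/+", "high"),
            ("A1-ε_D(E)-g+/+", "A1-γ_D(F)-g+/+", "high"),
            ("A1-β(E)-g+/+", "A1-γ_D(F)-g+/+", "high"),
            # side-chain change within extended backbones is medium
            ("A1-ε_D(E)-g+/+", "A1-ε_D(E)-g−/+", "medium"),
            ("A1-β(E)-g+/+", "A1-β(E)-g+/−", "medium"),
            # same side-chain type, extended backbones (beta<->epsilon) is low
            ("A1-β(E)-g+/+", "A1-ε_D(E)-g+/+", "low"),
            ("A2-ε_L(E)-g+/+", "A1-β(E)-g+/+", "low"),  # terminus swing only
            # same folded backbone, same side chain: terminal rotation only
            ("A1-γ_D(F)-g+/+", "A2-γ_D(F)-g+/+", "low"),
            ("A1-γ_D(F)-g+/+", "A1-γ_D(F)-g−/−", "medium"),
        ],
    )
    def test_rules(self, a, b, cls):
        assert kinetics.predict_barrier_class(T(a), T(b)) == cls
        assert kinetics.predict_barrier_class(T(b), T(a)) == cls  # symmetric

    def test_untyped_rejected(self):
        with pytest.raises(ValueError):
            kinetics.predict_barrier_class(
                StructuralType("U", "β", "g+", "+"), T("A1-β(E)-g+/+")
            )


class TestConversionGraph:
    def test_same_side_chain_family_fully_connected(self):
        types = {f"e{i}": T("A1-β(E)-g+/+") for i in range(4)}
        g = kinetics.build_conversion_graph(types, types=types)
        assert nx.number_connected_components(g) == 1

    def test_folded_conformer_isolated_among_extended(self):
        types = {
            "f": T("A1-γ_D(F)-g+/+"),
            "e1": T("A1-β(E)-g+/+"),
            "e2": T("A1-ε_D(E)-g+/+"),
        }
        g = kinetics.build_conversion_graph(types, types=types)
        assert g.degree["f"] == 0
        assert g.has_edge("e1", "e2")

    def test_empty_ensemble(self):
        g = kinetics.build_conversion_graph([])
        assert len(g) == 0

    def test_explicit_barriers_override_type_prediction(self):
        # type heuristic says low, measured barrier says medium -> no edge
        types = {"a": T("A1-β(E)-g+/+"), "b": T("A1-ε_D(E)-g+/+")}
        barriers = [BarrierRecord(("a", "b"), 3.4)]
        g = kinetics.build_conversion_graph(types, types=types, barriers=barriers)
        assert not g.has_edge("a", "b")
        # and the reverse: heuristic says high, measured barrier is low
        types2 = {"a": T("A1-γ_D(F)-g+/+"), "b": T("A1-β(E)-g+/+")}
        g2 = kinetics.build_conversion_graph(
            types2, types=types2, barriers=[BarrierRecord(("a", "b"), 1.2)]
        )
        assert g2.has_edge("a", "b")


def brute_force_partition(ids, edges):
    """Oracle: transitive closure by repeated sweeps (no graph library)."""
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        parent[ra] = rb
    groups = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(v) for v in groups.values()}


class TestPooling:
    def _yg_450(self):
        return {
            "yg12": 1.88, "yg14": 8.65, "yg19": 1.58, "yg58": 1.90,
            "yg17": 8.10, "yg18": 1.10, "yg25": 1.55,
        }

    def test_reference_gpp_family_pools_to_14(self):
        g = nx.Graph()
        members = ["yg12", "yg14", "yg19", "yg58"]
        g.add_edges_from(zip(members, members[1:]))
        g.add_nodes_from(["yg17", "yg18", "yg25"])
        g.add_edges_from([("yg17", "yg18"), ("yg18", "yg25")])
        basins = kinetics.pool_populations(
            g, self._yg_450(), g_at_tref={"yg14": 0.0, "yg17": 0.0},
        )
        by_sink = {b.sink: b for b in basins}
        assert by_sink["yg14"].pooled_population == pytest.approx(14.01)
        assert round(by_sink["yg14"].pooled_population) == 14
        assert by_sink["yg17"].pooled_population == pytest.approx(10.75)
        assert round(by_sink["yg17"].pooled_population) == 11
        assert by_sink["yg14"].observable and by_sink["yg17"].observable

    def test_singleton_basin_keeps_own_population(self):
        g = nx.Graph()
        g.add_node("x")
        (b,) = kinetics.pool_populations(g, {"x": 5.5})
        assert b.sink == "x" and b.pooled_population == 5.5 and not b.observable

    def test_missing_population_names_the_node(self):
        g = nx.Graph()
        g.add_edge("a", "b")
        with pytest.raises(KeyError, match="b"):
            kinetics.pool_populations(g, {"a": 1.0})

    def test_sink_tie_breaks_on_energy_then_id(self):
        g = nx.Graph()
        g.add_edge("b", "a")
        (basin,) = kinetics.pool_populations(
            g, {"a": 1.0, "b": 2.0}, g_at_tref={"a": 0.0, "b": 0.0},
            e_rel={"a": 0.5, "b": 0.1},
        )
        assert basin.sink == "b"  # lower electronic energy wins the G tie
        (basin2,) = kinetics.pool_populations(
            g, {"a": 1.0, "b": 2.0}, g_at_tref={"a": 0.0, "b": 0.0},
        )
        assert basin2.sink == "a"  # lexicographic fallback

    def test_mass_conservation_and_oracle_on_random_graphs(self):
        rng = random.Random(20260920)
        for trial in range(40):
            n = rng.randint(1, 12)
            ids = [f"n{i}" for i in range(n)]
            edges = [
                (a, b)
                for i, a in enumerate(ids)
                for b in ids[i + 1 :]
                if rng.random() < 0.25
            ]
            g = nx.Graph()
            g.add_nodes_from(ids)
            g.add_edges_from(edges)
            pops = {i: rng.uniform(0, 10) for i in ids}
            total = sum(pops.values())
            basins = kinetics.pool_populations(g, pops)
            assert sum(b.pooled_population for b in basins) == pytest.approx(
                total, abs=1e-9
            )
            assert {b.members for b in basins} == brute_force_partition(ids, edges)
            covered = set().union(*(b.members for b in basins))
            assert covered == set(ids)  # basins partition the node set

    def test_relabelling_invariance(self):
        rng = random.Random(7)
        ids = [f"n{i}" for i in range(8)]
        edges = [("n0", "n1"), ("n1", "n2"), ("n4", "n5")]
        pops = {i: rng.uniform(0, 10) for i in ids}
        g = nx.Graph()
        g.add_nodes_from(ids)
        g.add_edges_from(edges)
        base = kinetics.pool_populations(g, pops)
        mapping = {i: f"x_{i}" for i in ids}
        g2 = nx.relabel_nodes(g, mapping)
        pops2 = {mapping[k]: v for k, v in pops.items()}
        relab = kinetics.pool_populations(g2, pops2)
        assert {
            frozenset(mapping[m] for m in b.members): round(b.pooled_population, 12)
            for b in base
        } == {b.members: round(b.pooled_population, 12) for b in relab}

    def test_raising_barrier_never_merges_basins(self):
        # monotone refinement: dropping an edge cannot decrease basin count
        types = {f"c{i}": T("A1-β(E)-g+/+") for i in range(5)}
        pops = {c: 20.0 for c in types}
        low = kinetics.build_conversion_graph(types, types=types)
        n_low = len(kinetics.pool_populations(low, pops))
        for u, v in list(low.edges):
            barriers = [BarrierRecord((u, v), 5.0)]  # raise one barrier to medium
            g = kinetics.build_conversion_graph(types, types=types, barriers=barriers)
            assert len(kinetics.pool_populations(g, pops)) >= n_low


class TestObservability:
    def _basins(self, pooled):
        return [
            kinetics.BasinResult(frozenset({f"s{i}"}), f"s{i}", p, p > 8.0)
            for i, p in enumerate(pooled)
        ]

    def test_threshold_is_strict_and_sorted(self):
        obs = kinetics.observable_conformers(self._basins([5.0, 14.0, 8.0, 9.0]))
        assert obs == [("s1", 14.0), ("s3", 9.0)]

    def test_all_below_threshold(self):
        assert kinetics.observable_conformers(self._basins([5.0, 5.0])) == []

    def test_zero_threshold_returns_everything(self):
        assert len(kinetics.observable_conformers(self._basins([1.0, 2.0]), 0)) == 2
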