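import numpy as np
import pytest

from ddadia.crossmode import (CrossModeConfig, build_cross_network,
                              merge_into_dia, retain_cross_mode,
                              run_crossmode, select_dda_components)
from ddadia.models import (Feature, FeatureTable, Mode, MolecularNetwork,
                           SimilarityEdge, Spectrum)
from ddadia.networking import component_stats

from conftest import make_spectrum


def net_from_edges(nodes, edges, mode=Mode.DDA):
    net = MolecularNetwork()
    for n in nodes:
        net.add_node(n, 500.0, 10.0, mode)
    for a, b in edges:
        net.add_edge(SimilarityEdge(a, b, 0.9, 5, 0.0))
    net.label_components()
    return net


class TestSelectComponents:
    def test_four_node_path_selected(self):
        net = net_from_edges("ABCD", [("A", "B"), ("B", "C"), ("C", "D")])
        assert select_dda_components(net) == {"A", "B", "C", "D"}

    def test_three_node_triangle_rejected(self):
        net = net_from_edges("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        assert select_dda_components(net) == set()

    def test_four_nodes_two_edges_rejected(self):
        net = net_from_edges("ABCD", [("A", "B"), ("C", "D")])
        assert select_dda_components(net) == set()

    def test_inclusive_variant(self):
        net = net_from_edges("ABC", [("A", "B"), ("B", "C"), ("A", "C")])
        cfg = CrossModeConfig(nodes_strict=False)
        assert select_dda_components(net, cfg) == {"A", "B", "C"}

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_over_component_stats(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        ids = [f"N{i:02d}" for i in range(n)]
        edges, seen = [], set()
        for _ in range(int(rng.integers(0, 2 * n))):
            i, j = rng.choice(n, 2, replace=False)
            key = frozenset((i, j))
            if key not in seen:
                seen.add(key)
                edges.append((ids[i], ids[j]))
        net = net_from_edges(ids, edges)
        cfg = CrossModeConfig()
        expected = set()
        for row in component_stats(net).itertuples():
            if row.n_nodes > 3 and row.n_edges >= 3:
                expected |= set(net.components[row.component_id])
        assert select_dda_components(net, cfg) == expected


def dia_table(rows):
    return FeatureTable([Feature(fid, mz, rt, 5000.0, fid, Mode.DIA)
                         for fid, mz, rt in rows], mode=Mode.DIA)


class TestMergeIntoDia:
    def test_match_within_both_tolerances(self):
        dda = [Feature("DDA_1", 301.0354, 10.00, 8000.0, "DDA_1", Mode.DDA)]
        dia = dia_table([("DIA_1", 301.0360, 10.03)])
        res = merge_into_dia(dda, dia)
        assert len(res.table) == 2
        (cand,) = res.matches["DDA_1"]
        assert cand.dia_id == "DIA_1" and cand.primary

    def test_rt_outside_tolerance_not_matched(self):
        dda = [Feature("DDA_1", 301.0354, 10.00, 8000.0, "DDA_1", Mode.DDA)]
        dia = dia_table([("DIA_1", 301.0354, 10.06)])
        res = merge_into_dia(dda, dia)
        assert res.matches["DDA_1"] == []
        assert len(res.table) == 2  # inserted regardless

    def test_multiple_matches_best_flagged_primary(self):
        dda = [Feature("DDA_1", 301.0354, 10.00, 8000.0, "DDA_1", Mode.DDA)]
        dia = dia_table([("DIA_far", 301.0440, 10.04),
                         ("DIA_near", 301.0356, 10.01)])
        res = merge_into_dia(dda, dia)
        cands = {c.dia_id: c for c in res.matches["DDA_1"]}
        assert cands["DIA_near"].primary and not cands["DIA_far"].primary

    def test_id_collision_rekeyed(self):
        dda = [Feature("F1", 301.0354, 10.0, 8000.0, "F1", Mode.DDA)]
        dia = dia_table([("F1", 301.0354, 10.0)])
        res = merge_into_dia(dda, dia)
        assert res.renamed == {"F1": "DDA::F1"}
        assert set(res.table.ids()) == {"F1", "DDA::F1"}

    def test_planted_pairs_and_decoys(self):
        """50 jittered true pairs + 50 decoys outside tolerance ->
        exactly 50 primary matches."""
        rng = np.random.default_rng(31)
        dda, dia_rows = [], []
        for i in range(50):
            mz = float(rng.uniform(150, 950))
            rt = float(rng.uniform(1, 34))
            dda.append(Feature(f"DDA_{i:02d}", mz, rt, 8000.0,
                               f"DDA_{i:02d}", Mode.DDA))
            dia_rows.append((f"DIA_{i:02d}",
                             mz + float(rng.uniform(-0.008, 0.008)),
                             rt + float(rng.uniform(-0.04, 0.04))))
        for i in range(50):  # decoys: pushed outside the m/z window
            mz = float(rng.uniform(150, 950))
            dia_rows.append((f"DEC_{i:02d}", mz + 0.05,
                             float(rng.uniform(1, 34))))
        res = merge_into_dia(dda, dia_table(dia_rows))
        primaries = res.primary_pairs()
        assert len(primaries) == 50
        assert {a.replace("DDA", "DIA") for a, _ in primaries} == \
            {b for _, b in primaries}


def _paired_spectra():
    peaks = [(100.0 + 25 * i, 5000.0) for i in range(6)]
    dda = make_spectrum("DDA_1", 301.0354, peaks, rt_min=10.0, mode=Mode.DDA)
    dia = make_spectrum("DIA_1", 301.0360, peaks, rt_min=10.02, mode=Mode.DIA)
    return dda, dia


class TestBuildCrossNetwork:
    def test_same_compound_component_has_both_modes(self):
        dda_s, dia_s = _paired_spectra()
        dda_f = Feature("DDA_1", 301.0354, 10.0, 8000.0, "DDA_1", Mode.DDA)
        dia = dia_table([("DIA_1", 301.0360, 10.02)])
        merged = merge_into_dia([dda_f], dia)
        net = build_cross_network(merged, {"DDA_1": dda_s, "DIA_1": dia_s})
        assert len(net.components) == 1
        kinds = {e.kind for e in net.edges}
        assert "match" in kinds and "similarity" in kinds

    def test_feature_without_ms2_is_flagged_isolated(self):
        dda_s, _ = _paired_spectra()
        dda_f = Feature("DDA_1", 301.0354, 10.0, 8000.0, "DDA_1", Mode.DDA)
        dia = dia_table([("DIA_lone", 600.0, 25.0)])
        dia.features[0].spectrum_ref = None
        merged = merge_into_dia([dda_f], dia)
        net = build_cross_network(merged, {"DDA_1": dda_s})
        assert net.nodes["DIA_lone"]["has_ms2"] is False
        assert net.nodes["DIA_lone"]["component_id"] is not None

    def test_dda_only_component_stays_pure(self):
        peaks = [(100.0 + 25 * i, 5000.0) for i in range(6)]
        a = make_spectrum("DDA_a", 500.0, peaks, mode=Mode.DDA)
        b = make_spectrum("DDA_b", 500.0, peaks, mode=Mode.DDA)
        feats = [Feature("DDA_a", 500.0, 10.0, 8000.0, "DDA_a", Mode.DDA),
                 Feature("DDA_b", 500.0, 10.0, 8000.0, "DDA_b", Mode.DDA)]
        merged = merge_into_dia(feats, dia_table([("DIA_far", 900.0, 30.0)]))
        net = build_cross_network(
            merged, {"DDA_a": a, "DDA_b": b,
                     "DIA_far": make_spectrum("DIA_far", 900.0,
                                              [(700.0, 100.0)], mode=Mode.DIA)})
        comp_of_a = net.nodes["DDA_a"]["component_id"]
        members = net.components[comp_of_a]
        assert all(net.nodes[m]["mode"] is Mode.DDA for m in members)


class TestRetain:
    def test_same_mode_neighbours_only_not_retained(self):
        net = net_from_edges(["A", "B"], [("A", "B")], mode=Mode.DDA)
        assert retain_cross_mode(net) == []

    def test_match_edge_retains_both(self):
        net = MolecularNetwork()
        net.add_node("DDA_1", 301.0354, 10.0, Mode.DDA)
        net.add_node("DIA_1", 301.0360, 10.02, Mode.DIA)
        net.add_edge(SimilarityEdge("DDA_1", "DIA_1", None, None, -0.0006,
                                    kind="match", primary=True))
        net.label_components()
        retained = retain_cross_mode(net)
        assert {r.feature_id for r in retained} == {"DDA_1", "DIA_1"}
        assert all(len(r.linked_ids) == 1 for r in retained)
        assert all(net.nodes[r.feature_id]["retained"] for r in retained)

    def test_similarity_only_witness_mode(self):
        net = MolecularNetwork()
        net.add_node("DDA_1", 301.0354, 10.0, Mode.DDA)
        net.add_node("DIA_1", 301.0360, 10.02, Mode.DIA)
        net.add_edge(SimilarityEdge("DDA_1", "DIA_1", None, None, -0.0006,
                                    kind="match"))
        net.label_components()
        cfg = CrossModeConfig(cross_witness="similarity_only")
        assert retain_cross_mode(net, cfg) == []

    def test_output_sorted_by_component_then_id(self, default_pipeline):
        _, res = default_pipeline
        keys = [(r.component_id, r.feature_id) for r in res.retained]
        assert keys == sorted(keys)

    def test_retained_subset_of_merged_and_witnesses_verifiable(
            self, default_pipeline):
        _, res = default_pipeline
        merged_ids = set(res.merged_table.ids())
        adj = res.cross_network.adjacency()
        for r in res.retained:
            assert r.feature_id in merged_ids
            for w in r.linked_ids:
                assert any(other == w for other, _ in adj[r.feature_id])
                assert res.cross_network.nodes[w]["mode"] != r.provenance


class TestPipelineInvariants:
    def test_removing_dia_empties_retention(self, default_dataset):
        ds = default_dataset
        dda_sp = {s.spectrum_id: s for s in ds.dda_spectra}
        empty_dia = FeatureTable([], mode=Mode.DIA)
        _, _, _, _, retained = run_crossmode(dda_sp, ds.dda_table, {},
                                             empty_dia)
        assert retained == []

    def test_removing_dda_errors_out(self, default_dataset):
        ds = default_dataset
        dia_sp = {s.spectrum_id: s for s in ds.dia_spectra}
        with pytest.raises(ValueError):
            run_crossmode({}, FeatureTable([], mode=Mode.DDA), dia_sp,
                          ds.dia_table)

    def test_chain_is_deterministic(self, default_dataset):
        ds = default_dataset
        dda_sp = {s.spectrum_id: s for s in ds.dda_spectra}
        dia_sp = {s.spectrum_id: s for s in ds.dia_spectra}
        runs = [run_crossmode(dda_sp, ds.dda_table, dia_sp, ds.dia_table)
                for _ in range(2)]
        r0 = [(r.feature_id, r.provenance, r.component_id, r.linked_ids)
              for r in runs[0][4]]
        r1 = [(r.feature_id, r.provenance, r.component_id, r.linked_ids)
              for r in runs[1][4]]
        assert r0 == r1
        assert runs[0][1] == runs[1][1]

    def test_planted_cross_mode_recovery(self, default_pipeline):
        ds, res = default_pipeline
        from ddadia.simgen import evaluate
        metrics = evaluate(res.retained, ds.truth)
        assert metrics.recall >= 0.9
        assert metrics.precision >= 0.9


def test_config_validation():
    with pytest.raises(ValueError):
        CrossModeConfig(mz_match_tol=0.0)
    with pytest.raises(ValueError):
        CrossModeConfig(cross_witness="sometimes")
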