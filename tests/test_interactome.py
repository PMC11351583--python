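"""Interactome filter cascade, Pearson screen and network export."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import networkx as nx

from mirlink.de import size_factors
from mirlink.interactome import (
    InteractomeConfig,
    apply_shared_target_filter,
    apply_validation_filter,
    consensus_pairs,
    correlation_threshold,
    export_network,
    pearson_pair_correlations,
    pearson_with_p,
    read_edge_tsv,
    select_final_pairs,
)
from mirlink.io import CountMatrix, load_fixture


def predictions_from(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "tool"])


def random_prediction_table(rng, n_mirnas=5, n_genes=10, n_tools=8, density=0.3):
    rows = []
    for m in range(n_mirnas):
        for g in range(n_genes):
            for t in range(n_tools):
                if rng.random() < density:
                    rows.append((f"m{m}", f"g{g}", f"t{t}"))
    return predictions_from(rows)


class TestConsensus:
    def test_three_tools_kept(self):
        table = predictions_from([("m1", "g1", t) for t in ("T1", "T2", "T3")])
        out = consensus_pairs(["m1"], ["g1"], table, k=3)
        assert len(out) == 1 and out.loc[0, "tool_count"] == 3

    def test_two_tools_dropped_at_k3(self):
        table = predictions_from([("m1", "g1", "T1"), ("m1", "g1", "T2")])
        assert consensus_pairs(["m1"], ["g1"], table, k=3).empty

    def test_restricted_to_dem_deg_cross(self):
        table = predictions_from([("m1", "g1", t) for t in "ABC"] + [("mX", "g1", t) for t in "ABC"])
        out = consensus_pairs(["m1"], ["g1"], table, k=3)
        assert list(out["mirna"]) == ["m1"]

    def test_monotone_in_k_on_random_tables(self):
        rng = np.random.default_rng(17)
        dems = [f"m{i}" for i in range(5)]
        degs = [f"g{i}" for i in range(10)]
        for _ in range(100):
            table = random_prediction_table(rng)
            k3 = set(map(tuple, consensus_pairs(dems, degs, table, k=3)[["mirna", "gene"]].values))
            k4 = set(map(tuple, consensus_pairs(dems, degs, table, k=4)[["mirna", "gene"]].values))
            assert k4 <= k3

    def test_unknown_tool_warns(self, caplog):
        table = predictions_from([("m1", "g1", "mystery")])
        with caplog.at_level("WARNING", logger="mirlink"):
            consensus_pairs(["m1"], ["g1"], table, k=1, tool_vocabulary=["T1"])
        assert any("vocabulary" in r.message for r in caplog.records)


class TestPearson:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        r, p = pearson_with_p(x, x)
        assert r == 1.0 and p == 0.0

    def test_matches_scipy_to_1e10(self):
        rng = np.random.default_rng(5)
        for n in (5, 7, 30):
            for _ in range(50):
                x, y = rng.random(n), rng.random(n)
                r, p = pearson_with_p(x, y)
                r_ref, p_ref = stats.pearsonr(x, y)
                assert abs(r - r_ref) < 1e-10
                assert abs(p - p_ref) < 1e-10

    def test_known_p_at_r07_n7(self):
        # two-sided p for r = -0.7 at n = 7: t = -0.7*sqrt(5/0.51), df = 5
        t = -0.7 * np.sqrt(5 / (1 - 0.49))
        assert 2 * stats.t.sf(abs(t), 5) == pytest.approx(0.0799, abs=5e-4)

    def test_zero_variance_returns_nan(self):
        r, p = pearson_with_p(np.ones(5), np.arange(5.0))
        assert np.isnan(r) and np.isnan(p)

    def test_table2_mir486_arms_perfectly_correlated(self, table2):
        s = size_factors(table2)
        pairs = pd.DataFrame({"mirna": ["hsa-miR-486-5p"], "gene": ["hsa-miR-486-3p"]})
        rec = pearson_pair_correlations(pairs, table2, table2, s, s)
        assert rec.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)
        assert rec.loc[0, "n"] == 7

    def test_missing_feature_reported_skipped(self, table2):
        s = size_factors(table2)
        pairs = pd.DataFrame({"mirna": ["nope"], "gene": ["hsa-miR-1-3p"]})
        rec = pearson_pair_correlations(pairs, table2, table2, s, s)
        assert rec.loc[0, "status"] == "missing"


class TestThresholdGeometry:
    def test_joint_rule_equivalent_r_cutoff_at_n7(self):
        assert correlation_threshold(7, 0.05) == pytest.approx(0.7545, abs=5e-5)

    def test_r_minus072_at_n7_rejected(self):
        # r < -0.7 holds but p = 0.068 >= 0.05, so the joint rule rejects
        r = -0.72
        t = r * np.sqrt(5 / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), 5)
        assert p >= 0.05
        assert abs(r) < correlation_threshold(7, 0.05)


class TestValidationFilter:
    def _pairs(self):
        return pd.DataFrame({"mirna": ["m1", "m2"], "gene": ["g1", "g2"], "tool_count": [3, 3]})

    def _validated(self):
        return pd.DataFrame({"mirna": ["m1"], "gene": ["g1"], "source": ["mirtarbase"]})

    def test_present_pair_kept_and_flagged(self):
        out = apply_validation_filter(self._pairs(), self._validated(), require=True)
        assert list(out["mirna"]) == ["m1"]
        assert out.loc[0, "validated"] and out.loc[0, "sources"] == "mirtarbase"

    def test_absent_pair_dropped_when_required(self):
        out = apply_validation_filter(self._pairs(), self._validated(), require=True)
        assert "m2" not in set(out["mirna"])

    def test_passthrough_with_annotation(self):
        out = apply_validation_filter(self._pairs(), self._validated(), require=False)
        assert len(out) == 2
        assert list(out["validated"]) == [True, False]


class TestSharedTargetFilter:
    def test_shared_gene_kept(self):
        pairs = pd.DataFrame({"mirna": ["ma", "mb"], "gene": ["G", "G"]})
        assert len(apply_shared_target_filter(pairs, 2)) == 2

    def test_solo_gene_dropped(self):
        pairs = pd.DataFrame({"mirna": ["ma"], "gene": ["H"]})
        assert apply_shared_target_filter(pairs, 2).empty

    def test_matches_groupby_oracle_on_random_lists(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(1, 30))
            pairs = pd.DataFrame(
                {"mirna": rng.choice([f"m{i}" for i in range(5)], n),
                 "gene": rng.choice([f"g{i}" for i in range(8)], n)}
            ).drop_duplicates().reset_index(drop=True)
            m = int(rng.integers(1, 4))
            got = set(map(tuple, apply_shared_target_filter(pairs, m)[["mirna", "gene"]].values))
            counts = {}
            for mi, g in pairs[["mirna", "gene"]].itertuples(index=False):
                counts.setdefault(g, set()).add(mi)
            want = {
                (mi, g) for mi, g in pairs[["mirna", "gene"]].itertuples(index=False)
                if len(counts[g]) >= m
            }
            assert got == want


def toy_cascade_inputs():
    """Four candidate pairs of which exactly one survives every filter.

    (m1,g1): 3 tools, validated, strong anti-correlation      -> survives
    (m2,g1): 3 tools, validated, strong positive correlation  -> dies at correlation
    (m1,g2): 2 tools                                          -> dies at consensus
    (m2,g3): 3 tools, not validated                           -> dies at validation
    """
    samples = [f"s{j}" for j in range(7)]
    up = np.array([100, 200, 300, 400, 500, 600, 700])  # linear ramp: r(up, down) = -1
    down = up[::-1].copy()
    flat = np.full(7, 500)
    mirna = CountMatrix(pd.DataFrame([up, down], index=["m1", "m2"], columns=samples))
    mrna = CountMatrix(
        pd.DataFrame([down, flat, up], index=["g1", "g2", "g3"], columns=samples)
    )
    predictions = predictions_from(
        [("m1", "g1", t) for t in "ABC"]
        + [("m2", "g1", t) for t in "ABC"]
        + [("m1", "g2", t) for t in "AB"]
        + [("m2", "g3", t) for t in "ABC"]
    )
    validated = pd.DataFrame(
        {"mirna": ["m1", "m2"], "gene": ["g1", "g1"], "source": ["db", "db"]}
    )
    de_mirna = pd.DataFrame({"feature": ["m1", "m2"], "log2fc": [2.0, -2.0], "called": True})
    de_mrna = pd.DataFrame(
        {"feature": ["g1", "g2", "g3"], "log2fc": [-2.0, 1.0, 2.0], "called": True}
    )
    return mirna, mrna, predictions, validated, de_mirna, de_mrna


class TestSelectFinalPairs:
    def test_empty_input_empty_output(self):
        edges, counts = select_final_pairs(
            pd.DataFrame(columns=["mirna", "gene", "tool_count", "tools"]),
            pd.DataFrame(columns=["mirna", "gene", "r", "p_corr", "n", "status"]),
            pd.DataFrame(columns=["feature", "log2fc"]),
            pd.DataFrame(columns=["feature", "log2fc"]),
        )
        assert edges.empty and counts["final"] == 0

    def test_toy_cascade_single_survivor(self):
        mirna, mrna, predictions, validated, de_mirna, de_mrna = toy_cascade_inputs()
        cfg = InteractomeConfig(correlation_input="raw")
        pairs = consensus_pairs(["m1", "m2"], ["g1", "g2", "g3"], predictions, k=cfg.min_tools)
        s = pd.Series(1.0, index=mirna.sample_ids)
        correlations = pearson_pair_correlations(pairs, mirna, mrna, s, s, cfg)
        edges, counts = select_final_pairs(pairs, correlations, de_mirna, de_mrna, cfg, validated)
        assert counts == {"consensus": 3, "validated": 2, "shared": 2, "correlation": 1, "final": 1}
        assert list(zip(edges["mirna"], edges["gene"])) == [("m1", "g1")]
        assert edges.loc[0, "r"] < -0.7 and edges.loc[0, "tool_count"] == 3

    def test_validation_applied_before_sharing(self):
        # gene shared by two miRNAs but one pair unvalidated: the fixed order
        # (validation first, sharing recomputed after) eliminates both pairs
        pairs = pd.DataFrame(
            {"mirna": ["m1", "m2"], "gene": ["G", "G"], "tool_count": [3, 3], "tools": ["A,B,C"] * 2}
        )
        validated = pd.DataFrame({"mirna": ["m1"], "gene": ["G"], "source": ["db"]})
        correlations = pd.DataFrame(
            {"mirna": ["m1", "m2"], "gene": ["G", "G"], "r": [-0.95, -0.95],
             "p_corr": [0.001, 0.001], "n": 7, "status": "ok"}
        )
        de_mirna = pd.DataFrame({"feature": ["m1", "m2"], "log2fc": [2.0, 2.0]})
        de_mrna = pd.DataFrame({"feature": ["G"], "log2fc": [-2.0]})
        edges, counts = select_final_pairs(pairs, correlations, de_mirna, de_mrna, validated=validated)
        assert edges.empty
        assert counts == {"consensus": 2, "validated": 1, "shared": 0, "correlation": 0, "final": 0}

    def test_stricter_config_yields_subset(self):
        rng = np.random.default_rng(31)
        mirnas = [f"m{i}" for i in range(4)]
        genes = [f"g{i}" for i in range(8)]
        for _ in range(100):
            n = int(rng.integers(4, 20))
            pairs = pd.DataFrame(
                {"mirna": rng.choice(mirnas, n), "gene": rng.choice(genes, n),
                 "tool_count": rng.integers(1, 9, n)}
            ).drop_duplicates(["mirna", "gene"]).reset_index(drop=True)
            pairs = pairs[pairs["tool_count"] >= 3].reset_index(drop=True)
            correlations = pairs[["mirna", "gene"]].assign(
                r=rng.uniform(-1, 0, len(pairs)), p_corr=rng.uniform(0, 0.2, len(pairs)),
                n=7, status="ok",
            )
            validated = pairs[["mirna", "gene"]].assign(source="db")
            de_mirna = pd.DataFrame({"feature": mirnas, "log2fc": 2.0})
            de_mrna = pd.DataFrame({"feature": genes, "log2fc": -2.0})
            lax = InteractomeConfig(min_sharing=1, r_max=-0.5, p_max=0.1)
            strict = InteractomeConfig(min_sharing=2, r_max=-0.8, p_max=0.02)
            e_lax, _ = select_final_pairs(pairs, correlations, de_mirna, de_mrna, lax, validated)
            e_strict, _ = select_final_pairs(pairs, correlations, de_mirna, de_mrna, strict, validated)
            assert set(zip(e_strict["mirna"], e_strict["gene"])) <= set(
                zip(e_lax["mirna"], e_lax["gene"])
            )

    def test_sign_concordance_filter(self):
        pairs = pd.DataFrame(
            {"mirna": ["m1", "m2"], "gene": ["G", "G"], "tool_count": [3, 3], "tools": ["A,B,C"] * 2}
        )
        validated = pairs[["mirna", "gene"]].assign(source="db")
        correlations = pairs[["mirna", "gene"]].assign(r=-0.95, p_corr=0.001, n=7, status="ok")
        de_mirna = pd.DataFrame({"feature": ["m1", "m2"], "log2fc": [2.0, -2.0]})
        de_mrna = pd.DataFrame({"feature": ["G"], "log2fc": [-2.0]})
        edges, _ = select_final_pairs(pairs, correlations, de_mirna, de_mrna, validated=validated)
        # m2 and G share the down direction, so only (m1, G) is concordant
        assert list(edges["mirna"]) == ["m1"]


class TestExportNetwork:
    def edges_from_published(self):
        pairs = load_fixture("published_pairs")
        return pd.DataFrame(
            {"mirna": [m for m, _ in pairs], "gene": [g for _, g in pairs],
             "tool_count": 3, "validated": True, "r": -0.9, "p_corr": 0.01}
        )

    def test_published_network_node_and_edge_counts(self, tmp_path):
        edges = self.edges_from_published()
        path = tmp_path / "net.graphml"
        export_network(edges, path, format="graphml")
        graph = nx.read_graphml(path)
        assert graph.number_of_nodes() == 16
        assert graph.number_of_edges() == 11
        types = nx.get_node_attributes(graph, "type")
        assert sum(t == "mirna" for t in types.values()) == 5
        assert sum(t == "gene" for t in types.values()) == 11

    def test_empty_edge_list_valid_graph(self, tmp_path):
        empty = pd.DataFrame(columns=["mirna", "gene", "tool_count", "validated", "r", "p_corr"])
        path = tmp_path / "empty.graphml"
        export_network(empty, path, format="graphml")
        assert nx.read_graphml(path).number_of_nodes() == 0

    def test_edge_tsv_roundtrip_preserves_attributes(self, tmp_path):
        edges = self.edges_from_published()
        path = tmp_path / "edges.tsv"
        export_network(edges, path, format="edge_tsv")
        back = read_edge_tsv(path)
        for col in ("mirna", "gene", "tool_count", "validated", "r", "p_corr"):
            assert list(back[col]) == list(edges[col])
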