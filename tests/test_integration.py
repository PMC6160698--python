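import numpy as np
import pandas as pd
import pytest

from lncmetnet import (
    export_network,
    filter_mirna_targets,
    integrate,
    load_graphml,
    node_profile,
    summarize,
)


def coexpr(*pairs_with_sign):
    return pd.DataFrame(
        [{"gene_a": a, "gene_b": b, "sign": s, "r": 0.9 if s == "positive" else -0.9}
         for a, b, s in pairs_with_sign],
        columns=["gene_a", "gene_b", "sign", "r"],
    )


def ppi(*pairs):
    return pd.DataFrame(list(pairs) or None, columns=["gene_a", "gene_b"])


def mirna(*pairs):
    return pd.DataFrame(list(pairs) or None, columns=["mirna", "target"])


def nodes(**biotype):
    return pd.DataFrame(
        [{"gene": g, "biotype": b, "direction": "up", "log2_fc": 1.0}
         for g, b in biotype.items()]
    )


TOY_NODES = nodes(
    A="protein_coding", B="protein_coding", C="protein_coding",
    L1="lncRNA", M1="miRNA",
)


class TestFilterMirnaTargets:
    def test_opposite_direction_kept_same_dropped(self):
        pairs = mirna(("m1", "G1"), ("m2", "G2"))
        out = filter_mirna_targets(
            pairs, {"m1": "down", "m2": "up"}, {"G1": "up", "G2": "up"}
        )
        assert out["mirna"].tolist() == ["m1"]

    def test_unknown_direction_dropped_and_logged(self, caplog):
        pairs = mirna(("m1", "G1"), ("m2", "G2"))
        with caplog.at_level("INFO"):
            out = filter_mirna_targets(pairs, {"m1": "down"}, {"G1": "up", "G2": "up"})
        assert len(out) == 1
        assert "unknown direction" in caplog.text

    def test_malformed_direction_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            filter_mirna_targets(mirna(("m1", "G1")), {"m1": "UP?"}, {"G1": "up"})

    def test_idempotent_and_subset(self):
        pairs = mirna(("m1", "G1"), ("m2", "G2"), ("m3", "G3"))
        mdir = {"m1": "down", "m2": "up", "m3": "down"}
        gdir = {"G1": "up", "G2": "up", "G3": "down"}
        once = filter_mirna_targets(pairs, mdir, gdir)
        twice = filter_mirna_targets(once, mdir, gdir)
        pd.testing.assert_frame_equal(once, twice)
        merged = once.merge(pairs, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()

    def test_generator_decoys_never_survive(self, small_config):
        from lncmetnet import simulate_expression, simulate_mirna

        _, truth = simulate_expression(small_config)
        directions, pairs = simulate_mirna(truth, small_config)
        mdir = dict(zip(directions["mirna"], directions["direction"]))
        gdir = truth.de_direction()
        out = filter_mirna_targets(pairs, mdir, gdir)
        kept = set(zip(out["mirna"], out["target"]))
        assert kept == truth.mirna_planted
        assert not kept & truth.mirna_decoys


class TestIntegrate:
    def test_empty_inputs_empty_network(self):
        net = integrate(coexpr(), ppi(), mirna(), TOY_NODES)
        assert net.number_of_edges() == 0

    def test_shared_pair_carries_two_typed_edges(self):
        net = integrate(
            coexpr(("A", "B", "positive")), ppi(("A", "B")), mirna(), TOY_NODES
        )
        etypes = sorted(d["etype"] for _, _, d in net.edges(data=True))
        assert etypes == ["coexpr_pos", "ppi"]

    def test_toy_counts(self):
        net = integrate(
            coexpr(("A", "B", "positive"), ("A", "C", "negative"), ("L1", "A", "positive")),
            ppi(("A", "B"), ("B", "C")),
            mirna(("M1", "L1")),
            TOY_NODES,
        )
        assert net.number_of_edges() == 6
        s = summarize(net)
        assert s.n_ppi == 2 and s.n_ppi_overlap_total == 1
        assert s.n_ppi_overlap_pos == 1 and s.n_ppi_overlap_neg == 0
        assert s.n_mirna_lncrna_links == 1

    def test_unknown_node_rejected(self):
        with pytest.raises(ValueError, match="unknown nodes"):
            integrate(coexpr(("A", "ZZZ", "positive")), ppi(), mirna(), TOY_NODES)

    def test_coexpression_cannot_touch_mirna(self):
        with pytest.raises(ValueError, match="miRNA"):
            integrate(coexpr(("A", "M1", "positive")), ppi(), mirna(), TOY_NODES)

    def test_mirna_edge_needs_mirna_source(self):
        with pytest.raises(ValueError, match="not a miRNA"):
            integrate(coexpr(), ppi(), mirna(("A", "B")), TOY_NODES)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError, match="self-loop"):
            integrate(coexpr(("A", "A", "positive")), ppi(), mirna(), TOY_NODES)


def random_toy_network(rng, n_nodes=30, max_edges=500):
    names = (
        [f"G{i}" for i in range(n_nodes)]
        + [f"L{i}" for i in range(n_nodes // 3)]
        + [f"M{i}" for i in range(n_nodes // 3)]
    )
    biotype = {}
    for g in names:
        biotype[g] = {"G": "protein_coding", "L": "lncRNA", "M": "miRNA"}[g[0]]
    node_table = pd.DataFrame(
        [{"gene": g, "biotype": biotype[g],
          "direction": rng.choice(["up", "down"]), "log2_fc": float(rng.normal())}
         for g in names]
    )
    non_mirna = [g for g in names if biotype[g] != "miRNA"]
    mirnas = [g for g in names if biotype[g] == "miRNA"]
    n_coexpr = rng.integers(0, max_edges // 3)
    n_ppi = rng.integers(0, max_edges // 3)
    n_mt = rng.integers(0, max_edges // 3)
    seen = set()
    ce_rows = []
    for _ in range(n_coexpr):
        a, b = rng.choice(non_mirna, size=2, replace=False)
        pair = (min(a, b), max(a, b))
        if pair in seen:
            continue
        seen.add(pair)
        ce_rows.append({"gene_a": pair[0], "gene_b": pair[1],
                        "sign": rng.choice(["positive", "negative"]), "r": 0.5})
    ppi_rows = []
    seen_ppi = set()
    for _ in range(n_ppi):
        a, b = rng.choice(non_mirna, size=2, replace=False)
        pair = (min(a, b), max(a, b))
        if pair in seen_ppi:
            continue
        seen_ppi.add(pair)
        ppi_rows.append({"gene_a": pair[0], "gene_b": pair[1]})
    mt_rows = []
    seen_mt = set()
    for _ in range(n_mt):
        m = rng.choice(mirnas)
        t = rng.choice(non_mirna)
        if (m, t) in seen_mt:
            continue
        seen_mt.add((m, t))
        mt_rows.append({"mirna": m, "target": t})
    ce = pd.DataFrame(ce_rows, columns=["gene_a", "gene_b", "sign", "r"])
    pp = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b"])
    mt = pd.DataFrame(mt_rows, columns=["mirna", "target"])
    return ce, pp, mt, node_table, biotype


def brute_force_summary(ce, pp, mt, biotype):
    sign_of = {(min(a, b), max(a, b)): s
               for a, b, s in zip(ce["gene_a"], ce["gene_b"], ce["sign"])}
    ppi_pairs = {(min(a, b), max(a, b)) for a, b in zip(pp["gene_a"], pp["gene_b"])}
    overlap = [sign_of[p] for p in ppi_pairs if p in sign_of]
    return {
        "n_mirna_target": len(mt),
        "n_coexpr_pos": sum(1 for s in sign_of.values() if s == "positive"),
        "n_coexpr_neg": sum(1 for s in sign_of.values() if s == "negative"),
        "n_ppi": len(ppi_pairs),
        "n_ppi_overlap_total": len(overlap),
        "n_ppi_overlap_pos": overlap.count("positive"),
        "n_ppi_overlap_neg": overlap.count("negative"),
        "n_mirna_lncrna_links": sum(
            1 for t in mt["target"] if biotype[t] == "lncRNA"
        ),
    }


class TestSummarize:
    def test_no_ppi_means_no_overlap(self):
        net = integrate(coexpr(("A", "B", "positive")), ppi(), mirna(), TOY_NODES)
        s = summarize(net)
        assert s.n_ppi == s.n_ppi_overlap_total == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        ce, pp, mt, node_table, biotype = random_toy_network(rng)
        net = integrate(ce, pp, mt, node_table)
        assert summarize(net).to_dict() == brute_force_summary(ce, pp, mt, biotype)


class TestNodeProfile:
    def test_isolated_node(self):
        net = integrate(coexpr(), ppi(), mirna(), TOY_NODES)
        profile = node_profile(net, "L1")
        assert profile == {"coexpressed_protein_coding": 0,
                           "coexpressed_lncrna": 0, "regulating_mirnas": 0}

    def test_star_toy(self):
        node_table = nodes(L0="lncRNA", L1="lncRNA", A="protein_coding",
                           B="protein_coding", M1="miRNA")
        net = integrate(
            coexpr(("L0", "A", "positive"), ("L0", "B", "negative"),
                   ("L0", "L1", "positive")),
            ppi(),
            mirna(("M1", "L0")),
            node_table,
        )
        assert node_profile(net, "L0") == {
            "coexpressed_protein_coding": 2,
            "coexpressed_lncrna": 1,
            "regulating_mirnas": 1,
        }

    def test_absent_node_rejected(self):
        net = integrate(coexpr(), ppi(), mirna(), TOY_NODES)
        with pytest.raises(ValueError, match="not in network"):
            node_profile(net, "NOPE")


class TestExportImport:
    def build_toy(self):
        return integrate(
            coexpr(("A", "B", "positive"), ("L1", "A", "negative")),
            ppi(("A", "B")),
            mirna(("M1", "L1")),
            TOY_NODES,
        )

    def test_graphml_round_trip(self, tmp_path):
        net = self.build_toy()
        path = tmp_path / "net.graphml"
        export_network(net, str(path), fmt="graphml")
        back = load_graphml(str(path))
        assert summarize(back).to_dict() == summarize(net).to_dict()
        assert set(back.nodes) == set(net.nodes)
        assert back.nodes["A"]["node_type"] == "mRNA"

    def test_sif_line_format(self, tmp_path):
        net = self.build_toy()
        path = tmp_path / "net.sif"
        export_network(net, str(path), fmt="sif")
        lines = path.read_text().strip().split("\n")
        assert len(lines) == net.number_of_edges()
        assert all(len(line.split("\t")) == 3 for line in lines)
        mirna_lines = [l for l in lines if "mirna_target" in l]
        assert all(l.split("\t")[0] == "M1" for l in mirna_lines)

    def test_tsv_row_count(self, tmp_path):
        net = self.build_toy()
        path = tmp_path / "net.tsv"
        export_network(net, str(path), fmt="tsv")
        assert len(pd.read_csv(path, sep="\t")) == net.number_of_edges()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            export_network(self.build_toy(), str(tmp_path / "x"), fmt="dot")
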