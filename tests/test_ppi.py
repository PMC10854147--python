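"""PPI ingest, dedup, ortholog inference, induced subnetworks."""

import random

import pytest

from gsthemes import PPIEdge, dedup_edges, induce_subnetwork, map_orthologs, read_ppi

PSIMITAB_HEADER_COLS = 15


def mitab_line(id_a, id_b, tax_a="taxid:9606(human)", tax_b="taxid:9606(human)",
               conf="intact-miscore:0.7"):
    fields = ["-"] * PSIMITAB_HEADER_COLS
    fields[0] = f"uniprotkb:{id_a}"
    fields[1] = f"uniprotkb:{id_b}"
    fields[9] = tax_a
    fields[10] = tax_b
    fields[14] = conf
    return "\t".join(fields)


class TestDedup:
    def test_max_confidence_kept(self):
        edges = [PPIEdge("A", "B", 0.4), PPIEdge("B", "A", 0.7)]
        out = dedup_edges(edges)
        assert out == [PPIEdge("A", "B", 0.7)]

    def test_self_edges_dropped(self):
        assert dedup_edges([PPIEdge("A", "A", 0.9)]) == []

    def test_idempotent(self):
        edges = [PPIEdge("A", "B", 0.4), PPIEdge("B", "A", 0.7), PPIEdge("C", "D", 0.2)]
        once = dedup_edges(edges)
        assert dedup_edges(once) == once

    def test_order_independent(self):
        edges = [
            PPIEdge("A", "B", 0.4),
            PPIEdge("B", "A", 0.7),
            PPIEdge("C", "D", 0.2),
            PPIEdge("D", "C", 0.2),
            PPIEdge("A", "C", 0.5),
        ]
        expected = dedup_edges(edges)
        rng = random.Random(0)
        for _ in range(10):
            shuffled = edges[:]
            rng.shuffle(shuffled)
            assert dedup_edges(shuffled) == expected

    def test_native_wins_confidence_tie(self):
        out = dedup_edges([PPIEdge("A", "B", 0.8, inferred=True), PPIEdge("A", "B", 0.8)])
        assert out == [PPIEdge("A", "B", 0.8, inferred=False)]


class TestReadPpi:
    def test_tsv_with_header(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_a\tgene_b\tconfidence\nA\tB\t0.4\nB\tA\t0.7\nA\tA\t0.9\n")
        assert read_ppi(p) == [PPIEdge("A", "B", 0.7)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("")
        assert read_ppi(p) == []

    def test_unparsable_line_skipped_with_warning(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\tnot_a_number\nC\tD\t0.5\n")
        with pytest.warns(UserWarning, match="line 1"):
            edges = read_ppi(p)
        assert edges == [PPIEdge("C", "D", 0.5)]

    def test_psimitab_extraction(self, tmp_path):
        p = tmp_path / "e.mitab"
        p.write_text(mitab_line("P1", "P2") + "\n")
        assert read_ppi(p, dialect="psimitab") == [PPIEdge("P1", "P2", 0.7)]

    def test_psimitab_cross_species_dropped(self, tmp_path):
        p = tmp_path / "e.mitab"
        p.write_text(
            mitab_line("P1", "P2", tax_b="taxid:10090(mouse)") + "\n"
            + mitab_line("P3", "P4") + "\n"
        )
        assert read_ppi(p, dialect="psimitab") == [PPIEdge("P3", "P4", 0.7)]

    def test_psimitab_duplicate_max_merge(self, tmp_path):
        p = tmp_path / "e.mitab"
        p.write_text(
            mitab_line("P1", "P2", conf="intact-miscore:0.3") + "\n"
            + mitab_line("P2", "P1", conf="intact-miscore:0.9") + "\n"
        )
        assert read_ppi(p, dialect="psimitab") == [PPIEdge("P1", "P2", 0.9)]

    def test_unknown_dialect_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("A\tB\t0.5\n")
        with pytest.raises(ValueError):
            read_ppi(p, dialect="xml")


class TestMapOrthologs:
    def test_fully_mapped_edge_inferred(self):
        out = map_orthologs([PPIEdge("Ah", "Bh", 0.8)], {"Ah": "Am", "Bh": "Bm"})
        inferred = [e for e in out if e.inferred]
        assert inferred == [PPIEdge("Am", "Bm", 0.8, inferred=True)]
        assert PPIEdge("Ah", "Bh", 0.8) in out  # native edge retained

    def test_unmapped_endpoint_yields_nothing(self):
        out = map_orthologs([PPIEdge("Ah", "Bh", 0.8)], {"Ah": "Am"})
        assert all(not e.inferred for e in out)

    def test_inferred_duplicate_of_native_keeps_native(self):
        native = PPIEdge("Am", "Bm", 0.9)
        out = map_orthologs([native, PPIEdge("Ah", "Bh", 0.8)], {"Ah": "Am", "Bh": "Bm"})
        merged = [e for e in out if e.key == ("Am", "Bm")]
        assert merged == [PPIEdge("Am", "Bm", 0.9, inferred=False)]

    def test_one_to_many_expansion(self):
        out = map_orthologs([PPIEdge("Ah", "Bh", 0.5)], {"Ah": ["A1", "A2"], "Bh": "B1"})
        inferred = sorted(e.key for e in out if e.inferred)
        assert inferred == [("A1", "B1"), ("A2", "B1")]


TRIANGLE = [PPIEdge("A", "B", 0.9), PPIEdge("B", "C", 0.9), PPIEdge("A", "C", 0.2)]


class TestInduceSubnetwork:
    def test_confidence_filter(self):
        g = induce_subnetwork(TRIANGLE, {"A", "B", "C"}, min_confidence=0.5)
        assert set(map(frozenset, g.edges)) == {frozenset("AB"), frozenset("BC")}
        assert g.nodes["B"]["degree"] == 2 and g.nodes["A"]["degree"] == 1

    def test_single_pass_degree_filter_star(self):
        star = [PPIEdge("C", f"L{i}", 0.9) for i in range(3)]
        g = induce_subnetwork(star, {"C", "L0", "L1", "L2"}, min_degree=2)
        # leaves (degree 1) dropped; centre left isolated and dropped too
        assert g.number_of_nodes() == 0

    def test_genes_disjoint_from_edges(self):
        g = induce_subnetwork(TRIANGLE, {"X", "Y"})
        assert g.number_of_nodes() == 0

    def test_inferred_excluded_on_request(self):
        edges = [PPIEdge("A", "B", 0.9, inferred=True), PPIEdge("B", "C", 0.9)]
        g = induce_subnetwork(edges, {"A", "B", "C"}, include_inferred=False)
        assert set(map(frozenset, g.edges)) == {frozenset("BC")}

    def test_gene_statistics_attached(self):
        g = induce_subnetwork(TRIANGLE, {"A", "B", "C"}, gene_stats={"A": 1.5})
        assert g.nodes["A"]["statistic"] == 1.5
        assert "statistic" not in g.nodes["B"]

    def test_monotone_in_thresholds(self):
        import numpy as np

        rng = np.random.default_rng(31)
        genes = [f"n{i}" for i in range(15)]
        edges = [
            PPIEdge(genes[i], genes[j], float(rng.uniform()))
            for i in range(15)
            for j in range(i + 1, 15)
            if rng.uniform() < 0.4
        ]
        prev_edges = None
        for conf in (0.0, 0.25, 0.5, 0.75):
            g = induce_subnetwork(edges, genes, min_confidence=conf)
            es = set(map(frozenset, g.edges))
            if prev_edges is not None:
                assert es <= prev_edges
            prev_edges = es
        prev_edges = None
        for deg in (0, 1, 2, 3, 4):
            g = induce_subnetwork(edges, genes, min_degree=deg)
            es = set(map(frozenset, g.edges))
            if prev_edges is not None:
                assert es <= prev_edges
            prev_edges = es

    def test_degree_sums_to_twice_edges_before_node_filter(self):
        g = induce_subnetwork(TRIANGLE, {"A", "B", "C"}, min_confidence=0.5)
        assert sum(d for _, d in g.degree) == 2 * g.number_of_edges()
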