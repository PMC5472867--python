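"""Network readers, the top-k similarity filter, and assembly."""

import logging

import numpy as np
import pytest

from hetprop.errors import AssemblyError, ParseError, ValidationError
from hetprop.hetnet_io import (
    BipartiteAssociations,
    GeneNetwork,
    assemble_heterogeneous,
    read_bipartite,
    read_disease_similarity,
    read_gene_network,
    write_bipartite,
    write_disease_similarity,
    write_gene_network,
)

from conftest import make_hetnet, random_hetnet


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGeneNetwork:
    def test_basic_tsv(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "g1\tg2\t1.0\ng2\tg3\t1.0\n")
        net = read_gene_network(p)
        assert net.gene_ids == ("g1", "g2", "g3")
        assert net.w[0, 1] == 1.0 and net.w[1, 0] == 1.0
        assert len(list(net.edges())) == 2

    def test_missing_weight_defaults_to_one(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "g1\tg2\n")
        assert next(read_gene_network(p).edges()) == ("g1", "g2", 1.0)

    def test_self_loop_dropped_but_node_kept(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "g1\tg1\t1.0\n")
        net = read_gene_network(p)
        assert net.gene_ids == ("g1",)
        assert list(net.edges()) == []

    def test_duplicate_edges_keep_max_weight(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "g1\tg2\t2.0\ng2\tg1\t3.0\n")
        assert list(read_gene_network(p).edges()) == [("g1", "g2", 3.0)]

    def test_sif_dialect_one_to_many(self, tmp_path):
        p = _write(tmp_path, "g.sif", "g1\tpp\tg2\tg3\n")
        net = read_gene_network(p, dialect="sif")
        assert sorted(net.edges()) == [("g1", "g2", 1.0), ("g1", "g3", 1.0)]

    def test_comments_and_blanks_skipped(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "# header\n\ng1\tg2\t1.0\n")
        assert len(list(read_gene_network(p).edges())) == 1

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "g1\tg2\t1.0\ng3\n")
        with pytest.raises(ParseError, match=r":2:"):
            read_gene_network(p)

    def test_negative_weight_rejected(self, tmp_path):
        p = _write(tmp_path, "g.tsv", "g1\tg2\t-1.0\n")
        with pytest.raises(ValidationError):
            read_gene_network(p)


class TestDiseaseSimilarity:
    def test_top1_matrix_filter(self, tmp_path):
        # a's best is b, b's best is a, c's best is b => edges {a-b, b-c}
        p = _write(
            tmp_path, "d.tsv",
            ".\ta\tb\tc\n"
            "a\t0\t0.9\t0.2\n"
            "b\t0.9\t0\t0.8\n"
            "c\t0.2\t0.8\t0\n",
        )
        net = read_disease_similarity(p, format="matrix", k_top=1)
        assert sorted(net.edges()) == [("a", "b", 0.9), ("b", "c", 0.8)]

    def test_large_k_keeps_complete_graph(self, tmp_path):
        p = _write(
            tmp_path, "d.tsv",
            ".\ta\tb\tc\n"
            "a\t0\t0.9\t0.2\n"
            "b\t0.9\t0\t0.8\n"
            "c\t0.2\t0.8\t0\n",
        )
        net = read_disease_similarity(p, format="matrix", k_top=10)
        assert len(list(net.edges())) == 3
        assert np.all(net.w.toarray().diagonal() == 0)

    def test_asymmetric_entries_averaged_before_filter(self, tmp_path):
        p = _write(tmp_path, "d.tsv", ".\ta\tb\na\t0\t0.4\nb\t0.6\t0\n")
        net = read_disease_similarity(p, format="matrix", k_top=1)
        assert list(net.edges()) == [("a", "b", 0.5)]

    def test_all_zero_row_keeps_disease_with_no_edges(self, tmp_path):
        p = _write(
            tmp_path, "d.tsv",
            ".\ta\tb\tc\na\t0\t0.9\t0\nb\t0.9\t0\t0\nc\t0\t0\t0\n",
        )
        net = read_disease_similarity(p, format="matrix", k_top=2)
        assert net.disease_ids == ("a", "b", "c")
        assert net.w[[2], :].nnz == 0

    def test_edgelist_format(self, tmp_path):
        p = _write(tmp_path, "d.tsv", "a\tb\t0.9\nb\tc\t0.8\n")
        net = read_disease_similarity(p, format="edgelist", k_top=5)
        assert sorted(net.edges()) == [("a", "b", 0.9), ("b", "c", 0.8)]

    def test_topk_ties_broken_lexicographically(self, tmp_path):
        # a sees b and c at the same weight; top-1 must pick b
        p = _write(tmp_path, "d.tsv", "a\tc\t0.5\na\tb\t0.5\n")
        net = read_disease_similarity(p, format="edgelist", k_top=1)
        # both edges survive because c also selects a, but a's own choice is b
        assert ("a", "b", 0.5) in list(net.edges())

    def test_non_square_matrix_rejected(self, tmp_path):
        p = _write(tmp_path, "d.tsv", ".\ta\tb\tc\na\t0\t1\t0\nb\t1\t0\t0\n")
        with pytest.raises(ValidationError, match="square"):
            read_disease_similarity(p, format="matrix", k_top=1)

    def test_entry_outside_unit_interval_rejected(self, tmp_path):
        p = _write(tmp_path, "d.tsv", ".\ta\tb\na\t0\t1.5\nb\t1.5\t0\n")
        with pytest.raises(ValidationError):
            read_disease_similarity(p, format="matrix", k_top=1)

    def test_k_top_below_one_rejected(self, tmp_path):
        p = _write(tmp_path, "d.tsv", "a\tb\t0.9\n")
        with pytest.raises(ValidationError):
            read_disease_similarity(p, k_top=0)

    def test_filter_keeps_only_topk_choices(self):
        """No surviving edge lacks a top-k endorsement from an endpoint."""
        rng = np.random.default_rng(7)
        n, k = 12, 3
        ids = tuple(f"d{i:02d}" for i in range(n))
        sim = {}
        for i in range(n):
            for j in range(i + 1, n):
                sim[(ids[i], ids[j])] = float(rng.uniform(0.01, 1.0))
        from hetprop.hetnet_io import _topk_sparsify

        net = _topk_sparsify(ids, sim, k)
        # recompute each disease's top-k by brute force
        best = {}
        for d in ids:
            nbrs = [(o, sim[(d, o) if d < o else (o, d)]) for o in ids if o != d]
            nbrs.sort(key=lambda t: (-t[1], t[0]))
            best[d] = {o for o, _ in nbrs[:k]}
        for a, b, _ in net.edges():
            assert b in best[a] or a in best[b]
        deg = (net.w.toarray() > 0).sum(axis=1)
        assert (deg >= 1).all()


class TestBipartite:
    def test_default_weight(self, tmp_path):
        p = _write(tmp_path, "b.tsv", "MIM114480\tBRCA2\n")
        assert read_bipartite(p).pairs == {("MIM114480", "BRCA2"): 1.0}

    def test_duplicate_pair_keeps_max(self, tmp_path):
        p = _write(tmp_path, "b.tsv", "d1\tg1\t1.0\nd1\tg1\t2.0\n")
        assert read_bipartite(p).pairs == {("d1", "g1"): 2.0}

    def test_empty_file_gives_empty_set(self, tmp_path):
        p = _write(tmp_path, "b.tsv", "# nothing\n")
        assert len(read_bipartite(p)) == 0

    def test_nonpositive_weight_rejected(self, tmp_path):
        p = _write(tmp_path, "b.tsv", "d1\tg1\t0\n")
        with pytest.raises(ValidationError):
            read_bipartite(p)


class TestAssembly:
    def test_micro_net_index_layout(self, micro_net):
        assert micro_net.n_nodes == 5
        assert [micro_net.index_map[i] for i in ("g1", "g2", "g3", "d1", "d2")] == [0, 1, 2, 3, 4]
        # genes strictly before diseases, map is a bijection
        assert max(micro_net.index_map[g] for g in ("g1", "g2", "g3")) < min(
            micro_net.index_map[d] for d in ("d1", "d2")
        )
        assert sorted(micro_net.index_map.values()) == list(range(5))

    def test_unresolvable_pair_dropped_and_logged(self, caplog):
        with caplog.at_level(logging.WARNING, logger="hetprop.hetnet_io"):
            net = make_hetnet(
                [("g1", "g2", 1.0)], ["d1", "d2"], [("d1", "d2", 1.0)],
                [("d1", "g1"), ("d1", "gX")], gene_ids=["g1", "g2"],
            )
        assert ("d1", "gX") not in net.bipartite.pairs
        assert "1 bipartite pairs" in caplog.text

    def test_degree_zero_node_rejected_by_name(self):
        with pytest.raises(AssemblyError, match="g4"):
            make_hetnet(
                [("g1", "g2", 1.0)], ["d1", "d2"], [("d1", "d2", 1.0)],
                [("d1", "g1")], gene_ids=["g1", "g2", "g4"],
            )

    def test_gene_disease_id_collision_rejected(self):
        with pytest.raises(AssemblyError, match="both gene and disease"):
            make_hetnet(
                [("x", "g2", 1.0)], ["x", "d2"], [("x", "d2", 1.0)], [("x", "g2")],
            )

    def test_empty_component_rejected(self):
        from hetprop.hetnet_io import DiseaseNetwork, GeneNetwork, _symmetric_csr
        with pytest.raises(AssemblyError, match="non-empty"):
            assemble_heterogeneous(
                GeneNetwork((), _symmetric_csr((), {})),
                DiseaseNetwork(("d1",), _symmetric_csr(("d1",), {})),
                BipartiteAssociations({}),
            )


class TestRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_write_read_identity(self, tmp_path, seed):
        rng = np.random.default_rng(seed)
        net = random_hetnet(rng)
        write_gene_network(net.gene_net, tmp_path / "g.tsv")
        write_disease_similarity(net.disease_net, tmp_path / "d.tsv")
        write_bipartite(net.bipartite, tmp_path / "b.tsv")
        g2 = read_gene_network(tmp_path / "g.tsv")
        d2 = read_disease_similarity(tmp_path / "d.tsv", k_top=net.n_diseases)
        b2 = read_bipartite(tmp_path / "b.tsv")
        def norm(edges):
            return {frozenset((a, b)): w for a, b, w in edges}

        e1, e2 = norm(net.gene_net.edges()), norm(g2.edges())
        assert e1.keys() == e2.keys()
        assert all(np.isclose(e1[k], e2[k]) for k in e1)
        assert norm(net.disease_net.edges()).keys() == norm(d2.edges()).keys()
        assert set(b2.pairs) == set(net.bipartite.pairs)
        for k in b2.pairs:
            assert b2.pairs[k] == pytest.approx(net.bipartite.pairs[k])
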