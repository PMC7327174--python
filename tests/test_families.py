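"""Orthologous-family clustering, abundance matrix and conservation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hemenet.errors import ConfigurationError, IntegrityError, ParameterError
from hemenet.families import (
    abundance_matrix,
    build_homology_graph,
    cluster_families,
    conservation_summary,
    families_frame,
    write_summary,
)
from hemenet.homology import PairwiseHit, search
from hemenet.hemescan import scan_proteome


def make_hit(q, s, evalue=1e-30, pident=80.0, bit=100.0, length=100):
    return PairwiseHit(
        query_id=q, subject_id=s, raw_score=0, bit_score=bit, pident=pident,
        length=length, mismatches=0, gap_opens=0, qstart=1, qend=length,
        sstart=1, send=length, evalue=evalue, qcov=100.0,
    )


class TestHomologyGraph:
    def test_no_hits_all_isolated(self):
        g = build_homology_graph([], nodes=["a", "b", "c"])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 0

    def test_mutual_passing_hits_create_edge(self):
        hits = [make_hit("a", "b"), make_hit("b", "a")]
        g = build_homology_graph(hits, max_evalue=1e-20, min_identity=50)
        assert g.has_edge("a", "b")

    def test_one_directional_hit_no_edge(self):
        g = build_homology_graph([make_hit("a", "b")], max_evalue=1e-20, min_identity=50)
        assert not g.has_edge("a", "b")

    def test_threshold_violations_block_edge(self):
        weak_e = [make_hit("a", "b", evalue=1e-10), make_hit("b", "a", evalue=1e-10)]
        weak_i = [make_hit("a", "b", pident=40), make_hit("b", "a", pident=40)]
        assert not build_homology_graph(weak_e, 1e-20, 50).has_edge("a", "b")
        assert not build_homology_graph(weak_i, 1e-20, 50).has_edge("a", "b")

    def test_no_self_edges(self):
        g = build_homology_graph([make_hit("a", "a"), make_hit("a", "a")])
        assert g.number_of_edges() == 0


class TestClusterFamilies:
    def genome_of(self, pid):
        return pid.split(".")[0]

    def test_edgeless_graph_gives_singletons(self):
        g = nx.Graph()
        g.add_nodes_from(["g1.a", "g1.b", "g2.c"])
        fams = cluster_families(g, genome_of=self.genome_of)
        assert len(fams) == 3 and all(f.size == 1 for f in fams)

    def test_clique_is_one_family(self):
        g = nx.complete_graph([f"g{i}.p" for i in range(5)])
        fams = cluster_families(g, genome_of=self.genome_of)
        assert len(fams) == 1 and fams[0].size == 5

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            cluster_families(nx.Graph(), genome_of=self.genome_of, method="kmeans")

    def test_mcl_like_matches_components_on_disjoint_cliques(self):
        g = nx.Graph()
        for tag in ("x", "y"):
            nodes = [f"g1.{tag}{i}" for i in range(4)]
            g.add_edges_from(nx.complete_graph(nodes).edges)
        by_comp = cluster_families(g, genome_of=self.genome_of, method="components")
        by_mcl = cluster_families(g, genome_of=self.genome_of, method="mcl-like")
        assert {f.members for f in by_comp} == {f.members for f in by_mcl}

    def test_family_ids_stable_by_size_then_member(self):
        g = nx.Graph()
        g.add_edges_from([("g1.b", "g1.c"), ("g1.b", "g1.d")])
        g.add_node("g1.a")
        fams = cluster_families(g, genome_of=self.genome_of)
        assert fams[0].size == 3 and fams[0].family_id == "OF00001"
        assert fams[1].members == ("g1.a",)

    def test_partition_property(self, small_set, small_scan):
        annotations, _ = small_scan
        prots = small_set.all_proteins()
        genome_of = {p.protein_id: p.genome_id for p in prots}
        mhc_ids = sorted(a.protein_id for a in annotations if a.is_mhc)
        mhc = [p for p in prots if p.protein_id in set(mhc_ids)]
        hits = search(mhc, mhc)
        graph = build_homology_graph(hits, 1e-3, 50, nodes=mhc_ids)
        fams = cluster_families(graph, genome_of=genome_of)
        members = [pid for f in fams for pid in f.members]
        assert sorted(members) == mhc_ids  # every MHC in exactly one family
        assert sum(f.size for f in fams) == len(mhc_ids)

    def test_planted_families_recovered_exactly(self, small_set, small_scan):
        annotations, _ = small_scan
        prots = small_set.all_proteins()
        genome_of = {p.protein_id: p.genome_id for p in prots}
        mhc_ids = sorted(a.protein_id for a in annotations if a.is_mhc)
        mhc = [p for p in prots if p.protein_id in set(mhc_ids)]
        hits = search(mhc, mhc)
        graph = build_homology_graph(hits, 1e-3, 50, nodes=mhc_ids)
        fams = cluster_families(graph, genome_of=genome_of)
        pred = {pid: f.family_id for f in fams for pid in f.members}
        truth = small_set.truth.family_of
        labels_true = [truth.get(pid, f"single:{pid}") for pid in mhc_ids]
        labels_pred = [pred[pid] for pid in mhc_ids]
        assert adjusted_rand_score(labels_true, labels_pred) == 1.0

    def test_tightening_thresholds_never_merges(self):
        hits = []
        for q, s, ident in [("a", "b", 80), ("b", "a", 80), ("b", "c", 55), ("c", "b", 55)]:
            hits.append(make_hit(q, s, pident=ident))
        loose = cluster_families(
            build_homology_graph(hits, 1e-20, 50, nodes=list("abc")),
            genome_of=lambda p: "g1",
        )
        tight = cluster_families(
            build_homology_graph(hits, 1e-20, 60, nodes=list("abc")),
            genome_of=lambda p: "g1",
        )
        # tight partition must refine the loose partition
        loose_of = {pid: f.family_id for f in loose for pid in f.members}
        for fam in tight:
            assert len({loose_of[pid] for pid in fam.members}) == 1


class TestAbundanceMatrix:
    def fam(self, fid, members):
        from hemenet.families import OrthoFamily

        counts = {}
        for pid in members:
            g = pid.split(".")[0]
            counts[g] = counts.get(g, 0) + 1
        return OrthoFamily(
            family_id=fid, members=tuple(sorted(members)),
            genomes=tuple(sorted(counts)), per_genome_counts=tuple(sorted(counts.items())),
        )

    def test_single_genome_singletons(self):
        fams = [self.fam(f"OF{i}", [f"g1.p{i}"]) for i in range(3)]
        mat = abundance_matrix(fams, ["g1"])
        assert mat.shape == (1, 3) and (mat.values == 1).all()

    def test_row_and_column_sums(self):
        fams = [
            self.fam("OF1", ["g1.a", "g1.b", "g2.c"]),
            self.fam("OF2", ["g2.d"]),
        ]
        mat = abundance_matrix(fams, ["g1", "g2", "g3"])
        assert mat.sum(axis=0).tolist() == [3, 1]  # column sum = family size
        assert mat.loc["g3"].sum() == 0  # all-zero row kept

    def test_unknown_genome_rejected(self):
        with pytest.raises(IntegrityError):
            abundance_matrix([self.fam("OF1", ["gX.a"])], ["g1"])

    def test_matrix_support_equals_planted_presence(self, small_set, small_scan):
        annotations, _ = small_scan
        prots = small_set.all_proteins()
        genome_of = {p.protein_id: p.genome_id for p in prots}
        truth_members = small_set.truth.family_members()
        fams = [
            self.fam(fid, members)
            for fid, members in sorted(truth_members.items())
        ]
        # rebuild with real genome ids (header style genome|scaffold|idx)
        from hemenet.families import OrthoFamily

        fams = []
        for fid, members in sorted(truth_members.items()):
            counts = {}
            for pid in members:
                counts[genome_of[pid]] = counts.get(genome_of[pid], 0) + 1
            fams.append(
                OrthoFamily(fid, tuple(sorted(members)), tuple(sorted(counts)),
                            tuple(sorted(counts.items())))
            )
        mat = abundance_matrix(fams, sorted(small_set.proteins))
        cfg = small_set.config
        presence = small_set.config.family_presence
        for fi, fam in enumerate(fams):
            for gi, g in enumerate(sorted(small_set.proteins)):
                expected = any(
                    genome_of[pid] == g for pid in truth_members[fam.family_id]
                )
                assert (mat.loc[g, fam.family_id] > 0) == expected


class TestConservation:
    def test_single_genome_all_core(self):
        mat = pd.DataFrame([[1, 2, 1]], index=["g1"], columns=["a", "b", "c"])
        assert conservation_summary(mat, 1) == (3, 3)

    def test_known_presence_counts(self):
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 0, 0], [1, 1, 0]],
            index=["g1", "g2", "g3"], columns=["a", "b", "c"],
        )
        assert conservation_summary(mat, 2) == (2, 1)
        assert conservation_summary(mat, 3) == (1, 1)

    @pytest.mark.parametrize("k", [0, 4])
    def test_k_out_of_range(self, k):
        mat = pd.DataFrame([[1], [1], [0]], index=["g1", "g2", "g3"], columns=["a"])
        with pytest.raises(ParameterError):
            conservation_summary(mat, k)

    def test_summary_json(self, tmp_path):
        mat = pd.DataFrame(
            [[1, 1], [1, 0]], index=["g1", "g2"], columns=["OF1", "OF2"]
        )
        from hemenet.families import OrthoFamily

        fams = [
            OrthoFamily("OF1", ("g1.a", "g2.b"), ("g1", "g2"), (("g1", 1), ("g2", 1))),
            OrthoFamily("OF2", ("g1.c",), ("g1",), (("g1", 1),)),
        ]
        summary = write_summary(fams, mat, tmp_path / "s.json")
        assert summary["n_families"] == 2
        assert summary["n_core_families"] == 1
        assert summary["families_in_ge_k"]["2"] == 1
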