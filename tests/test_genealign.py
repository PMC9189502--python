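"""Gene alignment extraction, filtering, concatenation and NJ trees."""

import numpy as np
import pytest

from skit._seq import MISSING
from skit.genealign import (GeneAlignment, concatenate,
                            extract_gene_alignments, filter_gene_alignments,
                            nj_tree, p_distance_matrix)
from skit.genotypes import GenotypeMatrix
from skit.simgenome import (GeneModel, SimNode, random_chromosome,
                            simulate_allele_histories)


def make_matrix(gt, pos=None, dp=None, gq=None, samples=None):
    gt = np.asarray(gt, dtype=np.int8)
    S, N = gt.shape[:2]
    return GenotypeMatrix(
        chrom=np.full(S, "chr1"),
        pos=np.arange(S, dtype=np.int64) if pos is None else
        np.asarray(pos, dtype=np.int64),
        samples=samples or [f"s{i}" for i in range(N)], gt=gt,
        dp=None if dp is None else np.asarray(dp, dtype=np.int32),
        gq=None if gq is None else np.asarray(gq, dtype=np.int32))


class TestExtraction:
    def test_heterozygote_becomes_iupac(self):
        gt = np.zeros((6, 2, 2))
        gt[2, 0] = (0, 2)    # A/G -> R
        gt[4, 1] = (1, 3)    # C/T -> Y
        mat = make_matrix(gt)
        aln = extract_gene_alignments(mat, [GeneModel("g", ((0, 6),))],
                                      min_gq=0, min_dp=0)["g"]
        assert aln.seqs[0] == "AARAAA"
        assert aln.seqs[1] == "AAAAYA"

    def test_site_missing_in_any_sample_removed_for_all(self):
        gt = np.zeros((6, 3, 2))
        gt[3, 1] = MISSING
        mat = make_matrix(gt)
        aln = extract_gene_alignments(mat, [GeneModel("g", ((0, 6),))],
                                      min_gq=0, min_dp=0)["g"]
        # removed site resurfaces as N in every sample
        assert all(s == "AAANAA" for s in aln.seqs)

    def test_quality_masking_or_rule(self):
        gt = np.zeros((4, 1, 2))
        dp = [[10], [4], [10], [4]]
        gq = [[30], [30], [10], [10]]
        mat = make_matrix(gt, dp=dp, gq=gq)
        aln_or = extract_gene_alignments(mat, [GeneModel("g", ((0, 4),))],
                                         min_gq=20, min_dp=5)["g"]
        assert aln_or.seqs[0] == "ANNN"    # fail either threshold -> missing
        aln_and = extract_gene_alignments(mat, [GeneModel("g", ((0, 4),))],
                                          min_gq=20, min_dp=5,
                                          combine="and")["g"]
        assert aln_and.seqs[0] == "AAAN"   # literal AND keeps partial passes

    def test_minus_strand_reverse_complement_splice(self, rng):
        """Minus-strand extraction equals direct simulation of the CDS."""
        anc = random_chromosome("chr1", 3_000, rng, n_genes=4,
                                exons_per_gene=2, exon_length=120,
                                intron_length=60)
        minus = [g for g in anc.genes if g.strand == "-"][0]
        codes = np.frombuffer(anc.sequence.encode(), np.uint8)
        lut = np.full(256, -1, np.int8)
        for i, b in enumerate("ACGT"):
            lut[ord(b)] = i
        hap = lut[codes]
        gt = np.stack([np.stack([hap, hap], axis=1)], axis=1)
        mat = make_matrix(gt)
        aln = extract_gene_alignments(mat, [minus], min_gq=0, min_dp=0)[
            minus.gene_id]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        spliced = "".join(anc.sequence[s:e] for s, e in minus.exons)
        expected = "".join(comp[c] for c in reversed(spliced))
        assert aln.seqs[0] == expected

    def test_positions_absent_from_callset_become_n(self):
        gt = np.zeros((3, 2, 2))
        mat = make_matrix(gt, pos=[0, 2, 4])
        aln = extract_gene_alignments(mat, [GeneModel("g", ((0, 6),))],
                                      min_gq=0, min_dp=0)["g"]
        assert all(s == "ANANAN" for s in aln.seqs)

    def test_no_jointly_missing_columns_survive(self, rng):
        gt = rng.integers(0, 4, (60, 4, 2)).astype(np.int8)
        miss = rng.random((60, 4)) < 0.2
        gt[miss] = MISSING
        mat = make_matrix(gt)
        aln = extract_gene_alignments(mat, [GeneModel("g", ((0, 60),))],
                                      min_gq=0, min_dp=0)["g"]
        cols = list(zip(*aln.seqs))
        for col in cols:
            assert set(col) == {"N"} or "N" not in col

    def test_sample_order_irrelevant(self, rng):
        gt = rng.integers(0, 4, (30, 3, 2)).astype(np.int8)
        mat = make_matrix(gt)
        perm = [2, 0, 1]
        mat2 = GenotypeMatrix(chrom=mat.chrom, pos=mat.pos,
                              samples=[mat.samples[i] for i in perm],
                              gt=mat.gt[:, perm, :])
        g = [GeneModel("g", ((0, 30),))]
        a1 = extract_gene_alignments(mat, g, min_gq=0, min_dp=0)["g"]
        a2 = extract_gene_alignments(mat2, g, min_gq=0, min_dp=0)["g"]
        for s in a1.samples:
            assert a1.seqs[a1.samples.index(s)] == a2.seqs[a2.samples.index(s)]


class TestFilters:
    def _aln(self, n_count, length=1_000):
        seq_bad = "N" * n_count + "A" * (length - n_count)
        return {"g": GeneAlignment("g", ["a", "b"],
                                   [seq_bad, "A" * length])}

    def test_n_count_over_500_dropped(self):
        assert filter_gene_alignments(self._aln(600)) == {}
        assert "g" in filter_gene_alignments(self._aln(500))

    def test_n_fraction_threshold_inclusive(self):
        # exactly 75% Ns with the count rule disabled by a high max_n
        aln = self._aln(300, length=400)
        assert filter_gene_alignments(aln, max_n=500, max_n_frac=0.75) == {}
        aln2 = self._aln(299, length=400)
        assert "g" in filter_gene_alignments(aln2, max_n=500, max_n_frac=0.75)

    def test_clean_alignment_kept(self):
        assert "g" in filter_gene_alignments(self._aln(0))


class TestConcatenate:
    def test_partition_offsets(self):
        a = GeneAlignment("g1", ["x", "y"], ["A" * 300, "C" * 300])
        b = GeneAlignment("g2", ["x", "y"], ["G" * 600, "T" * 600])
        combined, parts = concatenate({"g1": a, "g2": b}, ["g1", "g2"])
        assert combined.length == 900
        assert parts == [("g1", 0, 300), ("g2", 300, 900)]
        assert combined.seqs[0] == "A" * 300 + "G" * 600

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            concatenate({}, [])


class TestDistancesAndNJ:
    def test_iupac_expected_mismatch(self):
        aln = GeneAlignment("g", ["a", "b", "c"],
                            ["R", "A", "G"])
        dm = p_distance_matrix(aln)
        assert dm["a", "b"] == pytest.approx(0.5)   # R vs A
        assert dm["a", "c"] == pytest.approx(0.5)   # R vs G
        assert dm["b", "c"] == 1.0

    def test_n_excluded_pairwise(self):
        aln = GeneAlignment("g", ["a", "b"], ["ANAT", "AGCT"])
        dm = p_distance_matrix(aln)
        assert dm["a", "b"] == pytest.approx(1 / 3)  # N column skipped

    def test_three_taxa_closed_form(self):
        # distances: ab=0.2, ac=0.4, bc=0.4 -> branch a=0.1, b=0.1, c=0.3
        aln = GeneAlignment("g", ["a", "b", "c"], [
            "A" * 8 + "C" * 2, "A" * 10, "G" * 4 + "A" * 6])
        tree = nj_tree(aln)
        tips = {t.name: t.length for t in tree.tips()}
        dm = p_distance_matrix(aln)
        d_ab, d_ac, d_bc = dm["a", "b"], dm["a", "c"], dm["b", "c"]
        assert tips["a"] + tips["b"] == pytest.approx(d_ab)
        assert tips["a"] + tips["c"] == pytest.approx(d_ac)

    def test_additive_four_taxon_matrix_recovered(self):
        """On an additive distance matrix NJ returns the generating
        topology with exact branch lengths (skbio path, our distances)."""
        from skbio import DistanceMatrix
        from skbio.tree import nj
        # ((a:1,b:2):1,(c:3,d:4)) -> additive matrix
        d = np.array([[0, 3, 5, 6],
                      [3, 0, 6, 7],
                      [5, 6, 0, 7],
                      [6, 7, 7, 0]], dtype=float)
        tree = nj(DistanceMatrix(d, ids=list("abcd")))
        dist = {frozenset((x, y)): tree.find(x).distance(tree.find(y))
                for x in "abcd" for y in "abcd" if x != y}
        for (i, x) in enumerate("abcd"):
            for (j, y) in enumerate("abcd"):
                if i < j:
                    assert dist[frozenset((x, y))] == pytest.approx(d[i, j])

    def test_ultrametric_simulated_topology_recovery(self, rng):
        """Noise-free clocklike data: NJ groups the true clades."""
        for rep in range(5):
            anc = random_chromosome("chr1", 20_000, rng)
            r = 0.01
            tree = SimNode("root", children=[
                SimNode("ab", subs_rate=2 * r, children=[
                    SimNode("a", subs_rate=r), SimNode("b", subs_rate=r)]),
                SimNode("cd", subs_rate=2 * r, children=[
                    SimNode("c", subs_rate=r), SimNode("d", subs_rate=r)]),
            ])
            tips = simulate_allele_histories(anc, tree, rng)
            aln = GeneAlignment("g", list(tips),
                                [tips[k].sequence for k in tips])
            t = nj_tree(aln)
            # the a-b split: removing the root edge separates {a,b}|{c,d}
            dm = p_distance_matrix(aln)
            assert dm["a", "b"] < dm["a", "c"]
            tip_sets = [frozenset(x.name for x in cl.tips())
                        for cl in t.non_tips()]
            assert frozenset(("a", "b")) in tip_sets or \
                frozenset(("c", "d")) in tip_sets

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(GeneAlignment("g", ["a", "b"], ["A", "A"]))
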