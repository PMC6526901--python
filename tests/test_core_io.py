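"""Alignment/tree containers, FASTA I/O, and the pre-analysis gates."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import imprintsel as ims
from imprintsel.core_io import FrameError, InputError


def write_fasta(tmp_path, records, name="aln.fasta"):
    path = tmp_path / name
    path.write_text("".join(f">{t}\n{s}\n" for t, s in records))
    return path


class TestReadCodonFasta:
    def test_minimal_wellformed_alignment(self, tmp_path):
        path = write_fasta(tmp_path, [("x", "ATGAAA"), ("y", "ATGAAG")])
        aln = ims.read_codon_fasta(path)
        assert aln.taxa == ["x", "y"]
        assert aln.n_codons == 2
        assert aln.codon(1, 2) == "AAG"

    def test_length_not_divisible_by_three_is_frame_error(self, tmp_path):
        path = write_fasta(tmp_path, [("x", "ATGAAAG"), ("y", "ATGAAAG")])
        with pytest.raises(FrameError):
            ims.read_codon_fasta(path)

    def test_internal_stop_names_taxon_and_codon(self, tmp_path):
        path = write_fasta(tmp_path, [("x", "ATGTAAAAA"), ("y", "ATGAAAAAA")])
        with pytest.raises(FrameError, match="codon 2") as err:
            ims.read_codon_fasta(path)
        assert "x" in str(err.value)

    def test_terminal_stop_codon_is_allowed(self, tmp_path):
        path = write_fasta(tmp_path, [("x", "ATGAAATAA"), ("y", "ATGAAATGA")])
        assert ims.read_codon_fasta(path).n_codons == 3

    def test_duplicate_identifier_rejected(self, tmp_path):
        path = write_fasta(tmp_path, [("x", "ATGAAA"), ("x", "ATGAAG")])
        with pytest.raises(InputError, match="duplicated"):
            ims.read_codon_fasta(path)

    def test_roundtrip_preserves_taxa_order_and_sequences(self, tmp_path):
        aln = ims.CodonAlignment(["b", "a", "c"], ["ATGAAA", "ATG---", "ATGCAA"])
        out = tmp_path / "rt.fasta"
        ims.write_codon_fasta(aln, out)
        assert ims.read_codon_fasta(out) == aln


class TestPhyloTree:
    def test_newick_roundtrip_and_lengths(self):
        tree = ims.PhyloTree.from_newick("((a:0.1,b:0.2):0.05,c:0.3);")
        again = ims.PhyloTree.from_newick(tree.to_newick())
        assert again.leaf_names == tree.leaf_names
        np.testing.assert_allclose(again.branch_lengths(), tree.branch_lengths())

    def test_foreground_hash_tag_parsing(self):
        tree = ims.PhyloTree.from_newick("((a#1:0.1,b:0.2):0.05,c:0.3);")
        assert tree.foreground == {"a"}
        assert "a#1" in tree.to_newick()

    def test_set_foreground_validates_names(self):
        tree = ims.PhyloTree.from_newick("((a:0.1,b:0.2):0.05,c:0.3);")
        tree.set_foreground(["b"])
        assert tree.foreground == {"b"}
        with pytest.raises(InputError):
            tree.set_foreground(["nope"])


class TestClusterSizeGate:
    def _cluster(self, n_other):
        taxa = ["focal"] + [f"s{i}" for i in range(n_other)]
        seqs = ["ATGAAA"] * len(taxa)
        newick = "(" + ",".join(f"{t}:0.1" for t in taxa) + ");"
        return ims.OrthologCluster(
            "focal", ims.CodonAlignment(taxa, seqs), ims.PhyloTree.from_newick(newick)
        )

    @pytest.mark.parametrize(
        "n_other,min_species,expected",
        [(6, 6, True), (5, 6, False), (5, 0, True), (7, 6, True)],
    )
    def test_boundary(self, n_other, min_species, expected):
        decision = ims.cluster_size_gate(self._cluster(n_other), min_species)
        assert decision.passed is expected
        assert decision.details["n_species"] == n_other


class TestQualityScore:
    def test_identical_sequences_score_one(self):
        aln = ims.CodonAlignment(["a", "b", "c"], ["ATGAAACAT"] * 3)
        assert ims.alignment_quality_score(aln) == pytest.approx(1.0)

    def test_all_residue_gap_pairs_score_zero(self):
        aln = ims.CodonAlignment(["a", "b"], ["ATGAAA", "------"])
        assert ims.alignment_quality_score(aln) == pytest.approx(0.0)

    def test_scrambled_sequence_lowers_score(self, ps_site_data):
        aln, _ = ps_site_data
        rng = np.random.default_rng(0)
        codons = [aln.codon(0, c) for c in range(1, aln.n_codons + 1)]
        scrambled = "".join(codons[i] for i in rng.permutation(len(codons)))
        worse = ims.CodonAlignment(aln.taxa, aln.sequences[:-1] + [scrambled])
        assert ims.alignment_quality_score(worse) < ims.alignment_quality_score(aln)

    def test_single_sequence_is_error(self):
        with pytest.raises(InputError):
            ims.alignment_quality_score(ims.CodonAlignment(["a"], ["ATGAAA"]))

    @settings(deadline=None, max_examples=20)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, rnd):
        aln = ims.CodonAlignment(
            ["a", "b", "c", "d"],
            ["ATGAAACATTGG", "ATGAAGCAT---", "ATGCAACGTTGG", "ATG---CATTGC"],
        )
        order = list(range(4))
        rnd.shuffle(order)
        shuffled = ims.CodonAlignment(
            [aln.taxa[i] for i in order], [aln.sequences[i] for i in order]
        )
        assert ims.alignment_quality_score(shuffled) == pytest.approx(
            ims.alignment_quality_score(aln)
        )


class TestQualityGate:
    def test_pass_above_threshold_without_removal(self):
        aln = ims.CodonAlignment(["a", "b", "c"], ["ATGAAACAT"] * 3)
        res = ims.quality_gate(aln, threshold=0.6)
        assert res.passed and res.removed == []

    def test_drop_worst_and_retry_recovers(self):
        # three matching sequences plus one gap-ridden outlier drag the
        # score down; removing the outlier restores it
        good = "ATGAAACATTGGCCG"
        bad = "---------------"
        aln = ims.CodonAlignment(["a", "b", "g"], [good, good, bad])
        res = ims.quality_gate(aln, threshold=0.6, drop_and_retry=True)
        assert res.passed
        assert res.removed == ["g"]
        assert res.alignment.taxa == ["a", "b"]

    def test_unrecoverable_alignment_fails(self):
        aln = ims.CodonAlignment(["a", "b"], ["ATGAAA", "------"])
        res = ims.quality_gate(aln, threshold=0.6, drop_and_retry=True)
        assert not res.passed


class TestColumnGapFraction:
    def test_fractions_and_count_conservation(self):
        taxa = [f"t{i}" for i in range(10)]
        seqs = ["ATGAAA"] * 5 + ["ATG---"] * 5
        aln = ims.CodonAlignment(taxa, seqs)
        frac = ims.column_gap_fraction(aln)
        np.testing.assert_allclose(frac, [0.0, 0.5])
        # gap + non-gap counts sum to the number of taxa at every column
        for c, f in enumerate(frac, start=1):
            gaps = sum(1 for codon in aln.codon_column(c) if "-" in codon)
            assert gaps + (aln.n_taxa - gaps) == aln.n_taxa
            assert gaps / aln.n_taxa == f


class TestSNPTable:
    def test_read_and_validate(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text(
            "gene\tpos\tref\talt\tacc1\tacc2\n"
            "g1\t4\tA\tG\tA\tG\n"
            "g1\t7\tC\tT\t.\tT\n"
        )
        snps = ims.read_snp_table(path)["g1"]
        assert snps.n_accessions == 2
        assert list(snps.positions) == [4, 7]
        assert snps.genotypes.loc["acc1", 7] == "."

    def test_bad_allele_rejected(self, tmp_path):
        path = tmp_path / "snps.tsv"
        path.write_text("gene\tpos\tref\talt\tacc1\ng1\t4\tA\tX\tA\n")
        with pytest.raises(InputError):
            ims.read_snp_table(path)
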