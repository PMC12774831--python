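import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from snvcadd.annotate import (
    VariantAnnotator,
    classify_consequence,
    grantham,
    remap_density,
)
from snvcadd.genes import GeneModel, GeneSet
from snvcadd.io import GenomeSequence, IntervalTrack, PerBaseTrack
from snvcadd.training import Variant


class TestGrantham:
    def test_reference_values(self):
        assert grantham("A", "A") == 0
        assert grantham("L", "I") == 5
        assert grantham("C", "W") == 215

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            a, b = rng.choice(aas, 2)
            assert grantham(a, b) == grantham(b, a)

    def test_stop_not_applicable(self):
        assert grantham("*", "W") is None
        assert grantham("A", "*") is None


class TestCodingConsequences:
    """CDS 'ATG GCT TAA' at positions 15-23 of the simple genome."""

    def test_synonymous(self, simple_genome):
        genome, genes = simple_genome
        # codon 2 third base: GCT -> GCA, Ala -> Ala
        rec = classify_consequence(Variant("chr1", 20, "T", "A"), genes, genome)
        assert (rec.consequence, rec.oAA, rec.nAA, rec.protPos) == ("SN", "A", "A", 2)
        assert rec.CDSpos == 6
        assert rec.relCDSpos == pytest.approx(6 / 9)

    def test_nonsynonymous(self, simple_genome):
        genome, genes = simple_genome
        # codon 2 first base: GCT -> CCT, Ala -> Pro
        rec = classify_consequence(Variant("chr1", 18, "G", "C"), genes, genome)
        assert (rec.consequence, rec.oAA, rec.nAA) == ("NS", "A", "P")

    def test_stop_loss(self, simple_genome):
        genome, genes = simple_genome
        # codon 3 third base: TAA -> TAC, stop -> Tyr
        rec = classify_consequence(Variant("chr1", 23, "A", "C"), genes, genome)
        assert (rec.consequence, rec.oAA, rec.nAA) == ("SL", "*", "Y")

    def test_stop_gain(self):
        # dedicated gene with codon 2 = TGC (Cys), one change from TGA
        seq = "AAAA" + "ATGTGCTAA" + "AAAA"
        genome2 = GenomeSequence({"g": seq})
        gene = GeneModel("gx", "g", "+", 5, 13, exons=[(5, 13)], cds=[(5, 13)])
        genes2 = GeneSet([gene], flank=4)
        # codon 2 TGC (Cys) at positions 8-10; C->A gives TGA (stop)
        rec = classify_consequence(Variant("g", 10, "C", "A"), genes2, genome2)
        assert (rec.consequence, rec.oAA, rec.nAA) == ("SG", "C", "*")

    def test_utrs_and_intergenic(self, simple_genome):
        genome, genes = simple_genome
        assert classify_consequence(Variant("chr1", 12, "T", "A"), genes, genome).consequence == "U5"
        assert classify_consequence(Variant("chr1", 25, "G", "A"), genes, genome).consequence == "U3"
        up = classify_consequence(Variant("chr1", 8, "T", "A"), genes, genome)
        assert up.consequence == "UP"
        dn = classify_consequence(Variant("chr1", 30, "G", "A"), genes, genome)
        assert dn.consequence == "DN"
        ig = classify_consequence(Variant("chr1", 47, "T", "A"), genes, genome)
        assert ig.consequence == "IG"

    def test_ref_mismatch_rejected(self, simple_genome):
        genome, genes = simple_genome
        with pytest.raises(ValueError, match="disagrees"):
            classify_consequence(Variant("chr1", 20, "C", "A"), genes, genome)


class TestSpliceCategories:
    @pytest.fixture()
    def intron_gene(self):
        # CDS "ATG GCA TAA" split across two exons by a 20 bp intron with
        # canonical GT..AG dinucleotides
        seq = "AAAAA" + "ATGGCA" + "GT" + "A" * 16 + "AG" + "TAA" + "AAAAA"
        genome = GenomeSequence({"c": seq})
        exon1 = (6, 11)
        intron = (12, 31)
        exon2 = (32, 34)
        gene = GeneModel("gi", "c", "+", 6, 34, exons=[exon1, exon2],
                         cds=[exon1, exon2])
        return genome, GeneSet([gene], flank=5)

    def test_canonical_splice(self, intron_gene):
        genome, genes = intron_gene
        for pos in (12, 13, 30, 31):      # first/last 2 bp of the intron
            ref = genome.sequence("c", pos)
            alt = "C" if ref != "C" else "T"
            assert classify_consequence(Variant("c", pos, ref, alt), genes,
                                        genome).consequence == "CS"

    def test_splice_region_and_intron(self, intron_gene):
        genome, genes = intron_gene
        rec = classify_consequence(Variant("c", 15, "A", "C"), genes, genome)
        assert rec.consequence == "S"     # 3-8 bp into the intron
        rec = classify_consequence(Variant("c", 21, "A", "C"), genes, genome)
        assert rec.consequence == "I"     # deep intron

    def test_coding_beats_splice_region(self, intron_gene):
        genome, genes = intron_gene
        # last CDS base of exon1 (pos 11, within 3 bp of the junction):
        # GCA -> GCx is synonymous Ala; SN outranks S
        rec = classify_consequence(Variant("c", 11, "A", "G"), genes, genome)
        assert rec.consequence == "SN"


class TestReverseStrandGene:
    def test_minus_strand_codons(self):
        # sense-strand CDS ATG GCT TAA encoded on the minus strand:
        # genomic segment is its reverse complement "TTAAGCCAT"
        seq = "AAAA" + "TTAAGCCAT" + "AAAA"
        genome = GenomeSequence({"c": seq})
        gene = GeneModel("gm", "c", "-", 5, 13, exons=[(5, 13)], cds=[(5, 13)])
        genes = GeneSet([gene], flank=4)
        # genomic pos 13 is the first CDS base (A of ATG read on minus strand)
        rec = classify_consequence(Variant("c", 13, "T", "G"), genes, genome)
        # T->G genomic is A->C on the transcript: ATG -> CTG, Met -> Leu
        assert (rec.consequence, rec.oAA, rec.nAA, rec.protPos) == ("NS", "M", "L", 1)
        # genomic pos 6 (T on plus) is codon 3 position 2: TAA -> TTA? on the
        # transcript: plus T -> transcript A; mutate plus T->C = transcript G:
        # TAA -> TGA, still a stop (synonymous stop retention)
        rec = classify_consequence(Variant("c", 6, "T", "C"), genes, genome)
        assert (rec.consequence, rec.oAA, rec.nAA) == ("SN", "*", "*")


class TestBruteForceOracle:
    def test_all_coding_snvs_match_whole_cds_translation(self, tiny_bundle):
        """Every possible coding SNV in the fixture genes: the classifier's
        amino-acid call must equal translating the whole mutant CDS."""
        genome, genes = tiny_bundle.genome, tiny_bundle.genes
        checked = 0
        for gene in list(genes)[:3]:
            cds_positions = gene.cds_positions()
            cds_seq = gene.cds_sequence(genome)
            protein = str(Seq(cds_seq).translate())
            for i, pos in enumerate(cds_positions):
                ref = genome.sequence(gene.chrom, int(pos))
                for alt in "ACGT":
                    if alt == ref:
                        continue
                    rec = classify_consequence(
                        Variant(gene.chrom, int(pos), ref, alt), genes, genome
                    )
                    mutant = list(cds_seq)
                    mutant[i] = alt  # sense-strand genes: no complementing
                    mutant_protein = str(Seq("".join(mutant)).translate())
                    codon_idx = i // 3
                    oAA, nAA = protein[codon_idx], mutant_protein[codon_idx]
                    if oAA == nAA:
                        expect = "SN"
                    elif nAA == "*":
                        expect = "SG"
                    elif oAA == "*":
                        expect = "SL"
                    else:
                        expect = "NS"
                    assert rec.consequence == expect, (gene.gene_id, pos, ref, alt)
                    assert (rec.oAA, rec.nAA) == (oAA, nAA)
                    assert rec.protPos == codon_idx + 1
                    checked += 1
        assert checked >= 200

    def test_class_semantics(self, tiny_bundle):
        """SN never changes the protein; NS always does; SG truncates; SL
        removes the terminal stop (implied by the oracle equality above on
        whole-CDS translations)."""
        genome, genes = tiny_bundle.genome, tiny_bundle.genes
        gene = next(iter(genes))
        cds_seq = gene.cds_sequence(genome)
        assert cds_seq.startswith("ATG")
        protein = str(Seq(cds_seq).translate())
        assert protein.endswith("*") and "*" not in protein[:-1]


class TestAnnotatorAssembly:
    def test_remap_density(self):
        track = IntervalTrack("ReMap")
        for _ in range(3):
            track.add("c", 5, 15)
        track.add("c", 8, 10)      # nested: still one count per record
        assert remap_density(Variant("c", 9, "A", "G"), track) == 4
        assert remap_density(Variant("c", 50, "A", "G"), track) == 0

    def test_cds_distance_and_missing_tracks(self, simple_genome):
        genome, genes = simple_genome
        sparse = PerBaseTrack("PhyloP")
        sparse.add("chr1", 1, 5, 1.0)
        ann = VariantAnnotator(genome, genes, per_base_tracks={"PhyloP": sparse})
        variants = pd.DataFrame(
            [("chr1", 20, "T", "A"), ("chr1", 30, "G", "A"), ("chr1", 3, "G", "A")],
            columns=["chrom", "pos", "ref", "alt"],
        )
        table = ann.annotate(variants)
        assert table.loc[0, "CDSdist"] == 0          # inside CDS
        assert table.loc[1, "CDSdist"] == 30 - 23    # 7 bp from the CDS edge
        assert table.loc[0, "Grantham"] is None      # SN variant
        assert np.isnan(table.loc[0, "PhyloP"])      # missing, not 0
        assert table.loc[2, "PhyloP"] == 1.0

    def test_gc_fraction_window(self):
        genome = GenomeSequence({"c": "G" * 100 + "A" * 100})
        ann = VariantAnnotator(genome, GeneSet([], flank=10))
        table = ann.annotate(
            pd.DataFrame([("c", 50, "G", "A"), ("c", 150, "A", "G")],
                         columns=["chrom", "pos", "ref", "alt"])
        )
        assert table.loc[0, "GC"] == 1.0
        assert table.loc[1, "GC"] == 0.0

    def test_undeclared_track_rejected(self, simple_genome):
        genome, genes = simple_genome
        ann = VariantAnnotator(genome, genes)
        with pytest.raises(KeyError, match="undeclared"):
            ann.require_tracks(["PhyloP"])
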