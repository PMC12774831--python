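"""Minimal gene models (gene -> single transcript -> exons/CDS) used by the
consequence classifier and the codon-level analyses."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from intervaltree import IntervalTree

from .io import GenomeSequence, IntervalTrack

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    start: int                     # gene span, 1-based inclusive
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    n_transcripts: int = 1

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self._cds_positions: np.ndarray | None = None

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_positions(self) -> np.ndarray:
        """Genomic positions of the spliced CDS, in translation order."""
        if self._cds_positions is None:
            parts = [np.arange(s, e + 1) for s, e in self.cds]
            pos = np.concatenate(parts) if parts else np.array([], dtype=int)
            if self.strand == "-":
                pos = pos[::-1]
            self._cds_positions = pos
        return self._cds_positions

    def cds_index(self, pos: int) -> int | None:
        """1-based index of a genomic position within the spliced CDS."""
        positions = self.cds_positions()
        hits = np.flatnonzero(positions == pos)
        return int(hits[0]) + 1 if hits.size else None

    def cds_sequence(self, genome: GenomeSequence) -> str:
        seq = "".join(genome.subseq(self.chrom, s, e) for s, e in self.cds)
        return revcomp(seq) if self.strand == "-" else seq

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out


class GeneSet:
    """Gene models indexed for positional lookup, with a CDS interval track."""

    def __init__(self, genes: list[GeneModel], flank: int = 500):
        self.flank = flank
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        self.cds_track = IntervalTrack("CDS")
        for g in genes:
            self._trees.setdefault(g.chrom, IntervalTree()).addi(
                max(1, g.start - flank), g.end + flank + 1, g.gene_id
            )
            for s, e in g.cds:
                self.cds_track.add(g.chrom, s, e, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def genes_near(self, chrom: str, pos: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [self.genes[iv.data] for iv in sorted(tree[pos], key=lambda i: i.begin)]

    def single_transcript_sense(self) -> "GeneSet":
        """Subset used by codon-position analyses: unique-transcript,
        sense-strand genes only."""
        keep = [
            g for g in self.genes.values()
            if g.n_transcripts == 1 and g.strand == "+" and g.is_coding
        ]
        return GeneSet(keep, flank=self.flank)


def read_gene_models(path: str | Path, flank: int = 500) -> GeneSet:
    """Load gene models from GFF3 (gene / mRNA / exon / CDS features)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for gene in db.features_of_type("gene"):
        transcripts = list(db.children(gene, featuretype="mRNA"))
        n_tx = max(1, len(transcripts))
        tx = transcripts[0] if transcripts else gene
        exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon")]
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS")]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=exons or [(gene.start, gene.end)],
                cds=cds,
                n_transcripts=n_tx,
            )
        )
    return GeneSet(genes, flank=flank)


def write_gff3(genes: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            cols = [g.chrom, "snvcadd", "gene", str(g.start), str(g.end), ".",
                    g.strand, ".", f"ID={g.gene_id}"]
            fh.write("\t".join(cols) + "\n")
            tx_id = f"{g.gene_id}.t1"
            fh.write("\t".join([g.chrom, "snvcadd", "mRNA", str(g.start),
                                str(g.end), ".", g.strand, ".",
                                f"ID={tx_id};Parent={g.gene_id}"]) + "\n")
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write("\t".join([g.chrom, "snvcadd", "exon", str(s), str(e),
                                    ".", g.strand, ".",
                                    f"ID={tx_id}.exon{i};Parent={tx_id}"]) + "\n")
            pieces = g.cds if g.strand == "+" else list(reversed(g.cds))
            done = 0
            for i, (s, e) in enumerate(pieces, 1):
                phase = (3 - done % 3) % 3
                fh.write("\t".join([g.chrom, "snvcadd", "CDS", str(s), str(e),
                                    ".", g.strand, str(phase),
                                    f"ID={tx_id}.cds{i};Parent={tx_id}"]) + "\n")
                done += e - s + 1
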