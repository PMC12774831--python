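"""Base annotations for single nucleotide variants.

Covers the sequence-based consequence classifier (a deterministic, VEP-like
categorization into 14 classes), Grantham distances, per-base track lookups,
interval memberships, regulatory-record density and CDS distance.  The
assembled table of base annotations feeds the combinatorial feature expansion
in :mod:`snvcadd.features`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .genes import GeneModel, GeneSet, revcomp
from .io import GenomeSequence, IntervalTrack, PerBaseTrack

# Consequence categories, most severe first.  A variant hitting several
# categories (possibly through several genes) takes the most severe one.
CONSEQUENCE_PRIORITY = [
    "CS", "SG", "SL", "NS", "SN", "S", "U5", "U3", "NC", "I", "UP", "DN", "IG",
    "O",
]
_RANK = {c: i for i, c in enumerate(CONSEQUENCE_PRIORITY)}

AMINO_ACIDS = tuple(sorted("ACDEFGHIKLMNPQRSTVWY")) + ("*",)

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


@dataclass
class ConsequenceRecord:
    consequence: str
    oAA: str | None = None
    nAA: str | None = None
    CDSpos: int | None = None
    protPos: int | None = None
    relCDSpos: float | None = None
    relProtPos: float | None = None


# ---------------------------------------------------------------------------
# Grantham distances
# ---------------------------------------------------------------------------

_GRANTHAM: pd.DataFrame | None = None


def _grantham_matrix() -> pd.DataFrame:
    global _GRANTHAM
    if _GRANTHAM is None:
        ref = importlib.resources.files("snvcadd.data").joinpath("grantham.tsv")
        with importlib.resources.as_file(ref) as path:
            _GRANTHAM = pd.read_csv(path, sep="\t", index_col=0)
    return _GRANTHAM


def grantham(oAA: str, nAA: str) -> float | None:
    """Symmetric Grantham (1974) distance; None for stop symbols."""
    if oAA == "*" or nAA == "*":
        return None
    mat = _grantham_matrix()
    try:
        return float(mat.loc[oAA, nAA])
    except KeyError as exc:
        raise KeyError(f"not a standard amino acid: {exc}") from exc


# ---------------------------------------------------------------------------
# Consequence classification
# ---------------------------------------------------------------------------

def _coding_consequence(
    gene: GeneModel, pos: int, alt: str, genome: GenomeSequence
) -> ConsequenceRecord:
    cds_idx = gene.cds_index(pos)
    assert cds_idx is not None
    cds_len = gene.cds_length
    if cds_len % 3:
        raise ValueError(f"gene {gene.gene_id}: CDS length {cds_len} not divisible by 3")
    codon_num = (cds_idx - 1) // 3 + 1
    offset = (cds_idx - 1) % 3
    positions = gene.cds_positions()
    codon_pos = positions[(codon_num - 1) * 3 : codon_num * 3]
    codon = "".join(genome.sequence(gene.chrom, int(p)) for p in codon_pos)
    alt_base = alt
    if gene.strand == "-":
        codon = "".join(revcomp(b) for b in codon)
        alt_base = revcomp(alt)
    new_codon = codon[:offset] + alt_base + codon[offset + 1 :]
    oAA = translate_codon(codon)
    nAA = translate_codon(new_codon)
    if oAA == "*" and nAA != "*":
        cons = "SL"
    elif nAA == "*" and oAA != "*":
        cons = "SG"
    elif oAA == nAA:
        cons = "SN"
    else:
        cons = "NS"
    n_codons = cds_len // 3  # protein length counted in codons incl. stop
    return ConsequenceRecord(
        consequence=cons,
        oAA=oAA,
        nAA=nAA,
        CDSpos=cds_idx,
        protPos=codon_num,
        relCDSpos=cds_idx / cds_len,
        relProtPos=codon_num / n_codons,
    )


def _gene_consequences(
    gene: GeneModel, pos: int, alt: str, genome: GenomeSequence, flank: int
) -> list[ConsequenceRecord]:
    out: list[ConsequenceRecord] = []
    in_exon = any(s <= pos <= e for s, e in gene.exons)
    if gene.is_coding and any(s <= pos <= e for s, e in gene.cds):
        out.append(_coding_consequence(gene, pos, alt, genome))
    # splice categories from intron boundaries
    for s, e in gene.introns():
        if s <= pos <= e:
            d = min(pos - s, e - pos)  # distance into the intron, 0-based
            if d <= 1:
                out.append(ConsequenceRecord("CS"))
            elif d <= 7:
                out.append(ConsequenceRecord("S"))
            else:
                out.append(ConsequenceRecord("I"))
        elif in_exon and (0 < s - pos <= 3 or 0 < pos - e <= 3):
            out.append(ConsequenceRecord("S"))  # exonic end of the splice region
    if in_exon and not any(s <= pos <= e for s, e in gene.cds):
        if not gene.is_coding:
            out.append(ConsequenceRecord("NC"))
        else:
            positions = gene.cds_positions()
            cds_first, cds_last = int(positions[0]), int(positions[-1])
            if gene.strand == "+":
                out.append(ConsequenceRecord("U5" if pos < cds_first else "U3"))
            else:
                out.append(ConsequenceRecord("U5" if pos > cds_first else "U3"))
    if pos < gene.start or pos > gene.end:
        if gene.start - flank <= pos < gene.start:
            out.append(ConsequenceRecord("UP" if gene.strand == "+" else "DN"))
        elif gene.end < pos <= gene.end + flank:
            out.append(ConsequenceRecord("DN" if gene.strand == "+" else "UP"))
    return out


def classify_consequence(
    variant, genes: GeneSet, genome: GenomeSequence, flank: int = 500
) -> ConsequenceRecord:
    """Assign the most severe consequence of a variant across gene models.

    Priority: CS > SG > SL > NS > SN > S > U5 > U3 > NC > I > UP > DN > IG.
    Variants away from every gene (beyond the upstream/downstream flank) are
    intergenic.
    """
    chrom, pos, ref, alt = variant.chrom, int(variant.pos), variant.ref, variant.alt
    if genome.sequence(chrom, pos) != ref:
        raise ValueError(
            f"variant ref {ref} disagrees with genome at {chrom}:{pos}"
        )
    candidates: list[ConsequenceRecord] = []
    for gene in genes.genes_near(chrom, pos):
        try:
            candidates.extend(_gene_consequences(gene, pos, alt, genome, flank))
        except ValueError:
            continue  # invalid CDS: score against remaining transcripts
    if not candidates:
        return ConsequenceRecord("IG")
    return min(candidates, key=lambda r: _RANK[r.consequence])


def remap_density(variant, records: IntervalTrack) -> int:
    """Number of regulatory records whose interval covers the position."""
    return records.count(variant.chrom, int(variant.pos))


# ---------------------------------------------------------------------------
# Assembly of the base-annotation table
# ---------------------------------------------------------------------------

PER_BASE_TRACK_NAMES = [
    "PhyloP", "PhyloP124", "PhyloP_all", "PhastCons", "PhastCons124",
    "GerpRS_all", "GERPN_all", "MGW", "Roll", "HelT", "ProT", "EP",
]
REPEAT_CLASSES = [
    "rep_DNA", "rep_LINE", "rep_LTR", "rep_LowComplexity", "rep_RollingCircle",
    "rep_Satellite", "rep_Simple", "rep_RNA",
]
INDICATOR_TRACK_NAMES = REPEAT_CLASSES + ["miRNA", "TFBS", "CRM", "pCRM"]
CHROMATIN_TRACKS = ["ChromatinBG3", "ChromatinS2"]

GC_WINDOW = 75  # bp window for local GC fraction, centered on the variant


class VariantAnnotator:
    """Compute the table of base annotations for a variant set.

    Parameters
    ----------
    genome, genes : reference sequence and gene models.
    per_base_tracks : mapping name -> PerBaseTrack (conservation, DNA shape).
    interval_tracks : mapping name -> IntervalTrack (repeats, TFBS, ...,
        plus the two chromatin-state tracks whose interval values are state
        labels).
    remap : IntervalTrack of regulatory records, counted per position.
    """

    def __init__(
        self,
        genome: GenomeSequence,
        genes: GeneSet,
        per_base_tracks: dict[str, PerBaseTrack] | None = None,
        interval_tracks: dict[str, IntervalTrack] | None = None,
        remap: IntervalTrack | None = None,
        flank: int = 500,
    ):
        self.genome = genome
        self.genes = genes
        self.per_base_tracks = per_base_tracks or {}
        self.interval_tracks = interval_tracks or {}
        self.remap = remap
        self.flank = flank
        self._gc_prefix: dict[str, np.ndarray] = {}

    def require_tracks(self, names: list[str]) -> None:
        known = set(self.per_base_tracks) | set(self.interval_tracks)
        missing = [n for n in names if n not in known]
        if missing:
            raise KeyError(f"undeclared track(s) referenced: {missing}")

    def _gc_fraction(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        if chrom not in self._gc_prefix:
            arr = self.genome.base_array(chrom)
            gc = ((arr == b"G") | (arr == b"C")).astype(np.int64)
            self._gc_prefix[chrom] = np.concatenate([[0], np.cumsum(gc)])
        prefix = self._gc_prefix[chrom]
        n = len(prefix) - 1
        half = GC_WINDOW // 2
        lo = np.clip(positions - 1 - half, 0, n)
        hi = np.clip(positions + half, 0, n)
        return (prefix[hi] - prefix[lo]) / np.maximum(hi - lo, 1)

    def annotate(self, variants: pd.DataFrame) -> pd.DataFrame:
        """Return one row of base annotations per variant (input order kept)."""
        records = []
        for var in variants.itertuples(index=False):
            rec = classify_consequence(var, self.genes, self.genome, self.flank)
            row: dict[str, object] = {
                "Consequence": rec.consequence,
                "oAA": rec.oAA,
                "nAA": rec.nAA,
                "CDSpos": rec.CDSpos,
                "relCDSpos": rec.relCDSpos,
                "protPos": rec.protPos,
                "relProtPos": rec.relProtPos,
            }
            if rec.consequence == "NS":
                row["Grantham"] = grantham(rec.oAA, rec.nAA)
            else:
                row["Grantham"] = None
            pos = int(var.pos)
            row["ReMapDensity"] = (
                self.remap.count(var.chrom, pos) if self.remap is not None else 0
            )
            d = self.genes.cds_track.distance(var.chrom, pos)
            row["CDSdist"] = d if d is not None else None
            row["CDS"] = bool(self.genes.cds_track.contains(var.chrom, pos))
            for name in INDICATOR_TRACK_NAMES:
                track = self.interval_tracks.get(name)
                row[name] = bool(track.contains(var.chrom, pos)) if track else False
            for name in CHROMATIN_TRACKS:
                track = self.interval_tracks.get(name)
                row[name] = track.label(var.chrom, pos) if track else None
            records.append(row)
        out = pd.DataFrame(records)

        # vectorized parts: per-base tracks and GC content
        chroms = variants["chrom"].to_numpy()
        positions = variants["pos"].to_numpy(dtype=np.int64)
        gc = np.empty(len(variants))
        track_vals = {name: np.full(len(variants), np.nan)
                      for name in self.per_base_tracks}
        for chrom in pd.unique(chroms):
            mask = chroms == chrom
            gc[mask] = self._gc_fraction(chrom, positions[mask])
            for name, track in self.per_base_tracks.items():
                track_vals[name][mask] = track.values(chrom, positions[mask])
        out["GC"] = gc
        for name, vals in track_vals.items():
            out[name] = vals
        out.index = variants.index
        return out
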