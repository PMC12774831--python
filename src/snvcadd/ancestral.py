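"""Ancestral sequence extraction from alignment blocks.

Maps the reconstructed ancestor row of each alignment block onto sense-strand
reference coordinates, and reports how much of the reference the ancestor
covers (reconstruction of deep ancestors is typically sparse, and a strong
chromosome or coding-sequence bias in coverage would skew the derived and
simulated variant sets toward particular regions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io import AlignmentBlock, GenomeSequence, IntervalTrack, VALID_BASES

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_GAP = 0  # sentinel byte for "unreconstructed"


class AncestorMap:
    """Per-chromosome ancestral base aligned to 1-based reference coordinates.

    Positions without a reconstructed base (alignment gaps, ambiguity codes,
    uncovered regions) report ``None``.
    """

    def __init__(self, chrom_lengths: dict[str, int]):
        self._arrays = {
            chrom: np.zeros(n, dtype=np.uint8) for chrom, n in chrom_lengths.items()
        }
        self.conflict_count = 0
        self.duplicate_ancestor_rows = 0

    @property
    def chrom_names(self) -> list[str]:
        return list(self._arrays)

    def length(self, chrom: str) -> int:
        return len(self._arrays[chrom])

    def set_base(self, chrom: str, pos: int, base: str) -> None:
        arr = self._arrays[chrom]
        if not 1 <= pos <= len(arr):
            raise IndexError(f"position {pos} outside reference length on {chrom}")
        if arr[pos - 1] != _GAP:
            self.conflict_count += 1  # first block wins
            return
        arr[pos - 1] = ord(base)

    def base(self, chrom: str, pos: int) -> str | None:
        arr = self._arrays[chrom]
        if not 1 <= pos <= len(arr):
            raise IndexError(f"position {pos} outside reference length on {chrom}")
        b = arr[pos - 1]
        return None if b == _GAP else chr(b)

    def base_array(self, chrom: str) -> np.ndarray:
        """uint8 array; 0 marks unreconstructed positions."""
        return self._arrays[chrom]

    def clear_range(self, chrom: str, start: int, end: int) -> None:
        """Mark [start, end] (1-based inclusive, clipped) as unreconstructed."""
        arr = self._arrays[chrom]
        arr[max(0, start - 1) : min(len(arr), end)] = _GAP

    def covered_positions(self, chrom: str) -> np.ndarray:
        """1-based positions with a reconstructed base."""
        return np.flatnonzero(self._arrays[chrom] != _GAP) + 1

    def coverage(self, chrom: str) -> float:
        arr = self._arrays[chrom]
        return float((arr != _GAP).mean()) if len(arr) else 0.0


def extract_ancestor(
    blocks: Iterable[AlignmentBlock],
    ancestor_label: str,
    reference_label: str,
    chrom_lengths: dict[str, int] | None = None,
) -> AncestorMap:
    """Project the ancestor row of each block onto reference coordinates.

    For every alignment column where both the reference and ancestor rows hold
    a base, the ancestor base is stored at the reference position (complemented
    when the reference row is on the minus strand, so stored bases are always
    sense-strand).  Ambiguity codes count as unreconstructed.  Overlapping
    blocks: the first block wins and the conflict is counted.
    """
    blocks = list(blocks)
    seen_ancestor = False
    lengths: dict[str, int] = dict(chrom_lengths or {})
    for block in blocks:
        for row in block.rows:
            if row.species == reference_label:
                lengths.setdefault(row.chrom, row.src_size)
    if not lengths:
        raise ValueError(f"reference label {reference_label!r} absent from all blocks")
    anc = AncestorMap(lengths)

    for block in blocks:
        ref_rows = [r for r in block.rows if r.species == reference_label]
        anc_rows = [r for r in block.rows if r.species == ancestor_label]
        if not anc_rows or not ref_rows:
            continue
        seen_ancestor = True
        if len(anc_rows) > 1:
            anc.duplicate_ancestor_rows += 1  # paralogy: flagged, first row used
        ref, anc_row = ref_rows[0], anc_rows[0]
        if ref.strand == "-" and ref.src_size <= 0:
            raise ValueError(
                "reference row on '-' strand without source length metadata"
            )
        j = 0  # count of non-gap reference bases seen
        for col, ref_char in enumerate(ref.text):
            if ref_char == "-":
                continue
            if ref.strand == "+":
                pos = ref.start + j + 1
            else:
                pos = ref.src_size - ref.start - j
            j += 1
            anc_char = anc_row.text[col].upper()
            if anc_char not in VALID_BASES:
                continue  # gap / N / IUPAC ambiguity -> unreconstructed
            if ref.strand == "-":
                anc_char = _COMPLEMENT[anc_char]
            anc.set_base(ref.chrom, pos, anc_char)

    if not seen_ancestor:
        raise ValueError(f"ancestor label {ancestor_label!r} absent from all blocks")
    return anc


@dataclass
class CoverageReport:
    genome_coverage: float
    per_chrom_coverage: dict[str, float]
    cds_coverage: float
    biased_chroms: list[str] = field(default_factory=list)


def coverage_report(
    anc: AncestorMap,
    genome: GenomeSequence,
    cds: IntervalTrack | None = None,
    bias_ratio: float = 2.0,
) -> CoverageReport:
    """Coverage fractions genome-wide, per chromosome and within CDS.

    A chromosome is flagged as biased when its coverage differs from the
    genome-wide coverage by more than ``bias_ratio`` in either direction.
    """
    per_chrom = {c: anc.coverage(c) for c in genome.chrom_names}
    total = sum(genome.length(c) for c in genome.chrom_names)
    covered = sum(per_chrom[c] * genome.length(c) for c in genome.chrom_names)
    genome_cov = covered / total if total else 0.0

    cds_positions = cds_covered = 0
    if cds is not None:
        for chrom in genome.chrom_names:
            arr = anc.base_array(chrom)
            for start, end, _ in cds.intervals(chrom):
                end = min(end, len(arr))
                if start > end:
                    continue
                cds_positions += end - start + 1
                cds_covered += int((arr[start - 1 : end] != _GAP).sum())
    cds_cov = cds_covered / cds_positions if cds_positions else float("nan")

    biased = []
    for chrom, cov in per_chrom.items():
        if genome_cov > 0 and (cov > bias_ratio * genome_cov or cov < genome_cov / bias_ratio):
            biased.append(chrom)
    return CoverageReport(
        genome_coverage=genome_cov,
        per_chrom_coverage=per_chrom,
        cds_coverage=cds_cov,
        biased_chroms=biased,
    )
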