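"""Readers and writers for the external formats the pipeline touches.

Coordinate contract: everything exposed by this module is 1-based with both
ends inclusive.  External 0-based half-open sources (BED, bedGraph, MAF block
starts) are converted here and only here.  GFF3 and VCF are 1-based already.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO
from intervaltree import IntervalTree

VALID_BASES = frozenset("ACGT")
_IUPAC = frozenset("ACGTNRYSWKMBDHV")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

class GenomeSequence:
    """In-memory reference genome with 1-based, inclusive coordinate access.

    Bases are stored uppercase as a byte array per chromosome; anything not in
    the IUPAC alphabet is rejected at load time.
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise FormatError("no records")
        self._arrays: dict[str, np.ndarray] = {}
        self.chrom_names: list[str] = []
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _IUPAC
            if bad:
                raise FormatError(
                    f"non-IUPAC character(s) {sorted(bad)} in record {name!r}"
                )
            self.chrom_names.append(name)
            self._arrays[name] = np.frombuffer(seq.encode("ascii"), dtype="S1").copy()

    def length(self, chrom: str) -> int:
        return len(self._arrays[chrom])

    def _check(self, chrom: str, pos: int) -> None:
        n = self.length(chrom)
        if not 1 <= pos <= n:
            raise IndexError(f"position {pos} outside [1, {n}] on {chrom}")

    def sequence(self, chrom: str, pos: int) -> str:
        self._check(chrom, pos)
        return self._arrays[chrom][pos - 1].decode()

    def subseq(self, chrom: str, start: int, end: int) -> str:
        """Bases from start to end, both 1-based inclusive."""
        self._check(chrom, start)
        self._check(chrom, end)
        return self._arrays[chrom][start - 1 : end].tobytes().decode()

    def base_array(self, chrom: str) -> np.ndarray:
        """Byte array of bases (dtype S1); index is 0-based internally."""
        return self._arrays[chrom]

    def bases_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        pos = np.asarray(positions)
        if pos.size and (pos.min() < 1 or pos.max() > self.length(chrom)):
            raise IndexError(f"positions outside [1, {self.length(chrom)}] on {chrom}")
        return self._arrays[chrom][pos - 1]


def read_genome(path: str | Path) -> GenomeSequence:
    """Load a FASTA file; multi-line records concatenated, case folded up."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise FormatError(f"duplicate chromosome name {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    if not seqs:
        raise FormatError("no records")
    return GenomeSequence(seqs)


def write_genome(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f">{chrom}\n")
            seq = genome.base_array(chrom).tobytes().decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# MAF alignment blocks
# ---------------------------------------------------------------------------

@dataclass
class AlignmentRow:
    src: str          # "species.chrom" or plain label
    start: int        # 0-based start on the strand of this row (MAF convention)
    size: int         # number of non-gap bases
    strand: str       # "+" or "-"
    src_size: int     # full length of the source sequence
    text: str         # gapped, aligned text

    @property
    def species(self) -> str:
        return self.src.split(".", 1)[0]

    @property
    def chrom(self) -> str:
        return self.src.split(".", 1)[1] if "." in self.src else self.src


@dataclass
class AlignmentBlock:
    rows: list[AlignmentRow]


def read_alignment_blocks(path: str | Path) -> Iterator[AlignmentBlock]:
    """Stream MAF alignment blocks; rows within a block share text length."""
    for msa in AlignIO.parse(str(path), "maf"):
        rows = []
        for rec in msa:
            ann = rec.annotations
            rows.append(
                AlignmentRow(
                    src=rec.id,
                    start=int(ann["start"]),
                    size=int(ann["size"]),
                    strand="+" if ann["strand"] in (1, "+") else "-",
                    src_size=int(ann["srcSize"]),
                    text=str(rec.seq),
                )
            )
        lengths = {len(r.text) for r in rows}
        if len(lengths) > 1:
            raise FormatError(f"rows of unequal gapped length in block: {sorted(lengths)}")
        yield AlignmentBlock(rows=rows)


def write_maf(blocks: Iterable[AlignmentBlock], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for block in blocks:
            fh.write("a\n")
            for r in block.rows:
                fh.write(
                    f"s {r.src} {r.start} {r.size} {r.strand} {r.src_size} {r.text}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# Population allele frequencies (VCF)
# ---------------------------------------------------------------------------

class PopulationAF:
    """Alt-allele frequencies per site; absent sites report ``None``."""

    def __init__(self) -> None:
        self._records: dict[tuple[str, int], list[tuple[str, float]]] = {}

    def add(self, chrom: str, pos: int, alt: str, freq: float) -> None:
        self._records.setdefault((chrom, pos), []).append((alt, float(freq)))

    def lookup(self, chrom: str, pos: int) -> list[tuple[str, float]] | None:
        return self._records.get((chrom, pos))

    def total_alt_freq(self, chrom: str, pos: int) -> float | None:
        recs = self.lookup(chrom, pos)
        if recs is None:
            return None
        return sum(f for _, f in recs)

    def __len__(self) -> int:
        return sum(len(v) for v in self._records.values())

    def sites(self) -> Iterable[tuple[str, int]]:
        return self._records.keys()

    def merge(self, other: "PopulationAF", policy: str = "mean") -> "PopulationAF":
        """Pool two AF sources.  ``mean``: unweighted average at shared sites;
        ``intersect``: keep only shared sites (averaged)."""
        out = PopulationAF()
        keys = set(self._records) | set(other._records)
        if policy == "intersect":
            keys = set(self._records) & set(other._records)
        elif policy != "mean":
            raise ValueError(f"unknown pooling policy {policy!r}")
        for key in keys:
            per_alt: dict[str, list[float]] = {}
            for src in (self, other):
                for alt, f in src._records.get(key, []):
                    per_alt.setdefault(alt, []).append(f)
            for alt, fs in per_alt.items():
                out.add(key[0], key[1], alt, sum(fs) / len(fs))
        return out


def read_population_af(path: str | Path, sample_filter: str | None = None) -> PopulationAF:
    """Read alt-allele frequencies from a VCF.

    INFO/AF is preferred; otherwise frequencies are computed from genotypes.
    With ``sample_filter="PASS"`` only FILTER==PASS sites are kept.
    """
    import pysam

    af = PopulationAF()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if sample_filter is not None:
                filters = list(rec.filter.keys())
                if filters and sample_filter not in filters:
                    continue
                if not filters and sample_filter != "PASS":
                    continue
            alts = rec.alts or ()
            if not alts:
                continue
            info_af = rec.info.get("AF") if "AF" in rec.info else None
            if info_af is not None:
                freqs = list(np.atleast_1d(info_af).astype(float))
            elif rec.samples is not None and len(rec.samples) > 0:
                n_allele = len(alts) + 1
                counts = np.zeros(n_allele)
                for sample in rec.samples.values():
                    for a in sample.get("GT") or ():
                        if a is not None:
                            counts[a] += 1
                total = counts.sum()
                if total == 0:
                    raise FormatError(
                        f"site {rec.chrom}:{rec.pos} has neither AF INFO nor genotypes"
                    )
                freqs = list(counts[1:] / total)
            else:
                raise FormatError(
                    f"site {rec.chrom}:{rec.pos} has neither AF INFO nor genotypes"
                )
            for alt, f in zip(alts, freqs):
                af.add(rec.chrom, rec.pos, alt, f)
    return af


# ---------------------------------------------------------------------------
# Interval tracks (BED / GFF3-style intervals)
# ---------------------------------------------------------------------------

class IntervalTrack:
    """Named intervals with 1-based inclusive ends; supports membership,
    per-position record counts and nearest-interval distance."""

    def __init__(self, name: str):
        self.name = name
        self._trees: dict[str, IntervalTree] = {}
        self._merged: dict[str, np.ndarray] | None = None
        self._serial = 0  # keeps duplicate records distinct (density counting)

    def add(self, chrom: str, start: int, end: int, value=None) -> None:
        if start > end:
            raise FormatError(f"interval start {start} > end {end} on {chrom}")
        # intervaltree is half-open; store [start, end+1)
        self._trees.setdefault(chrom, IntervalTree()).addi(
            start, end + 1, (self._serial, value)
        )
        self._serial += 1
        self._merged = None

    def intervals(self, chrom: str) -> list[tuple[int, int, object]]:
        tree = self._trees.get(chrom, IntervalTree())
        return sorted((iv.begin, iv.end - 1, iv.data[1]) for iv in tree)

    def chroms(self) -> list[str]:
        return sorted(self._trees)

    def contains(self, chrom: str, pos: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos))

    def count(self, chrom: str, pos: int) -> int:
        tree = self._trees.get(chrom)
        return len(tree[pos]) if tree is not None else 0

    def label(self, chrom: str, pos: int) -> object | None:
        """Value of the first covering interval (smallest start)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = sorted(tree[pos], key=lambda iv: (iv.begin, iv.end, iv.data[0]))
        return hits[0].data[1] if hits else None

    def _merged_arrays(self) -> dict[str, np.ndarray]:
        if self._merged is None:
            self._merged = {}
            for chrom, tree in self._trees.items():
                t = IntervalTree(tree)
                t.merge_overlaps(strict=False)
                ivs = sorted((iv.begin, iv.end - 1) for iv in t)
                self._merged[chrom] = np.array(ivs, dtype=np.int64).reshape(-1, 2)
        return self._merged

    def distance(self, chrom: str, pos: int) -> int | None:
        """0 inside an interval, else distance in bp to the nearest one."""
        merged = self._merged_arrays().get(chrom)
        if merged is None or merged.size == 0:
            return None
        starts, ends = merged[:, 0], merged[:, 1]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        best = None
        if i >= 0:
            if pos <= ends[i]:
                return 0
            best = pos - ends[i]
        if i + 1 < len(starts):
            d = starts[i + 1] - pos
            best = d if best is None else min(best, d)
        return int(best)


def read_bed_track(path: str | Path, name: str | None = None) -> IntervalTrack:
    """BED (0-based half-open) to a 1-based inclusive IntervalTrack."""
    track = IntervalTrack(name or Path(path).stem)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            value = parts[3] if len(parts) > 3 else None
            track.add(chrom, start + 1, end, value)
    return track


def read_gff_track(path: str | Path, name: str | None = None,
                   feature_types: set[str] | None = None) -> IntervalTrack:
    """GFF3 intervals (already 1-based inclusive)."""
    track = IntervalTrack(name or Path(path).stem)
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            if feature_types and parts[2] not in feature_types:
                continue
            track.add(parts[0], int(parts[3]), int(parts[4]), parts[2])
    return track


def write_bed_track(track: IntervalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, end, value in track.intervals(chrom):
                cols = [chrom, str(start - 1), str(end)]
                if value is not None:
                    cols.append(str(value))
                fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# Per-base numeric tracks (bedGraph / wiggle / TSV)
# ---------------------------------------------------------------------------

class PerBaseTrack:
    """Piecewise-constant per-base values; missing positions return None."""

    def __init__(self, name: str):
        self.name = name
        self._chunks: dict[str, list[tuple[int, int, float]]] = {}
        self._compiled: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        value = float(value)
        if not np.isfinite(value):
            raise FormatError(f"non-finite value at {chrom}:{start}-{end}")
        self._chunks.setdefault(chrom, []).append((start, end, value))
        self._compiled.pop(chrom, None)

    def _compile(self, chrom: str):
        if chrom not in self._compiled:
            ivs = sorted(self._chunks.get(chrom, []))
            arr = np.array(ivs, dtype=float).reshape(-1, 3)
            self._compiled[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return self._compiled[chrom]

    def value(self, chrom: str, pos: int) -> float | None:
        out = self.values(chrom, np.array([pos]))
        return None if np.isnan(out[0]) else float(out[0])

    def values(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Vectorized lookup; NaN marks missing positions."""
        starts, ends, vals = self._compile(chrom)
        pos = np.asarray(positions, dtype=np.int64)
        out = np.full(pos.shape, np.nan)
        if starts.size == 0:
            return out
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = idx >= 0
        inside = np.zeros_like(ok)
        inside[ok] = pos[ok] <= ends[idx[ok]]
        out[inside] = vals[idx[inside]]
        return out

    def chroms(self) -> list[str]:
        return sorted(self._chunks)

    def segments(self, chrom: str) -> list[tuple[int, int, float]]:
        return sorted(self._chunks.get(chrom, []))


def read_per_base_track(path: str | Path, name: str | None = None,
                        dialect: str | None = None) -> PerBaseTrack:
    """Read bedGraph, fixed/variable-step wiggle, or 3-column TSV
    (chrom, pos, value).  The dialect is sniffed when not given."""
    path = Path(path)
    track = PerBaseTrack(name or path.stem)
    if dialect is None:
        suffix = path.suffix.lower()
        dialect = {".bedgraph": "bedgraph", ".wig": "wig", ".tsv": "tsv"}.get(suffix)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if dialect is None:
        dialect = "wig" if any(
            l.startswith(("fixedStep", "variableStep")) for l in lines
        ) else "bedgraph"
        if dialect == "bedgraph" and lines:
            first = next((l for l in lines if l and not l.startswith(("#", "track"))), "")
            if len(first.split("\t")) == 3:
                dialect = "tsv"
    if dialect == "bedgraph":
        for line in lines:
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            track.add(chrom, int(start) + 1, int(end), float(value))
    elif dialect == "tsv":
        for line in lines:
            if not line or line.startswith("#"):
                continue
            chrom, pos, value = line.split("\t")[:3]
            track.add(chrom, int(pos), int(pos), float(value))
    elif dialect == "wig":
        chrom, start, step, span, mode = None, None, 1, 1, None
        for line in lines:
            if not line or line.startswith(("#", "track")):
                continue
            if line.startswith("fixedStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                start = int(kv["start"])
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                mode = "fixed"
            elif line.startswith("variableStep"):
                kv = dict(p.split("=") for p in line.split()[1:])
                chrom = kv["chrom"]
                span = int(kv.get("span", 1))
                mode = "variable"
            elif mode == "fixed":
                track.add(chrom, start, start + span - 1, float(line))
                start += step
            elif mode == "variable":
                p, v = line.split()
                track.add(chrom, int(p), int(p) + span - 1, float(v))
            else:
                raise FormatError("wiggle data before any step declaration")
    else:
        raise FormatError(f"unknown per-base track dialect {dialect!r}")
    return track


def write_bedgraph(track: PerBaseTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms():
            for start, end, value in track.segments(chrom):
                fh.write(f"{chrom}\t{start - 1}\t{end}\t{value:g}\n")


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ["chrom", "pos", "ref", "alt", "score"]


def write_scores(records: pd.DataFrame | Iterable, path: str | Path) -> None:
    """Write a score table sorted by (chrom, pos, alt) with 6-digit scores."""
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records), columns=SCORE_COLUMNS)
    df = records[SCORE_COLUMNS].copy()
    if len(df) and ((df["score"] < 0).any() or (df["score"] > 1).any()):
        raise ValueError("scores outside [0, 1]")
    df = df.sort_values(["chrom", "pos", "alt"], kind="mergesort")
    df["score"] = df["score"].map(lambda s: f"{s:.6f}")
    df.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"score table missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# Mutation-rate model serialization (TSV)
# ---------------------------------------------------------------------------

RATE_COLUMNS = ["chrom", "context", "from", "to", "numerator", "denominator", "rate"]


def write_rate_table(rows: Iterable[dict], path: str | Path) -> None:
    df = pd.DataFrame(list(rows), columns=RATE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_rate_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


# ---------------------------------------------------------------------------
# Model artifact (JSON-like text)
# ---------------------------------------------------------------------------

def spec_checksum(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_model_json(artifact: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(artifact, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_model_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
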