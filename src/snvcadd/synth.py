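"""Synthetic fixtures with known ground truth.

Generates every input the pipeline consumes — reference FASTA, a two-row
alignment carrying a partially reconstructed ancestor, a population VCF with
configurable residual ancestral allele frequencies, single-transcript gene
models, conservation-like per-base tracks with a planted class signal, and
assorted interval tracks — so the full pipeline is testable without any
download, and estimators can be checked against the generating truth.

What the generator emulates: ancestor/reference divergence driven by
per-chromosome substitution rates with elevated CpG transitions; sparse
ancestral coverage; nearly-fixed derived alleles; a single informative
conservation-like track separating the classes with a configurable
standardized effect.  What it does not emulate: linkage, demography,
selection gradients, alignment error — so passing tests demonstrate the
machinery, not biological performance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import ceil, erf, sqrt
from pathlib import Path

import numpy as np
import pandas as pd

from .ancestral import AncestorMap
from .genes import GeneModel, GeneSet, write_gff3
from .io import (
    AlignmentBlock,
    AlignmentRow,
    GenomeSequence,
    IntervalTrack,
    PerBaseTrack,
    PopulationAF,
    write_bed_track,
    write_bedgraph,
    write_genome,
    write_maf,
)
from .annotate import (
    CHROMATIN_TRACKS,
    INDICATOR_TRACK_NAMES,
    PER_BASE_TRACK_NAMES,
)
from .training import (
    BASES,
    MutationRateModel,
    build_labeled_set,
    call_derived,
    estimate_rates,
    simulate_variants,
    trim_to_match,
)

STOP_CODONS = ("TAA", "TAG", "TGA")
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


def default_true_rates(transition: float = 0.012, transversion: float = 0.006,
                       cpg_factor: float = 10.0) -> dict[tuple[str, str, str], float]:
    """Per-pair substitution rates: uniform transition/transversion rates
    outside CpG context; CpG transitions (C->T, G->A) elevated by
    ``cpg_factor``.  CpG rates exist only for C/G source bases, because
    CpG-context positions carry C or G on the reference by definition."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    rates: dict[tuple[str, str, str], float] = {}
    for b1 in BASES:
        for b2 in BASES:
            if b1 == b2:
                continue
            r = transition if (b1, b2) in transitions else transversion
            rates[("nonCpG", b1, b2)] = r
            if b1 in ("C", "G"):
                boost = cpg_factor if (b1, b2) in transitions else 1.0
                rates[("CpG", b1, b2)] = r * boost
    return rates


@dataclass
class FixtureConfig:
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"2L": 60_000, "2R": 40_000}
    )
    gc_fraction: float = 0.5
    coverage: float = 0.6
    transition_rate: float = 0.012
    transversion_rate: float = 0.006
    cpg_factor: float = 10.0
    residual_af: float = 0.05       # ancestral allele AF at derived sites
    low_af_fraction: float = 0.1    # sites held at low_af_value (filtered out)
    low_af_value: float = 0.5
    af_threshold: float = 0.9
    n_genes: int = 20
    effect_size: float = 2.0        # planted class separation in the PhyloP track
    noise_sd: float = 1.0
    sim_overshoot: float = 1.2      # simulate this multiple of the derived count
    block_length: int = 250         # alignment block granularity

    def true_rates(self) -> dict[tuple[str, str, str], float]:
        return default_true_rates(
            self.transition_rate, self.transversion_rate, self.cpg_factor
        )


# ---------------------------------------------------------------------------
# Reference
# ---------------------------------------------------------------------------

def make_reference(chrom_lengths: dict[str, int], gc_fraction: float,
                   seed: int) -> GenomeSequence:
    """i.i.d. reference with P(G)+P(C) = gc_fraction, deterministic per seed."""
    if not 0 < gc_fraction < 1 and gc_fraction != 1.0:
        raise ValueError("gc_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    seqs = {}
    for chrom, n in chrom_lengths.items():
        if n <= 0:
            raise ValueError("chromosome length must be positive")
        draws = rng.choice(4, size=n, p=probs)
        seqs[chrom] = "".join(np.array(list("ACGT"))[draws])
    return GenomeSequence(seqs)


# ---------------------------------------------------------------------------
# Gene models (edits the reference so every model is a valid ORF)
# ---------------------------------------------------------------------------

def _write_bases(genome: GenomeSequence, chrom: str, start: int, seq: str) -> None:
    arr = genome.base_array(chrom)
    arr[start - 1 : start - 1 + len(seq)] = np.frombuffer(
        seq.encode("ascii"), dtype="S1"
    )


def make_gene_models(genome: GenomeSequence, n_genes: int, seed: int,
                     flank: int = 500) -> GeneSet:
    """Insert non-overlapping, single-transcript, sense-strand two-exon genes
    (valid start/stop, CDS divisible by 3, no internal stop) into the
    reference, keeping ``flank`` bp clear on either side."""
    rng = np.random.default_rng(seed)
    total = sum(genome.length(c) for c in genome.chrom_names)
    genes: list[GeneModel] = []
    gi = 0
    remaining = n_genes
    for k, chrom in enumerate(genome.chrom_names):
        share = (
            remaining if k == len(genome.chrom_names) - 1
            else int(round(n_genes * genome.length(chrom) / total))
        )
        share = min(share, remaining)
        cursor = flank + 1
        for _ in range(share):
            utr5 = int(rng.integers(20, 50))
            utr3 = int(rng.integers(20, 50))
            n_codons = int(rng.integers(30, 60))
            cds_len = 3 * n_codons
            intron = int(rng.integers(60, 120))
            cds1 = int(rng.integers(30, cds_len - 30))
            gene_len = utr5 + cds1 + intron + (cds_len - cds1) + utr3
            gap = int(rng.integers(2 * flank + 50, 2 * flank + 400))
            start = cursor + gap
            end = start + gene_len - 1
            if end + flank > genome.length(chrom):
                break
            codons = [
                _NONSTOP_CODONS[i]
                for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons - 1)
            ]
            codons[0] = "ATG"
            codons.append(STOP_CODONS[int(rng.integers(0, 3))])
            cds_seq = "".join(codons)
            assert len(cds_seq) == cds_len
            exon1 = (start, start + utr5 + cds1 - 1)
            cds1_iv = (start + utr5, start + utr5 + cds1 - 1)
            intron_start = cds1_iv[1] + 1
            cds2_iv = (intron_start + intron, intron_start + intron + (cds_len - cds1) - 1)
            exon2 = (cds2_iv[0], cds2_iv[1] + utr3)
            _write_bases(genome, chrom, cds1_iv[0], cds_seq[:cds1])
            _write_bases(genome, chrom, cds2_iv[0], cds_seq[cds1:])
            # canonical splice dinucleotides
            _write_bases(genome, chrom, intron_start, "GT")
            _write_bases(genome, chrom, cds2_iv[0] - 2, "AG")
            gi += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene{gi:03d}",
                    chrom=chrom,
                    strand="+",
                    start=start,
                    end=exon2[1],
                    exons=[exon1, exon2],
                    cds=[cds1_iv, cds2_iv],
                )
            )
            cursor = exon2[1]
        remaining -= share
    if not genes:
        raise ValueError("genome too short to place any gene model")
    return GeneSet(genes, flank=flank)


# ---------------------------------------------------------------------------
# Ancestor
# ---------------------------------------------------------------------------

def make_ancestor(
    proto: GenomeSequence,
    true_rates: dict[tuple[str, str, str], float],
    coverage: float,
    seed: int,
    block_length: int = 250,
) -> tuple[GenomeSequence, AncestorMap]:
    """Diverge an ancestral sequence into a present-day reference.

    The input ``proto`` genome plays the ancestor: every position mutates
    forward into the reference with probability r[anc -> alt | context],
    where CpG context is read on the ancestral sequence — exactly the process
    whose rates :func:`snvcadd.training.estimate_rates` recovers, so the
    recovered rates are per-site binomial around the configured truth.  The
    ancestor is then exposed only over randomly covered blocks (fraction
    ``coverage``), emulating sparse reconstruction.

    Returns the mutated reference genome and the (partially gapped) ancestor
    map aligned to it.
    """
    from .training import _cpg_mask_from_bytes

    rng = np.random.default_rng(seed)
    ref_seqs: dict[str, str] = {}
    anc = AncestorMap({c: proto.length(c) for c in proto.chrom_names})
    for chrom in proto.chrom_names:
        n = proto.length(chrom)
        anc_bases = proto.base_array(chrom).copy()
        cpg = _cpg_mask_from_bytes(anc_bases == b"C", anc_bases == b"G")
        ref_bases = anc_bases.copy()
        u = rng.random(n)
        for context, ctx_mask in (("CpG", cpg), ("nonCpG", ~cpg)):
            for b1 in BASES:
                idx = np.flatnonzero(ctx_mask & (anc_bases == b1.encode()))
                if idx.size == 0:
                    continue
                cum = 0.0
                done = np.zeros(idx.size, dtype=bool)
                for b2 in BASES:
                    if b2 == b1:
                        continue
                    r = true_rates.get((context, b1, b2), 0.0)
                    hit = (~done) & (u[idx] >= cum) & (u[idx] < cum + r)
                    ref_bases[idx[hit]] = b2.encode()
                    done |= hit
                    cum += r
        n_blocks = ceil(n / block_length)
        covered = np.repeat(rng.random(n_blocks) < coverage, block_length)[:n]
        arr = anc.base_array(chrom)
        arr[covered] = anc_bases[covered].view(np.uint8)
        ref_seqs[chrom] = ref_bases.tobytes().decode()
    return GenomeSequence(ref_seqs), anc


def ancestor_blocks(genome: GenomeSequence, anc: AncestorMap) -> list[AlignmentBlock]:
    """Two-row alignment blocks over every reconstructed run of the ancestor."""
    blocks: list[AlignmentBlock] = []
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        ref = genome.base_array(chrom)
        anc_arr = anc.base_array(chrom)
        covered = (anc_arr != 0).view(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate([[0], covered, [0]])))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            ref_text = ref[run_start:run_end].tobytes().decode()
            anc_text = anc_arr[run_start:run_end].tobytes().decode()
            blocks.append(
                AlignmentBlock(
                    rows=[
                        AlignmentRow(f"ref.{chrom}", int(run_start),
                                     run_end - run_start, "+", n, ref_text),
                        AlignmentRow(f"anc.{chrom}", int(run_start),
                                     run_end - run_start, "+", n, anc_text),
                    ]
                )
            )
    return blocks


# ---------------------------------------------------------------------------
# Population VCF
# ---------------------------------------------------------------------------

def make_population(
    genome: GenomeSequence,
    anc: AncestorMap,
    residual_af: float,
    low_af_fraction: float,
    low_af_value: float,
    seed: int,
) -> tuple[PopulationAF, list[tuple[str, int, str, str, float]], set]:
    """Population AFs at every ancestor/reference mismatch site: the ancestral
    allele segregates at ``residual_af``, except at a random
    ``low_af_fraction`` of sites where it stays at ``low_af_value`` (those
    sites fail the nearly-fixed filter; their identity is ground truth)."""
    rng = np.random.default_rng(seed)
    af = PopulationAF()
    vcf_rows = []
    low_sites = set()
    for chrom in genome.chrom_names:
        ref = genome.base_array(chrom).view(np.uint8)
        anc_arr = anc.base_array(chrom)
        mism = np.flatnonzero((anc_arr != 0) & (anc_arr != ref))
        for idx in mism:
            pos = int(idx) + 1
            freq = residual_af
            if rng.random() < low_af_fraction:
                freq = low_af_value
                low_sites.add((chrom, pos))
            alt = chr(anc_arr[idx])
            af.add(chrom, pos, alt, freq)
            vcf_rows.append((chrom, pos, chr(ref[idx]), alt, freq))
    return af, vcf_rows, low_sites


def write_vcf(
    rows: list[tuple[str, int, str, str, float]],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for chrom, n in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={n}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt, freq in sorted(rows):
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\tAF={freq:g}\n")


# ---------------------------------------------------------------------------
# Tracks
# ---------------------------------------------------------------------------

def make_tracks(
    genome: GenomeSequence,
    labeled: pd.DataFrame,
    effect_size: float,
    noise_sd: float,
    seed: int,
) -> tuple[dict[str, PerBaseTrack], dict[str, IntervalTrack], IntervalTrack]:
    """One informative conservation-like track (PhyloP: N(effect, sd²) at
    simulated-class positions, N(0, sd²) elsewhere) plus uninformative
    per-base tracks, interval tracks, chromatin-state tilings and a ReMap
    record set."""
    if effect_size < 0:
        raise ValueError("effect_size must be non-negative")
    rng = np.random.default_rng(seed)
    per_base: dict[str, PerBaseTrack] = {}

    phylop = PerBaseTrack("PhyloP")
    sim_positions = {
        (r.chrom, int(r.pos))
        for r in labeled[labeled["label"] == 0].itertuples(index=False)
    }
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        vals = rng.normal(0.0, noise_sd, size=n)
        for chrom_key, pos in sim_positions:
            if chrom_key == chrom:
                vals[pos - 1] += effect_size
        for i, v in enumerate(vals):
            phylop.add(chrom, i + 1, i + 1, float(v))
    per_base["PhyloP"] = phylop

    seg = 200
    for name in PER_BASE_TRACK_NAMES:
        if name == "PhyloP":
            continue
        track = PerBaseTrack(name)
        for chrom in genome.chrom_names:
            n = genome.length(chrom)
            start = 1
            while start <= n:
                end = min(start + seg - 1, n)
                track.add(chrom, start, end, float(rng.normal(0.0, 1.0)))
                start = end + 1
        per_base[name] = track

    intervals: dict[str, IntervalTrack] = {}
    counts = {"miRNA": 5, "TFBS": 40, "CRM": 20, "pCRM": 20}
    for name in INDICATOR_TRACK_NAMES:
        track = IntervalTrack(name)
        n_iv = counts.get(name, 30)
        for chrom in genome.chrom_names:
            n = genome.length(chrom)
            for _ in range(max(1, int(n_iv * n / 100_000))):
                length = int(rng.integers(50, 500))
                s = int(rng.integers(1, max(2, n - length)))
                track.add(chrom, s, s + length - 1)
        intervals[name] = track
    for name in CHROMATIN_TRACKS:
        track = IntervalTrack(name)
        for chrom in genome.chrom_names:
            n = genome.length(chrom)
            start = 1
            while start <= n:
                end = min(start + int(rng.integers(1000, 3000)), n)
                track.add(chrom, start, end, str(int(rng.integers(1, 10))))
                start = end + 1
        intervals[name] = track

    remap = IntervalTrack("ReMap")
    for chrom in genome.chrom_names:
        n = genome.length(chrom)
        for _ in range(max(1, int(200 * n / 100_000))):
            length = int(rng.integers(100, 1000))
            s = int(rng.integers(1, max(2, n - length)))
            remap.add(chrom, s, s + length - 1)
    return per_base, intervals, remap


# ---------------------------------------------------------------------------
# Full fixture
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    config: FixtureConfig
    seed: int
    genome: GenomeSequence
    genes: GeneSet
    ancestor: AncestorMap
    maf_blocks: list[AlignmentBlock]
    population: PopulationAF
    vcf_rows: list
    low_af_sites: set
    derived: pd.DataFrame
    simulated: pd.DataFrame
    labeled: pd.DataFrame
    rates_true: MutationRateModel
    rates_estimated: MutationRateModel
    per_base_tracks: dict[str, PerBaseTrack]
    interval_tracks: dict[str, IntervalTrack]
    remap: IntervalTrack

    @property
    def truth(self) -> dict:
        cfg = self.config
        return {
            "seed": self.seed,
            "rates": {f"{c}:{a}>{b}": r for (c, a, b), r in cfg.true_rates().items()},
            "effect_size": cfg.effect_size,
            "noise_sd": cfg.noise_sd,
            "closed_form_auc": closed_form_auc(cfg.effect_size, cfg.noise_sd),
            "n_derived": int(len(self.derived)),
            "n_simulated": int(len(self.simulated)),
            "n_low_af_sites": len(self.low_af_sites),
            "config": {
                k: v for k, v in asdict(cfg).items() if not isinstance(v, dict)
            },
            "chrom_lengths": cfg.chrom_lengths,
        }


def closed_form_auc(effect_size: float, noise_sd: float) -> float:
    """AUC of the optimal classifier on one Gaussian feature: Φ(δ/(σ√2))."""
    return 0.5 * (1.0 + erf(effect_size / (noise_sd * sqrt(2.0) * sqrt(2.0))))


def make_full_fixture(
    config: FixtureConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> FixtureBundle:
    """Generate a complete, internally consistent input bundle.

    All randomness flows from ``seed`` through deterministic per-step
    sub-seeds, so regeneration is byte-identical.
    """
    config = config or FixtureConfig()
    master = np.random.default_rng(seed)
    sub = {name: int(s) for name, s in zip(
        ("reference", "genes", "ancestor", "population", "simulate", "trim", "tracks"),
        master.integers(0, 2**31 - 1, size=7),
    )}
    proto = make_reference(config.chrom_lengths, config.gc_fraction, sub["reference"])
    true_rates = config.true_rates()
    genome, anc = make_ancestor(
        proto, true_rates, config.coverage, sub["ancestor"], config.block_length
    )
    genes = make_gene_models(genome, config.n_genes, sub["genes"])
    # gene models are written into the reference after divergence, so the
    # edited spans no longer follow the substitution process: blank them from
    # the ancestor to keep derived calls and rate estimates truthful
    for gene in genes:
        anc.clear_range(gene.chrom, gene.start - 2, gene.end + 2)
    blocks = ancestor_blocks(genome, anc)
    population, vcf_rows, low_sites = make_population(
        genome, anc, config.residual_af, config.low_af_fraction,
        config.low_af_value, sub["population"],
    )
    derived = call_derived(genome, anc, population, config.af_threshold)
    rates_est = estimate_rates(genome, anc)
    simulated_raw = simulate_variants(
        genome, anc, rates_est,
        n_target=ceil(config.sim_overshoot * len(derived)),
        seed=sub["simulate"], exclusions=derived,
    )
    simulated = trim_to_match(simulated_raw, len(derived), sub["trim"])
    labeled = build_labeled_set(derived, simulated)
    per_base, intervals, remap = make_tracks(
        genome, labeled, config.effect_size, config.noise_sd, sub["tracks"]
    )
    rates_true = MutationRateModel.from_rates(genome.chrom_names, true_rates)
    bundle = FixtureBundle(
        config=config, seed=seed, genome=genome, genes=genes, ancestor=anc,
        maf_blocks=blocks, population=population, vcf_rows=vcf_rows,
        low_af_sites=low_sites, derived=derived, simulated=simulated,
        labeled=labeled, rates_true=rates_true, rates_estimated=rates_est,
        per_base_tracks=per_base, interval_tracks=intervals, remap=remap,
    )
    if out_dir is not None:
        write_fixture(bundle, out_dir)
    return bundle


def write_fixture(bundle: FixtureBundle, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_genome(bundle.genome, out / "reference.fa")
    write_maf(bundle.maf_blocks, out / "alignment.maf")
    write_vcf(bundle.vcf_rows, bundle.config.chrom_lengths, out / "population.vcf")
    write_gff3(bundle.genes, out / "genes.gff3")
    tracks_dir = out / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for name, track in sorted(bundle.per_base_tracks.items()):
        write_bedgraph(track, tracks_dir / f"{name}.bedgraph")
    for name, track in sorted(bundle.interval_tracks.items()):
        write_bed_track(track, tracks_dir / f"{name}.bed")
    write_bed_track(bundle.remap, tracks_dir / "ReMap.bed")
    bundle.labeled.to_csv(out / "labeled_variants.tsv", sep="\t", index=False)
    bundle.rates_estimated.to_table().to_csv(
        out / "estimated_rates.tsv", sep="\t", index=False
    )
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
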