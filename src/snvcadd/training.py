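"""Construction of the two training classes.

Proxy-benign class: *derived* variants — positions where the reference genome
carries an allele differing from the reconstructed ancestor, and the derived
(reference) allele is fixed or nearly fixed in present-day populations, so
purifying selection has had the chance to remove deleterious ones.

Proxy-impactful class: *simulated* de novo variants drawn from per-chromosome
substitution rates (CpG context modeled separately), never exposed to
selection, hence enriched for impactful alleles.

Variant sets are pandas DataFrames with columns (chrom, pos, ref, alt);
positions are 1-based.  The derived record stores the reference (derived)
allele as ``ref`` and the ancestral allele as ``alt``, so both classes are
annotated as substitutions on the reference genome.
"""

from __future__ import annotations

from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .ancestral import AncestorMap
from .io import GenomeSequence, RATE_COLUMNS

BASES = ("A", "C", "G", "T")
_BASE_BYTES = {b: ord(b) for b in BASES}
CONTEXTS = ("CpG", "nonCpG")

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt"]


class Variant(NamedTuple):
    chrom: str
    pos: int
    ref: str
    alt: str


def variants_frame(records: Iterable | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records[VARIANT_COLUMNS].copy() if len(records) else pd.DataFrame(
            columns=VARIANT_COLUMNS
        )
    return pd.DataFrame(list(records), columns=VARIANT_COLUMNS)


def _cpg_mask_from_bytes(is_c: np.ndarray, is_g: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(is_c), dtype=bool)
    if len(is_c) > 1:
        cg = is_c[:-1] & is_g[1:]
        mask[:-1] |= cg        # the C
        mask[1:] |= cg         # the G
    return mask


def cpg_context_mask(genome: GenomeSequence, chrom: str) -> np.ndarray:
    """Boolean mask (0-based index = pos-1): position is the C of a "CG"
    dinucleotide or the G of one, read on the reference sense strand.

    This is the context used when *simulating* new mutations of the
    reference genome."""
    arr = genome.base_array(chrom)
    return _cpg_mask_from_bytes(arr == b"C", arr == b"G")


def ancestral_cpg_context_mask(anc: AncestorMap, chrom: str) -> np.ndarray:
    """CpG context read on the ancestral sequence: the sequence in which the
    ancestor->reference substitutions originated.  Positions whose relevant
    neighbor is unreconstructed are conservatively non-CpG.

    This is the context used when *estimating* substitution rates from the
    ancestor/reference contrast (an ancestral CpG deamination leaves "TG" on
    the reference, so reference context cannot see the elevation)."""
    arr = anc.base_array(chrom)
    return _cpg_mask_from_bytes(arr == ord("C"), arr == ord("G"))


class MutationRateModel:
    """Per-chromosome substitution rates for the 12 ordered base pairs,
    estimated separately for CpG and non-CpG context positions."""

    def __init__(self) -> None:
        # chrom -> (context, from, to) -> (numerator, denominator)
        self._counts: dict[str, dict[tuple[str, str, str], tuple[int, int]]] = {}

    def set_counts(self, chrom: str, context: str, b1: str, b2: str,
                   numerator: int, denominator: int) -> None:
        self._counts.setdefault(chrom, {})[(context, b1, b2)] = (
            int(numerator), int(denominator)
        )

    def counts(self, chrom: str, context: str, b1: str, b2: str) -> tuple[int, int]:
        return self._counts.get(chrom, {}).get((context, b1, b2), (0, 0))

    def rate(self, chrom: str, context: str, b1: str, b2: str) -> float | None:
        num, den = self.counts(chrom, context, b1, b2)
        return None if den == 0 else num / den

    def chroms(self) -> list[str]:
        return sorted(self._counts)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for chrom in self.chroms():
            for (context, b1, b2), (num, den) in sorted(self._counts[chrom].items()):
                rows.append(
                    dict(chrom=chrom, context=context, **{"from": b1, "to": b2},
                         numerator=num, denominator=den,
                         rate=(num / den if den else np.nan))
                )
        return pd.DataFrame(rows, columns=RATE_COLUMNS)

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "MutationRateModel":
        model = cls()
        for _, row in table.iterrows():
            model.set_counts(str(row["chrom"]), row["context"], row["from"],
                             row["to"], int(row["numerator"]),
                             int(row["denominator"]))
        return model

    @classmethod
    def from_rates(cls, chroms: Iterable[str],
                   rates: dict[tuple[str, str, str], float],
                   denominator: int = 10**9) -> "MutationRateModel":
        """Build a model from exact rates (used for fixture ground truth)."""
        model = cls()
        for chrom in chroms:
            for (context, b1, b2), r in rates.items():
                if not 0 <= r <= 1:
                    raise ValueError(f"rate {r} outside [0, 1]")
                model.set_counts(chrom, context, b1, b2,
                                 int(round(r * denominator)), denominator)
        return model


def _aligned_masks(genome: GenomeSequence, anc: AncestorMap, chrom: str):
    ref = genome.base_array(chrom).view(np.uint8)
    anc_arr = anc.base_array(chrom)
    valid_ref = np.isin(ref, [ord(b) for b in BASES])
    aligned = (anc_arr != 0) & valid_ref
    return ref, anc_arr, aligned


def call_derived(
    genome: GenomeSequence,
    anc: AncestorMap,
    af: "PopulationAF | None",
    af_threshold: float = 0.9,
) -> pd.DataFrame:
    """Identify derived variants passing the allele-frequency filter.

    A site qualifies when ancestor and reference bases are both defined and
    differ; the derived (reference) allele's population frequency — one minus
    the summed alt frequencies at the site, or 1.0 for sites with no
    population record — must be at least ``af_threshold``.
    """
    if not 0 < af_threshold <= 1:
        raise ValueError(f"af_threshold {af_threshold} outside (0, 1]")
    records = []
    for chrom in genome.chrom_names:
        if chrom not in anc.chrom_names:
            continue
        ref, anc_arr, aligned = _aligned_masks(genome, anc, chrom)
        diff = aligned & (anc_arr != ref)
        for idx in np.flatnonzero(diff):
            pos = int(idx) + 1
            derived_freq = 1.0
            if af is not None:
                total_alt = af.total_alt_freq(chrom, pos)
                if total_alt is not None:
                    derived_freq = 1.0 - total_alt
            if derived_freq >= af_threshold:
                records.append((chrom, pos, chr(ref[idx]), chr(anc_arr[idx])))
    return pd.DataFrame(records, columns=VARIANT_COLUMNS)


def estimate_rates(genome: GenomeSequence, anc: AncestorMap) -> MutationRateModel:
    """Per-chromosome substitution rates from the ancestor/reference contrast.

    r[b1 -> b2 | context] = #(ancestral b1, reference b2, context)
                          / #(ancestral b1, context),
    with CpG context read off the ancestral sense strand (the sequence the
    substitutions originated in).  CpG-context rates therefore exist only for
    ancestral C and G.
    """
    model = MutationRateModel()
    for chrom in genome.chrom_names:
        if chrom not in anc.chrom_names:
            continue
        ref, anc_arr, aligned = _aligned_masks(genome, anc, chrom)
        if not aligned.any():
            raise ValueError(f"ancestor coverage is zero on {chrom}")
        cpg = ancestral_cpg_context_mask(anc, chrom)
        for context, ctx_mask in (("CpG", cpg), ("nonCpG", ~cpg)):
            sel = aligned & ctx_mask
            for b1 in BASES:
                from_mask = sel & (anc_arr == _BASE_BYTES[b1])
                den = int(from_mask.sum())
                for b2 in BASES:
                    if b1 == b2:
                        continue
                    num = int((from_mask & (ref == _BASE_BYTES[b2])).sum())
                    model.set_counts(chrom, context, b1, b2, num, den)
    return model


def simulate_variants(
    genome: GenomeSequence,
    anc: AncestorMap,
    rates: MutationRateModel,
    n_target: int,
    seed: int,
    exclusions: pd.DataFrame | Iterable | None = None,
    mutate_from: str = "reference",
) -> pd.DataFrame:
    """Draw de novo variants with probability proportional to the substitution
    rate of (mutating base -> alt) in the position's CpG context.

    Only positions with a reconstructed ancestral base are eligible; draws are
    distinct (chrom, pos, alt) pairs without replacement; excluded pairs are
    never emitted; deterministic for a given seed.
    """
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if mutate_from not in ("reference", "ancestor"):
        raise ValueError("mutate_from must be 'reference' or 'ancestor'")
    excl: set[tuple[str, int, str]] = set()
    if exclusions is not None:
        for rec in variants_frame(exclusions).itertuples(index=False):
            excl.add((rec.chrom, int(rec.pos), rec.alt))

    chrom_list, pos_list, ref_list, alt_list, weight_list = [], [], [], [], []
    for chrom in genome.chrom_names:
        if chrom not in anc.chrom_names:
            continue
        ref, anc_arr, aligned = _aligned_masks(genome, anc, chrom)
        source = ref if mutate_from == "reference" else anc_arr
        cpg = cpg_context_mask(genome, chrom)
        idx_all = np.flatnonzero(aligned)
        if idx_all.size == 0:
            continue
        for context, ctx_mask in (("CpG", cpg), ("nonCpG", ~cpg)):
            for b1 in BASES:
                sel = idx_all[
                    ctx_mask[idx_all] & (source[idx_all] == _BASE_BYTES[b1])
                ]
                if sel.size == 0:
                    continue
                for b2 in BASES:
                    if b2 == b1:
                        continue
                    r = rates.rate(chrom, context, b1, b2)
                    if r is None:
                        raise ValueError(
                            f"rate {b1}->{b2} ({context}) undefined on {chrom}: "
                            "zero denominator; simulation refuses to use it"
                        )
                    if r <= 0:
                        continue
                    keep = sel[ref[sel] != _BASE_BYTES[b2]]  # alt never equals ref
                    if keep.size == 0:
                        continue
                    chrom_list.append(np.full(keep.size, chrom, dtype=object))
                    pos_list.append(keep + 1)
                    ref_list.append(ref[keep])
                    alt_list.append(np.full(keep.size, b2, dtype=object))
                    weight_list.append(np.full(keep.size, r))

    if not pos_list:
        raise ValueError("no admissible (pos, alt) pairs")
    chroms = np.concatenate(chrom_list)
    positions = np.concatenate(pos_list)
    refs = np.concatenate(ref_list)
    alts = np.concatenate(alt_list)
    weights = np.concatenate(weight_list)

    if excl:
        mask = np.array(
            [
                (c, int(p), a) not in excl
                for c, p, a in zip(chroms, positions, alts)
            ]
        )
        chroms, positions, refs, alts, weights = (
            chroms[mask], positions[mask], refs[mask], alts[mask], weights[mask]
        )
    if n_target > len(positions):
        raise ValueError(
            f"n_target {n_target} exceeds {len(positions)} admissible (pos, alt) pairs"
        )

    # Weighted sampling without replacement via Gumbel top-k (Plackett-Luce
    # equivalent to successive draws), deterministic per seed.
    rng = np.random.default_rng(seed)
    # stable ordering of candidates before drawing so results do not depend on
    # assembly order
    order = np.lexsort((alts, positions, chroms))
    chroms, positions, refs, alts, weights = (
        chroms[order], positions[order], refs[order], alts[order], weights[order]
    )
    gumbel = rng.gumbel(size=len(weights))
    keys = np.log(weights) + gumbel
    top = np.argpartition(-keys, n_target - 1)[:n_target]

    out = pd.DataFrame(
        {
            "chrom": chroms[top],
            "pos": positions[top].astype(int),
            "ref": [chr(b) for b in refs[top]],
            "alt": alts[top],
        }
    )
    return out.sort_values(["chrom", "pos", "alt"], kind="mergesort").reset_index(drop=True)


def trim_to_match(simulated: pd.DataFrame, n_derived: int, seed: int) -> pd.DataFrame:
    """Uniform random subset of the simulated set matching the derived count."""
    simulated = variants_frame(simulated)
    if len(simulated) < n_derived:
        raise ValueError(
            f"only {len(simulated)} simulated variants for {n_derived} derived; "
            "increase the simulation n_target"
        )
    rng = np.random.default_rng(seed)
    keep = rng.choice(len(simulated), size=n_derived, replace=False)
    out = simulated.iloc[np.sort(keep)].reset_index(drop=True)
    return out


def build_labeled_set(derived: pd.DataFrame, simulated: pd.DataFrame) -> pd.DataFrame:
    """Merge the classes: derived labeled 1, simulated labeled 0.

    The classes must be disjoint on (chrom, pos, alt); duplicates within a
    class are rejected too.
    """
    derived = variants_frame(derived).assign(label=1)
    simulated = variants_frame(simulated).assign(label=0)
    for name, df in (("derived", derived), ("simulated", simulated)):
        dup = df.duplicated(subset=["chrom", "pos", "alt"])
        if dup.any():
            raise ValueError(f"duplicate (chrom, pos, alt) records in {name} set")
    key_d = set(map(tuple, derived[["chrom", "pos", "alt"]].itertuples(index=False)))
    key_s = set(map(tuple, simulated[["chrom", "pos", "alt"]].itertuples(index=False)))
    overlap = key_d & key_s
    if overlap:
        raise ValueError(
            f"{len(overlap)} records in both classes, e.g. {sorted(overlap)[:5]}"
        )
    out = pd.concat([derived, simulated], ignore_index=True)
    return out


def per_chromosome_counts(labeled: pd.DataFrame) -> pd.DataFrame:
    """Class counts per chromosome (the shape of a training-set summary table)."""
    table = (
        labeled.groupby(["chrom", "label"]).size().unstack(fill_value=0)
        .rename(columns={1: "derived", 0: "simulated"})
    )
    for col in ("derived", "simulated"):
        if col not in table:
            table[col] = 0
    return table[["derived", "simulated"]]
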