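"""Impact scoring: annotate -> expand -> scale -> predict, for arbitrary
variants or for every possible SNV over a region.

The impact score of a variant is the trained classifier's probability that it
belongs to the simulated (selection-free) class: scores near 0 look like
nearly-fixed derived variants (neutral-like), scores near 1 like de novo
mutations never exposed to purifying selection (impact-like).
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
import pandas as pd

from .annotate import VariantAnnotator
from .features import FeatureExpander, FeatureSpec, SdScaler, default_feature_spec
from .io import GenomeSequence, write_scores
from .model import TrainedModel

BASES = np.frombuffer(b"ACGT", dtype="S1")

CHUNK_SIZE = 10_000


def score_variants(
    model: TrainedModel,
    scaler: SdScaler,
    annotator: VariantAnnotator,
    variants: pd.DataFrame,
    spec: FeatureSpec | None = None,
) -> pd.DataFrame:
    """Score variants; returns (chrom, pos, ref, alt, score) in input order.

    Variants whose ref allele disagrees with the genome get a NaN score and an
    ``error`` note; the rest proceed.
    """
    spec = spec or default_feature_spec()
    if model.spec_checksum is not None and model.spec_checksum != spec.checksum():
        raise ValueError("feature spec checksum does not match the trained model")
    variants = variants.reset_index(drop=True)
    ok = np.ones(len(variants), dtype=bool)
    for i, var in enumerate(variants.itertuples(index=False)):
        if annotator.genome.sequence(var.chrom, int(var.pos)) != var.ref:
            ok[i] = False
    scores = np.full(len(variants), np.nan)
    if ok.any():
        sub = variants.loc[ok]
        annotated = annotator.annotate(sub)
        matrix = FeatureExpander(spec).fit(annotated).transform(annotated)
        scaled = scaler.transform(matrix)
        proba = model.predict_proba(scaled)
        # orientation: derived = 1, impact score = P(simulated) = 1 - P(y=1)
        scores[ok] = proba["P_simulated"].to_numpy()
    out = variants[["chrom", "pos", "ref", "alt"]].copy()
    out["score"] = scores
    out["error"] = np.where(ok, "", "ref mismatch")
    return out


def enumerate_all_snvs(
    genome: GenomeSequence,
    chrom: str,
    start: int | None = None,
    end: int | None = None,
) -> Iterator[pd.DataFrame]:
    """Yield chunks of all possible SNVs over [start, end] (1-based,
    inclusive), ordered by (pos, alt); ref=N positions are skipped."""
    start = 1 if start is None else start
    end = genome.length(chrom) if end is None else end
    if start < 1 or end > genome.length(chrom):
        raise IndexError(f"region [{start}, {end}] outside {chrom}")
    for chunk_start in range(start, end + 1, CHUNK_SIZE):
        chunk_end = min(chunk_start + CHUNK_SIZE - 1, end)
        positions = np.arange(chunk_start, chunk_end + 1)
        refs = genome.bases_at(chrom, positions)
        valid = np.isin(refs, BASES)
        positions, refs = positions[valid], refs[valid]
        if positions.size == 0:
            continue
        pos3 = np.repeat(positions, 3)
        ref3 = np.repeat(refs, 3)
        alt3 = np.empty(pos3.shape, dtype="S1")
        for base in BASES:
            alts = BASES[BASES != base]
            mask = ref3 == base
            # positions come in consecutive triples; fill each triple
            alt3[mask] = np.tile(alts, mask.sum() // 3)
        yield pd.DataFrame(
            {
                "chrom": chrom,
                "pos": pos3.astype(int),
                "ref": ref3.astype("U1"),
                "alt": alt3.astype("U1"),
            }
        )


def count_skipped_n(genome: GenomeSequence, chrom: str,
                    start: int | None = None, end: int | None = None) -> int:
    start = 1 if start is None else start
    end = genome.length(chrom) if end is None else end
    refs = genome.bases_at(chrom, np.arange(start, end + 1))
    return int((~np.isin(refs, BASES)).sum())


def precompute_scores(
    model: TrainedModel,
    scaler: SdScaler,
    annotator: VariantAnnotator,
    chrom: str,
    out_path,
    start: int | None = None,
    end: int | None = None,
    spec: FeatureSpec | None = None,
) -> int:
    """Stream-score all possible SNVs over a region into a score TSV.

    Chunks keep memory constant in region length; returns the record count.
    """
    frames = []
    n = 0
    for chunk in enumerate_all_snvs(annotator.genome, chrom, start, end):
        scored = score_variants(model, scaler, annotator, chunk, spec)
        frames.append(scored[["chrom", "pos", "ref", "alt", "score"]])
        n += len(scored)
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "score"])
    )
    write_scores(table, out_path)
    return n


def score_histogram(scores: np.ndarray, bin_width: float = 0.1) -> pd.DataFrame:
    """Counts of scores in [0, 0.1), [0.1, 0.2), ..., [0.9, 1.0]."""
    edges = np.round(np.arange(0.0, 1.0 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(np.asarray(scores), bins=edges)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
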