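"""Downstream statistics over score tables: codon-position contrasts,
allele-frequency bins, threshold fractions, gene windows and candidate
re-ranking."""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np
import pandas as pd
from scipy import stats

from .genes import GeneSet
from .io import GenomeSequence


# ---------------------------------------------------------------------------
# Mann-Whitney U (exact enumeration for small groups, normal approximation
# with tie and continuity correction otherwise)
# ---------------------------------------------------------------------------

def mann_whitney_u(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U statistic of the first sample, two-sided p-value).  Tied
    observations contribute ½ to U.  For groups of at most ``exact_max_n``
    observations each, the p-value is computed by exhaustive enumeration of
    all label assignments; otherwise by the normal approximation with tie
    correction and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    if n1 <= exact_max_n and n2 <= exact_max_n:
        # exhaustive enumeration over all C(n1+n2, n1) assignments
        n = n1 + n2
        dev = abs(u1 - mu)
        hits = total = 0
        for idx in _combinations(range(n), n1):
            u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return float(u1), hits / total

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return float(u1), 1.0
    z = (abs(u1 - mu) - 0.5) / np.sqrt(sigma2)
    p = 2.0 * stats.norm.sf(max(z, 0.0))
    return float(u1), float(min(p, 1.0))


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


# ---------------------------------------------------------------------------
# Codon-position analysis
# ---------------------------------------------------------------------------

def codon_min_scores(scores: pd.DataFrame, genes: GeneSet) -> pd.DataFrame:
    """Minimum score over the three alts at every coding position.

    Restricted to single-transcript, sense-strand gene models.  Positions
    with fewer than three scored alts are excluded (their count is recorded
    in ``DataFrame.attrs['n_incomplete']``).  Returns columns (gene, codon,
    codon_pos, pos, min_score) with codon_pos in {1, 2, 3}.
    """
    eligible = genes.single_transcript_sense()
    by_site = scores.groupby(["chrom", "pos"])["score"]
    counts = by_site.count()
    minima = by_site.min()
    rows = []
    n_incomplete = 0
    for gene in eligible:
        positions = gene.cds_positions()
        for i, pos in enumerate(positions):
            key = (gene.chrom, int(pos))
            if key not in minima.index:
                n_incomplete += 1
                continue
            if counts.loc[key] < 3:
                n_incomplete += 1
                continue
            rows.append(
                (gene.gene_id, i // 3 + 1, i % 3 + 1, int(pos), float(minima.loc[key]))
            )
    out = pd.DataFrame(rows, columns=["gene", "codon", "codon_pos", "pos", "min_score"])
    out.attrs["n_incomplete"] = n_incomplete
    return out


@dataclass
class CodonPositionResult:
    scope: str
    pairwise: pd.DataFrame                   # pair, U, p_raw, p_corrected
    bonferroni_factor: int
    per_gene: pd.DataFrame | None = None     # gene, pair, U, p_raw, p_corrected
    fraction_significant: dict[str, float] = field(default_factory=dict)


_PAIRS = [(1, 2), (1, 3), (2, 3)]


def compare_codon_positions(
    minima: pd.DataFrame, scope: str = "genome", alpha: float = 0.05
) -> CodonPositionResult:
    """Pairwise Mann-Whitney tests between codon positions.

    ``genome`` scope pools all transcripts (Bonferroni factor 3);
    ``per-gene`` scope tests within each gene (factor 3 x number of genes)
    and reports the fraction of genes significant per pair.
    """
    if scope not in ("genome", "per-gene"):
        raise ValueError("scope must be 'genome' or 'per-gene'")

    def _pair_tests(df: pd.DataFrame, factor: int) -> list[dict]:
        rows = []
        for a, b in _PAIRS:
            ga = df.loc[df["codon_pos"] == a, "min_score"].to_numpy()
            gb = df.loc[df["codon_pos"] == b, "min_score"].to_numpy()
            if len(ga) < 2 or len(gb) < 2:
                continue  # empty/degenerate group: pair skipped
            u, p = mann_whitney_u(ga, gb)
            rows.append(
                {"pair": f"pos{a}_vs_pos{b}", "U": u, "p_raw": p,
                 "p_corrected": bonferroni(p, factor),
                 "median_a": float(np.median(ga)), "median_b": float(np.median(gb))}
            )
        return rows

    if scope == "genome":
        factor = len(_PAIRS)
        pairwise = pd.DataFrame(_pair_tests(minima, factor))
        return CodonPositionResult(scope, pairwise, factor)

    genes = sorted(minima["gene"].unique())
    factor = len(_PAIRS) * len(genes)
    per_gene_rows = []
    for gene in genes:
        for row in _pair_tests(minima[minima["gene"] == gene], factor):
            per_gene_rows.append({"gene": gene, **row})
    per_gene = pd.DataFrame(per_gene_rows)
    frac = {}
    if len(per_gene):
        for pair, grp in per_gene.groupby("pair"):
            frac[str(pair)] = float((grp["p_corrected"] < alpha).mean())
    pooled = pd.DataFrame(_pair_tests(minima, len(_PAIRS)))
    return CodonPositionResult(scope, pooled, factor, per_gene, frac)


# ---------------------------------------------------------------------------
# Allele-frequency bins
# ---------------------------------------------------------------------------

@dataclass
class AFBinSummary:
    bins: pd.DataFrame          # bin_left, bin_right, count, mean, q25, q50, q75
    overall_mean: float
    rare_mean: float            # AF < rare_cut
    common_mean: float          # AF >= rare_cut
    n_rejected: int


def af_bin_summary(
    records: pd.DataFrame, bin_width: float = 0.025, rare_cut: float = 0.05
) -> AFBinSummary:
    """Score distribution across non-reference allele-frequency bins.

    Bins are left-open right-closed, the first being (0, bin_width].  Records
    with AF outside (0, 1] are rejected and counted.
    """
    df = records[["score", "af"]].copy()
    bad = (df["af"] <= 0) | (df["af"] > 1)
    n_rejected = int(bad.sum())
    df = df[~bad]
    n_bins = int(round(1.0 / bin_width))
    edges = np.round(np.linspace(0.0, 1.0, n_bins + 1), 12)
    idx = np.clip(np.ceil(df["af"].to_numpy() / bin_width).astype(int) - 1, 0, n_bins - 1)
    df = df.assign(bin=idx)
    rows = []
    for b in range(n_bins):
        sub = df.loc[df["bin"] == b, "score"]
        rows.append(
            {
                "bin_left": edges[b],
                "bin_right": edges[b + 1],
                "count": int(len(sub)),
                "mean": float(sub.mean()) if len(sub) else np.nan,
                "q25": float(sub.quantile(0.25)) if len(sub) else np.nan,
                "q50": float(sub.quantile(0.50)) if len(sub) else np.nan,
                "q75": float(sub.quantile(0.75)) if len(sub) else np.nan,
            }
        )
    bins = pd.DataFrame(rows)
    rare = df.loc[df["af"] < rare_cut, "score"]
    common = df.loc[df["af"] >= rare_cut, "score"]
    return AFBinSummary(
        bins=bins,
        overall_mean=float(df["score"].mean()) if len(df) else np.nan,
        rare_mean=float(rare.mean()) if len(rare) else np.nan,
        common_mean=float(common.mean()) if len(common) else np.nan,
        n_rejected=n_rejected,
    )


# ---------------------------------------------------------------------------
# Threshold fractions
# ---------------------------------------------------------------------------

def fraction_above(
    scores, thresholds: dict[float, str] | None = None
) -> dict[float, float]:
    """Fraction of scores beyond each threshold.

    Comparator semantics follow the reporting convention: strict ``>`` at 0.6
    ("above 0.6"), inclusive ``>=`` at 0.8 ("0.8 and higher").  Custom
    thresholds map value -> comparator ('gt' or 'ge').
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score set")
    if thresholds is None:
        thresholds = {0.6: "gt", 0.8: "ge"}
    out = {}
    for t, cmp in thresholds.items():
        if cmp == "gt":
            out[t] = float((arr > t).mean())
        elif cmp == "ge":
            out[t] = float((arr >= t).mean())
        else:
            raise ValueError(f"unknown comparator {cmp!r}")
    return out


# ---------------------------------------------------------------------------
# Gene windows
# ---------------------------------------------------------------------------

def gene_window_means(
    scores: pd.DataFrame,
    gene,
    genome: GenomeSequence | None = None,
    flank: int = 500,
    observed_variants: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean score over the three alts per position across the gene window
    [start - flank, end + flank] (clipped at chromosome bounds)."""
    start = gene.start - flank
    end = gene.end + flank
    if start < 1:
        import warnings

        warnings.warn(f"window start clipped at 1 for {gene.gene_id}")
        start = 1
    if genome is not None and end > genome.length(gene.chrom):
        import warnings

        warnings.warn(f"window end clipped for {gene.gene_id}")
        end = genome.length(gene.chrom)
    window = scores[
        (scores["chrom"] == gene.chrom)
        & (scores["pos"] >= start)
        & (scores["pos"] <= end)
    ]
    out = (
        window.groupby("pos")["score"]
        .agg(mean_score="mean", n_alts="count")
        .reset_index()
    )
    out["in_exon"] = out["pos"].map(
        lambda p: any(s <= p <= e for s, e in gene.exons)
    )
    if observed_variants is not None:
        observed = set(
            observed_variants.loc[
                observed_variants["chrom"] == gene.chrom, "pos"
            ].astype(int)
        )
        out["observed_variant"] = out["pos"].isin(observed)
    return out


# ---------------------------------------------------------------------------
# Candidate re-ranking
# ---------------------------------------------------------------------------

def rank_candidates(candidates: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Join candidates (chrom, pos, ref, alt[, p_value]) with impact scores
    and rank by score (descending), p-value ascending as tiebreak.

    Unscoreable candidates are returned with rank NaN and flagged.  The
    result carries the Spearman correlation between the two rankings in
    ``DataFrame.attrs['spearman']`` when p-values are present.
    """
    merged = candidates.merge(
        scores[["chrom", "pos", "ref", "alt", "score"]],
        on=["chrom", "pos", "ref", "alt"],
        how="left",
    )
    merged["scoreable"] = merged["score"].notna()
    has_p = "p_value" in merged.columns
    sort_cols = ["score"] + (["p_value"] if has_p else [])
    ascending = [False] + ([True] if has_p else [])
    scored = merged[merged["scoreable"]].sort_values(
        sort_cols, ascending=ascending, kind="mergesort"
    )
    scored = scored.assign(rank_by_score=np.arange(1, len(scored) + 1))
    rho = np.nan
    if has_p:
        scored["rank_by_p"] = scored["p_value"].rank(method="average")
        if len(scored) > 1 and scored["score"].nunique() > 1:
            rho = stats.spearmanr(scored["score"], -scored["p_value"]).statistic
    unscored = merged[~merged["scoreable"]]
    out = pd.concat([scored, unscored], ignore_index=True)
    if has_p and len(scored) > 1:
        out.attrs["spearman"] = float(rho)
    return out
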