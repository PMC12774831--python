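import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from snvcadd.analyses import (
    af_bin_summary,
    codon_min_scores,
    compare_codon_positions,
    fraction_above,
    gene_window_means,
    mann_whitney_u,
    rank_candidates,
)
from snvcadd.genes import GeneModel, GeneSet


def u_by_pair_counting(x, y):
    """Independent oracle: count (x, y) pairs with x > y, ties 1/2."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


class TestMannWhitney:
    def test_tiny_example(self):
        u, _ = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0  # brute force over all 4 pairs

    def test_u_matches_pair_counting(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n1, n2 = rng.integers(2, 9, size=2)
            x = rng.choice([0.1, 0.2, 0.3, 0.4], size=n1)   # forced ties
            y = rng.choice([0.1, 0.2, 0.3, 0.4], size=n2)
            u, _ = mann_whitney_u(x, y)
            assert u == pytest.approx(u_by_pair_counting(x, y))

    def test_exact_p_by_enumeration(self):
        """For small groups the p-value is the exact permutation tail."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            u, p = mann_whitney_u(x, y)
            mu = len(x) * len(y) / 2
            pooled = np.concatenate([x, y])
            ranks = stats.rankdata(pooled)
            devs = []
            for idx in itertools.combinations(range(9), 4):
                u_perm = ranks[list(idx)].sum() - 4 * 5 / 2
                devs.append(abs(u_perm - mu))
            expected = np.mean(np.array(devs) >= abs(u - mu) - 1e-12)
            assert p == pytest.approx(expected)

    def test_large_sample_matches_scipy(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        y = rng.normal(0.4, 1.0, size=50)
        u, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(3)
        pool = rng.normal(size=100)
        _, p = mann_whitney_u(pool[:50], pool[50:])
        assert min(1.0, p * 3) > 0.05

    def test_location_shift_detected(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0.0, 1.0, size=500)
        b = rng.normal(0.3, 1.0, size=500)
        _, p = mann_whitney_u(a, b)
        assert min(1.0, p * 3) < 0.05


class TestCodonMinScores:
    @pytest.fixture()
    def two_codon_gene(self):
        gene = GeneModel("g1", "c", "+", 1, 6, exons=[(1, 6)], cds=[(1, 6)])
        multi = GeneModel("g2", "c", "+", 11, 16, exons=[(11, 16)],
                          cds=[(11, 16)], n_transcripts=2)
        return GeneSet([gene, multi], flank=0)

    def _scores(self, positions, per_alt):
        rows = []
        for pos in positions:
            for alt, s in zip("ACG", per_alt(pos)):
                rows.append(("c", pos, "T", alt, s))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "score"])

    def test_min_over_alts_and_grouping(self, two_codon_gene):
        scores = self._scores(range(1, 7), lambda p: (0.2 + p / 100, 0.5, 0.9))
        minima = codon_min_scores(scores, two_codon_gene)
        assert len(minima) == 6          # 2 codons x 3 positions, one gene
        assert set(minima["gene"]) == {"g1"}          # multi-transcript excluded
        assert (minima.groupby("codon_pos").size() == 2).all()
        assert minima.loc[minima["pos"] == 1, "min_score"].iloc[0] == pytest.approx(0.21)

    def test_incomplete_positions_excluded(self, two_codon_gene):
        scores = self._scores(range(1, 7), lambda p: (0.2, 0.5, 0.9))
        scores = scores.drop(scores[(scores["pos"] == 4)].index[:1])
        minima = codon_min_scores(scores, two_codon_gene)
        assert len(minima) == 5
        assert minima.attrs["n_incomplete"] == 1


class TestCompareCodonPositions:
    def _planted(self, n_codons=500, means=(0.5, 0.6, 0.3), sd=0.1, seed=0,
                 n_genes=20):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_codons):
            gene = f"g{i % n_genes}"
            for k in range(3):
                rows.append((gene, i + 1, k + 1, 3 * i + k + 1,
                             float(np.clip(rng.normal(means[k], sd), 0, 1))))
        return pd.DataFrame(rows, columns=["gene", "codon", "codon_pos", "pos",
                                           "min_score"])

    def test_null_is_not_significant(self):
        minima = self._planted(means=(0.5, 0.5, 0.5), n_codons=50)
        result = compare_codon_positions(minima)
        assert result.bonferroni_factor == 3
        assert (result.pairwise["p_corrected"] > 0.05).all()

    def test_planted_ordering_recovered(self):
        minima = self._planted()
        result = compare_codon_positions(minima)
        assert (result.pairwise["p_corrected"] < 0.05).all()
        by_pos = minima.groupby("codon_pos")["min_score"].mean()
        assert by_pos[2] > by_pos[1] > by_pos[3]

    def test_per_gene_scope(self):
        minima = self._planted(n_codons=400, n_genes=10)
        result = compare_codon_positions(minima, scope="per-gene")
        assert result.bonferroni_factor == 3 * 10
        assert set(result.fraction_significant) <= {
            "pos1_vs_pos2", "pos1_vs_pos3", "pos2_vs_pos3"
        }
        # strong planted separation: essentially every gene significant
        assert result.fraction_significant["pos2_vs_pos3"] > 0.9


class TestAFBins:
    def test_hand_arithmetic(self):
        records = pd.DataFrame({"score": [0.2, 0.4, 0.6], "af": [0.01, 0.01, 0.5]})
        summary = af_bin_summary(records)
        assert summary.rare_mean == pytest.approx(0.3)
        assert summary.overall_mean == pytest.approx(0.4)
        assert summary.common_mean == pytest.approx(0.6)

    def test_bin_edges_left_open_right_closed(self):
        records = pd.DataFrame({"score": [0.5], "af": [0.025]})
        summary = af_bin_summary(records)
        assert summary.bins.loc[0, "count"] == 1        # first bin (0, 0.025]
        records2 = pd.DataFrame({"score": [0.5], "af": [0.0250001]})
        assert af_bin_summary(records2).bins.loc[1, "count"] == 1

    def test_counts_sum_and_rejection(self):
        rng = np.random.default_rng(0)
        records = pd.DataFrame({"score": rng.random(200),
                                "af": rng.random(200)})
        records.loc[0, "af"] = 0.0
        records.loc[1, "af"] = 1.5
        summary = af_bin_summary(records)
        assert summary.n_rejected == 2
        assert summary.bins["count"].sum() == 198

    def test_single_occupied_bin(self):
        records = pd.DataFrame({"score": [0.7], "af": [0.3]})
        summary = af_bin_summary(records)
        occupied = summary.bins[summary.bins["count"] > 0]
        assert len(occupied) == 1
        assert occupied["mean"].iloc[0] == pytest.approx(0.7)


class TestFractionAbove:
    def test_strict_at_point_six(self):
        scores = [0.7] * 9 + [0.1]
        assert fraction_above(scores)[0.6] == pytest.approx(0.9)

    def test_all_zero(self):
        out = fraction_above([0.0] * 5)
        assert out[0.6] == 0.0 and out[0.8] == 0.0

    def test_comparator_semantics_at_exact_threshold(self):
        out = fraction_above([0.8])
        assert out[0.8] == 1.0                      # >= 0.8 counts it
        assert fraction_above([0.6])[0.6] == 0.0    # > 0.6 does not

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(0)
        scores = rng.random(300)
        thresholds = {t: "gt" for t in np.linspace(0.05, 0.95, 10)}
        out = fraction_above(scores, thresholds)
        vals = [out[t] for t in sorted(out)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fraction_above([])


class TestGeneWindow:
    def test_window_means_and_markers(self):
        gene = GeneModel("g", "c", "+", 601, 650, exons=[(601, 650)],
                         cds=[(601, 648)])
        rows = []
        for pos in range(101, 1151):
            for alt, s in zip("ACG", (0.1, 0.2, 0.3)):
                rows.append(("c", pos, "T", alt, s))
        scores = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "score"])
        observed = pd.DataFrame({"chrom": ["c"], "pos": [700]})
        out = gene_window_means(scores, gene, observed_variants=observed)
        assert len(out) == 50 + 1000                   # gene + two 500 bp flanks
        assert np.allclose(out["mean_score"], 0.2)     # mean of the 3 alts
        assert out.loc[out["pos"] == 700, "observed_variant"].item()
        assert out.loc[out["pos"] == 620, "in_exon"].item()
        assert not out.loc[out["pos"] == 200, "in_exon"].item()

    def test_window_clipped_with_warning(self):
        gene = GeneModel("g", "c", "+", 101, 150, exons=[(101, 150)], cds=[])
        scores = pd.DataFrame({"chrom": ["c"], "pos": [120], "ref": ["T"],
                               "alt": ["A"], "score": [0.4]})
        with pytest.warns(UserWarning, match="clipped"):
            gene_window_means(scores, gene)


class TestRankCandidates:
    def _scores(self):
        return pd.DataFrame(
            [("c", 1, "A", "G", 0.9), ("c", 2, "A", "G", 0.1),
             ("c", 3, "A", "G", 0.1)],
            columns=["chrom", "pos", "ref", "alt", "score"],
        )

    def test_score_rank_can_reverse_p_rank(self):
        candidates = pd.DataFrame(
            [("c", 1, "A", "G", 1e-6), ("c", 2, "A", "G", 1e-9)],
            columns=["chrom", "pos", "ref", "alt", "p_value"],
        )
        out = rank_candidates(candidates, self._scores())
        assert out.loc[out["pos"] == 1, "rank_by_score"].item() == 1
        assert out.loc[out["pos"] == 1, "rank_by_p"].item() == 2

    def test_p_value_tiebreak_on_equal_scores(self):
        candidates = pd.DataFrame(
            [("c", 2, "A", "G", 0.5), ("c", 3, "A", "G", 1e-4)],
            columns=["chrom", "pos", "ref", "alt", "p_value"],
        )
        out = rank_candidates(candidates, self._scores())
        assert out.loc[out["rank_by_score"] == 1, "pos"].item() == 3

    def test_identical_rankings_spearman_one(self):
        candidates = pd.DataFrame(
            [("c", 1, "A", "G", 1e-9), ("c", 2, "A", "G", 1e-3)],
            columns=["chrom", "pos", "ref", "alt", "p_value"],
        )
        out = rank_candidates(candidates, self._scores())
        assert out.attrs["spearman"] == pytest.approx(1.0)

    def test_unscoreable_listed_separately(self):
        candidates = pd.DataFrame(
            [("c", 1, "A", "G", 0.1), ("c", 99, "A", "G", 0.2)],
            columns=["chrom", "pos", "ref", "alt", "p_value"],
        )
        out = rank_candidates(candidates, self._scores())
        assert not out.loc[out["pos"] == 99, "scoreable"].item()
        assert np.isnan(out.loc[out["pos"] == 99, "rank_by_score"].item())
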