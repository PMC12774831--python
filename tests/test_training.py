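import numpy as np
import pandas as pd
import pytest

from snvcadd.ancestral import AncestorMap
from snvcadd.io import GenomeSequence, PopulationAF
from snvcadd.training import (
    MutationRateModel,
    build_labeled_set,
    call_derived,
    cpg_context_mask,
    estimate_rates,
    per_chromosome_counts,
    simulate_variants,
    trim_to_match,
)


def ancestor_from_string(genome, chrom, anc_seq, skip="."):
    anc = AncestorMap({c: genome.length(c) for c in genome.chrom_names})
    for i, base in enumerate(anc_seq):
        if base != skip:
            anc.set_base(chrom, i + 1, base)
    return anc


class TestCallDerived:
    def _setup(self, alt_af):
        genome = GenomeSequence({"c": "AAGAA"})
        anc = ancestor_from_string(genome, "c", "AACAA")  # mismatch at pos 3
        af = PopulationAF()
        af.add("c", 3, "C", alt_af)
        return genome, anc, af

    def test_derived_allele_frequency_arithmetic(self):
        genome, anc, af = self._setup(0.05)
        derived = call_derived(genome, anc, af)          # 1 - 0.05 = 0.95 >= 0.9
        assert list(map(tuple, derived.itertuples(index=False))) == [("c", 3, "G", "C")]

    def test_below_threshold_dropped(self):
        genome, anc, af = self._setup(0.5)
        assert len(call_derived(genome, anc, af)) == 0   # 0.5 < 0.9

    def test_absent_site_treated_fixed(self):
        genome, anc, _ = self._setup(0.05)
        assert len(call_derived(genome, anc, PopulationAF())) == 1

    def test_identity_ancestor_yields_nothing(self):
        genome = GenomeSequence({"c": "ACGTACGT"})
        anc = ancestor_from_string(genome, "c", "ACGTACGT")
        assert len(call_derived(genome, anc, None)) == 0

    def test_threshold_validation_and_monotonicity(self):
        genome, anc, af = self._setup(0.2)
        with pytest.raises(ValueError):
            call_derived(genome, anc, af, af_threshold=0.0)
        with pytest.raises(ValueError):
            call_derived(genome, anc, af, af_threshold=1.5)
        # lowering the threshold never removes variants
        high = call_derived(genome, anc, af, af_threshold=0.9)
        low = call_derived(genome, anc, af, af_threshold=0.5)
        assert set(map(tuple, high.itertuples(index=False))) <= set(
            map(tuple, low.itertuples(index=False))
        )

    def test_n_reference_positions_excluded(self):
        genome = GenomeSequence({"c": "ANGAA"})
        anc = ancestor_from_string(genome, "c", "GC.AA")
        derived = call_derived(genome, anc, None)
        assert list(derived["pos"]) == [1]  # pos 2 has ref N, pos 3 no ancestor


class TestEstimateRates:
    def test_direct_counting_non_cpg(self):
        # 100 aligned ancestral A's (no CpG context anywhere), 2 become G
        anc_seq = "A" * 100
        ref_seq = "G" + "A" * 50 + "G" + "A" * 48
        genome = GenomeSequence({"c": ref_seq})
        anc = ancestor_from_string(genome, "c", anc_seq)
        rates = estimate_rates(genome, anc)
        assert rates.rate("c", "nonCpG", "A", "G") == pytest.approx(0.02)
        assert rates.rate("c", "nonCpG", "A", "C") == 0.0
        assert rates.counts("c", "nonCpG", "A", "G") == (2, 100)

    def test_direct_counting_cpg_context(self):
        # ten ancestral "CG" dinucleotides separated by A's; the C of each is
        # CpG-context on the ancestral strand; 3 C's became T in the reference
        anc_seq = "".join("CGA" for _ in range(10))
        ref = list(anc_seq)
        for k in range(3):
            ref[3 * k] = "T"
        genome = GenomeSequence({"c": "".join(ref)})
        anc = ancestor_from_string(genome, "c", anc_seq)
        rates = estimate_rates(genome, anc)
        assert rates.rate("c", "CpG", "C", "T") == pytest.approx(0.3)
        assert rates.counts("c", "CpG", "C", "T") == (3, 10)
        # ancestral A's in CpG context cannot exist
        assert rates.rate("c", "CpG", "A", "G") is None

    def test_identity_gives_zero_rates(self):
        genome = GenomeSequence({"c": "ACGTACGTAC"})
        anc = ancestor_from_string(genome, "c", "ACGTACGTAC")
        rates = estimate_rates(genome, anc)
        for b1 in "ACGT":
            for b2 in "ACGT":
                if b1 == b2:
                    continue
                r = rates.rate("c", "nonCpG", b1, b2)
                assert r is None or r == 0.0

    def test_zero_coverage_rejected(self):
        genome = GenomeSequence({"c": "ACGT"})
        anc = AncestorMap({"c": 4})
        with pytest.raises(ValueError, match="coverage"):
            estimate_rates(genome, anc)


class TestSimulate:
    @pytest.fixture()
    def uniform_setup(self):
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 1000)])
        genome = GenomeSequence({"c": seq})
        anc = ancestor_from_string(genome, "c", seq)
        rates = MutationRateModel.from_rates(
            ["c"],
            {("nonCpG", a, b): 0.01 for a in "ACGT" for b in "ACGT" if a != b}
            | {("CpG", a, b): 0.01 for a in "CG" for b in "ACGT" if a != b},
        )
        return genome, anc, rates

    def test_count_and_admissibility(self, uniform_setup):
        genome, anc, rates = uniform_setup
        sim = simulate_variants(genome, anc, rates, 100, seed=5)
        assert len(sim) == 100
        assert not sim.duplicated(["chrom", "pos", "alt"]).any()
        for rec in sim.itertuples(index=False):
            assert rec.ref == genome.sequence(rec.chrom, rec.pos)
            assert rec.alt != rec.ref

    def test_determinism(self, uniform_setup):
        genome, anc, rates = uniform_setup
        a = simulate_variants(genome, anc, rates, 50, seed=9)
        b = simulate_variants(genome, anc, rates, 50, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_variants(genome, anc, rates, 50, seed=10)
        assert not a.equals(c)

    def test_exclusions_never_emitted(self, uniform_setup):
        genome, anc, rates = uniform_setup
        first = simulate_variants(genome, anc, rates, 200, seed=1)
        excl = first.head(50)
        rest = simulate_variants(genome, anc, rates, 200, seed=1, exclusions=excl)
        banned = set(map(tuple, excl[["chrom", "pos", "alt"]].itertuples(index=False)))
        got = set(map(tuple, rest[["chrom", "pos", "alt"]].itertuples(index=False)))
        assert not banned & got

    def test_too_many_requested(self, uniform_setup):
        genome, anc, rates = uniform_setup
        with pytest.raises(ValueError, match="admissible"):
            simulate_variants(genome, anc, rates, 10**6, seed=0)

    def test_undefined_rate_refused(self):
        genome = GenomeSequence({"c": "AAAA"})
        anc = ancestor_from_string(genome, "c", "AAAA")
        empty = MutationRateModel()
        empty.set_counts("c", "nonCpG", "A", "G", 0, 0)  # zero denominator
        with pytest.raises(ValueError, match="undefined"):
            simulate_variants(genome, anc, empty, 1, seed=0)

    def test_rate_proportions_respected(self):
        """C->T draws split between CpG and non-CpG context in proportion to
        the configured 10x rate ratio (chi-square on the binary split)."""
        from scipy import stats

        rng = np.random.default_rng(2)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200_000)])
        genome = GenomeSequence({"c": seq})
        anc = ancestor_from_string(genome, "c", seq)
        rates = MutationRateModel.from_rates(
            ["c"],
            {("nonCpG", a, b): 0.01 for a in "ACGT" for b in "ACGT" if a != b}
            | {("CpG", a, b): (0.1 if (a, b) == ("C", "T") else 0.01)
               for a in "CG" for b in "ACGT" if a != b},
        )
        sim = simulate_variants(genome, anc, rates, 5000, seed=3)
        ct = sim[(sim["ref"] == "C") & (sim["alt"] == "T")]
        cpg = cpg_context_mask(genome, "c")
        in_cpg = cpg[ct["pos"].to_numpy() - 1]
        n_cpg_c = int((cpg & (genome.base_array("c") == b"C")).sum())
        n_non_c = int((~cpg & (genome.base_array("c") == b"C")).sum())
        w_cpg, w_non = n_cpg_c * 0.1, n_non_c * 0.01
        expected = np.array([w_cpg, w_non]) / (w_cpg + w_non) * len(ct)
        observed = np.array([in_cpg.sum(), (~in_cpg).sum()])
        assert stats.chisquare(observed, expected).pvalue > 0.001


class TestTrimAndLabel:
    def _variants(self, n, chrom="c", alt="G"):
        return pd.DataFrame(
            {"chrom": chrom, "pos": np.arange(1, n + 1), "ref": "A", "alt": alt}
        )

    def test_trim_size_contract(self):
        out = trim_to_match(self._variants(1500), 1000, seed=0)
        assert len(out) == 1000

    def test_trim_identity_when_equal(self):
        sim = self._variants(40)
        out = trim_to_match(sim, 40, seed=0)
        pd.testing.assert_frame_equal(out, sim)

    def test_trim_too_small_and_determinism(self):
        with pytest.raises(ValueError, match="increase"):
            trim_to_match(self._variants(5), 10, seed=0)
        a = trim_to_match(self._variants(100), 30, seed=4)
        b = trim_to_match(self._variants(100), 30, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_labels_and_counts(self):
        derived = self._variants(3)
        simulated = self._variants(3, alt="T")
        labeled = build_labeled_set(derived, simulated)
        assert list(labeled["label"]) == [1, 1, 1, 0, 0, 0]
        counts = per_chromosome_counts(labeled)
        assert counts.loc["c", "derived"] == 3
        assert counts.loc["c", "simulated"] == 3

    def test_overlap_rejected(self):
        derived = self._variants(3)
        with pytest.raises(ValueError, match="both classes"):
            build_labeled_set(derived, derived)

    def test_equal_class_sizes_after_pipeline(self, bundle):
        counts = bundle.labeled["label"].value_counts()
        assert counts[0] == counts[1]
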