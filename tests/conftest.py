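import numpy as np
import pytest

import snvcadd as sc
from snvcadd.synth import FixtureConfig


@pytest.fixture(scope="session")
def bundle():
    """Default-scale synthetic fixture (100 kb, ~2k variants per class)."""
    return sc.make_full_fixture(seed=1)


@pytest.fixture(scope="session")
def annotator(bundle):
    return sc.build_annotator(bundle)


@pytest.fixture(scope="session")
def fit_result(bundle, annotator):
    """Model trained on the default fixture at the default L2."""
    return sc.fit_impact_model(bundle.labeled, annotator, tune=False, l2=1.0)


@pytest.fixture(scope="session")
def tiny_bundle():
    """Small fixture for cheap I/O and CLI round-trips."""
    cfg = FixtureConfig(chrom_lengths={"2L": 15_000, "2R": 8_000}, n_genes=4)
    return sc.make_full_fixture(cfg, seed=3)


@pytest.fixture()
def simple_genome():
    """60 bp single-chromosome genome with one hand-placed gene:
    5'UTR(4) + CDS "ATGGCTTAA" + 3'UTR(4), all on the sense strand."""
    from snvcadd.genes import GeneModel, GeneSet
    from snvcadd.io import GenomeSequence

    left = "ACGTACGTAC"                      # 10 bp lead-in
    utr5, cds, utr3 = "TTTT", "ATGGCTTAA", "GGGG"
    right = "ACGTACGTACGTACGTACGTACGTACGTACGTA"
    seq = left + utr5 + cds + utr3 + right
    genome = GenomeSequence({"chr1": seq})
    gene = GeneModel(
        gene_id="g1", chrom="chr1", strand="+",
        start=11, end=11 + len(utr5 + cds + utr3) - 1,
        exons=[(11, 11 + len(utr5 + cds + utr3) - 1)],
        cds=[(15, 23)],
    )
    return genome, GeneSet([gene], flank=10)


def auc_pair_counting(scores, labels):
    """Brute-force ROC-AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        wins += (p > neg).sum()
        ties += (p == neg).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))
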