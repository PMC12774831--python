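# Methods

This note documents the model, the numerical choices, the synthetic-data
generator, and the known limitations of the `snvcadd` pipeline.

## Training-set construction

**Derived variants.** The ancestral extraction maps the ancestor row of each
alignment block onto sense-strand reference coordinates (reverse-strand
reference rows are complement-mapped; ambiguity codes and gaps count as
unreconstructed; overlapping blocks resolve first-wins with a logged conflict
count).  A position yields a derived variant when ancestor and reference
bases are both defined and differ and the derived (reference) allele's
population frequency is at least the threshold (default 0.9).  The derived
allele frequency is one minus the summed alt frequencies at the site;
sites with no population record are treated as fixed (frequency 1.0).  The
stored record keeps the reference allele as `ref` and the ancestral allele as
`alt`, so both training classes are annotated as substitutions on the
reference genome.

**Mutation rates.** Substitution rates are estimated per chromosome as
r[b₁→b₂ | context] = #(ancestral b₁, reference b₂, context) / #(ancestral
b₁, context), for the 12 ordered base pairs, split by CpG context.

*Context conventions.*  CpG context is the C or the G of a sense-strand "CG"
dinucleotide, but the sequence it is read from differs by direction of use:

* **Estimation** reads context off the **ancestral** sequence — the sequence
  the substitutions originated in.  An ancestral CpG deamination (C→T)
  leaves "TG" on the reference, so reference context is structurally blind to
  the CpG elevation; ancestral context makes it identifiable.  Positions
  whose relevant neighbor is unreconstructed are conservatively non-CpG.
  Since CpG-context positions carry C or G by definition, CpG rates exist
  only for ancestral C and G sources (6 rates); rates for ancestral A/T in
  CpG context have near-empty denominators and are reported as undefined.
* **Simulation** reads context off the **reference** — the sequence being
  mutated.

**Simulation.** De novo variants are drawn over all (position, alt) pairs
with a reconstructed ancestral base, with weight r[ref→alt | context],
without replacement (duplicates would leak identical rows into training),
via the Gumbel top-k construction, which reproduces successive
probability-proportional draws and is deterministic per seed.  Excluded
pairs (by default the derived set) are never emitted; `alt = ref` is
impossible by construction.  A `mutate_from="ancestor"` flag conditions the
draw on the ancestral base instead of the reference base; the reference
reading is the default.  The simulated set is randomly trimmed to the
derived count, giving exactly balanced classes.

## Annotation and features

The consequence classifier assigns one of 14 categories with the fixed
priority CS > SG > SL > NS > SN > S > U5 > U3 > NC > I > UP > DN > IG (O is a
fallback bucket); multi-gene hits take the most severe category.  Canonical
splice (CS) is the first/last 2 bp of an intron; the splice region (S) spans
intronic bases 3–8 and exonic bases 1–3 from a junction; upstream/downstream
use a 500 bp flank, matching the gene-window convention of the analyses.
Codon changes use the standard genetic code; protein length is counted in
codons including the terminal stop so that relProtPos ∈ (0, 1].  Grantham
distances come from the published 1974 matrix shipped as packaged data
(identity 0, maximum Cys–Trp 215); they are defined only for amino-acid pairs
(not stops) and only populated for non-synonymous changes.  Local GC content
uses a 75 bp window centered on the variant, clipped at chromosome ends.

The shipped feature specification declares 38 base annotations — 5
categoricals (consequence ×14, original and alternate amino acid ×21 each,
two 9-state chromatin tracks), 20 numerics, 13 indicator tracks — and 42
combination rules crossing a categorical with one or two numerics (one
product column per category).  Missing numerics impute to the declared
default (0) and three of them (Grantham, CDSpos, protPos — the ones undefined
outside coding sequence) additionally emit a 0/1 missingness column; missing
categoricals take the declared default category or an all-zero one-hot row
when none is declared.  This expands to exactly 691 columns, 581 of them
combinatorial.  The exact combination inventory of the original feature set
is not published column-by-column; the shipped spec reproduces the published
counts and the composite naming pattern and is a package-level
reconstruction, declared in `data/feature_spec_691.yaml` so it can be revised
without code changes.  The model artifact stores a checksum of the spec and
scoring refuses a mismatched layout.

Scaling divides each column by its training-set **population** standard
deviation (no centering); constant columns are dropped from the model's
view, and a scaled-matrix flag guards against dividing twice.

## Model

The classifier minimizes the summed negative log-likelihood plus (λ/2)‖w‖²
with an unpenalized intercept (penalizing it would couple scores to class
balance).  Because the penalty is applied to the *summed* likelihood, a given
λ means weaker relative regularization on larger datasets; the selected
constant is meaningful only relative to this convention.  Newton/IRLS
iterations use step halving whenever a full step would increase the
objective, converge at gradient norm < 10⁻⁸, and cap at 100 iterations.
λ is tuned over {0.01, 0.1, 1, 10, 100} by five repeated 90/10 sub-sampling
splits within the 90% training partition, selecting the argmax of mean
validation accuracy with ties broken toward the larger λ.  Held-out
evaluation reports accuracy at the 0.5 threshold and rank-based ROC-AUC
(ties ½).  The impact score is P(simulated) = 1 − σ(w·x + b) with the
derived class coded 1; a unit test pins this orientation because a silent
flip is the most dangerous possible bug in the scorer.

## Analyses

Mann–Whitney U uses exact enumeration of all label assignments for groups of
at most 8 observations each, and otherwise the normal approximation with tie
correction and 0.5 continuity correction.  Bonferroni families are defined
per invocation: 3 pairs genome-wide, 3 × genes for the per-gene scope; the
factor is reported in the result.  Codon-position contrasts use the minimum
score over the three alts per coding position (a conservative per-position
summary), restricted to single-transcript sense-strand gene models.
Allele-frequency bins are left-open right-closed with width 0.025, first bin
(0, 0.025], AF being the non-reference allele frequency; the rare-allele cut
is AF < 0.05.  Threshold fractions use strict `>` at 0.6 and inclusive `≥`
at 0.8, matching the phrasing these conventions come from ("above 0.6",
"0.8 and higher").

## Synthetic fixtures

The generator builds the study conditions end to end, ancestor-first: an
i.i.d. proto-sequence (gc = 0.5) plays the ancestor; every position mutates
forward into the reference with the configured rates under ancestral CpG
context — so rate estimation recovers the configured truth with per-site
binomial error; the ancestor is then exposed over randomly covered 250 bp
blocks (default coverage 0.60).  Defaults: non-CpG transitions 0.012,
transversions 0.006, CpG transitions ×10 (0.12); residual ancestral allele
frequency 0.05 at derived sites, with a random 10% of sites held at 0.5 so
the AF ≥ 0.9 filter has exactly known true negatives.  Gene models (valid
two-exon ORFs with canonical splice dinucleotides, 500 bp clear flanks) are
written into the reference after divergence, and their spans are blanked
from the ancestor so that the edited bases can neither contaminate the rate
estimates nor produce spurious derived calls — the consequence machinery is
therefore exercised by enumeration and dedicated unit fixtures rather than by
the training variants, whose coding-consequence features are constant and
dropped by the scaler.  One conservation-like track (PhyloP) carries the
planted class signal: N(effect, sd²) at simulated-class positions, N(0, sd²)
elsewhere, defaults effect = 2, sd = 1, giving the closed-form optimal AUC
Φ(effect/(sd·√2)) ≈ 0.921; all other tracks are uninformative noise.  The
default scale is 100 kb over two chromosomes with ~2,000 variants per class —
large enough for stable statistics, small enough that the full pipeline runs
in seconds.  All randomness flows from a single seed through deterministic
per-step sub-seeds; regeneration is byte-identical.

Problem sizes used by the acceptance script: rate recovery on a 10⁵-base
fully covered fixture (transition 0.01, transversion 0.002, CpG ×10);
simulator goodness of fit with n = 10⁴ draws on a 1 Mb fixture, where the
heaviest substitution type stays far from without-replacement saturation
(depletion ≈ 2%, negligible at the α = 0.001 test); Newton-vs-reference on a
200 × 5 problem; the end-to-end and tuning checks on the default fixture.

**What passing tests do and do not show.** The generator has no linkage,
demography, selection gradients, alignment error, or realistic annotation
correlation structure, and plants the class signal in a single track.
Passing therefore demonstrates that the machinery is correct — rates are
recovered, the simulator matches its configuration, the optimizer solves its
objective, planted signal is found and absent signal is not — not that the
scores are biologically accurate on real genomes.

## Known limitations

* Indels, MNVs and structural variants are out of scope; only SNVs.
* Mutation rates are per-chromosome, not windowed.
* The consequence classifier is a deterministic stand-in for a full
  annotation engine: it handles the 14 categories above on well-formed gene
  models but no biotype-specific rules, NMD, or overlapping-transcript
  subtleties.
* Conservation and DNA-shape values are consumed as tracks; the pipeline
  does not compute them from alignments.
* Pooling of multiple population VCFs is unweighted (mean) or intersection;
  no sample-size weighting.
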