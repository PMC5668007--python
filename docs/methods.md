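# Methods

## Disease vectorization

**Partition.**  The genome is divided into chromosome substructures in
karyotype order: a p and a q substructure for every divided chromosome, one
entry for each undivided chromosome, the mitochondrion last.  The default
undivided set {13, 14, 15, 22, MT} reflects the near-absence of annotated
protein-coding genes on the acrocentric p-arms and yields 45 substructures.
The set is configurable because it is a property of a particular gene-catalog
snapshot, not of the method.  Genes inside a substructure are ordered by
base-pair start (ties by gene id); positions are never used as distances,
only as an ordering, so coordinate resolution is irrelevant.  Empty
substructures are retained: downstream similarity and learning need vectors
of fixed length S.

**Status series and entropy.**  A disease's gene set marks a 0/1 series per
substructure.  Sliding a window of size k over a series of length m gives
W = m − k + 1 window patterns; the coordinate value is the Shannon entropy
−Σ f_q ln f_q over observed patterns (0·ln 0 = 0).  Conventions:

* natural logarithm — the base only rescales all vectors uniformly and the
  similarity is scale-invariant, so the choice is immaterial; it is still
  configurable in spirit by scaling, not exposed as a knob;
* series shorter than the window have no windows and entropy 0, keeping the
  map total;
* windows do not wrap around series ends (a linear scan with step 1).

The printed defaults k₁ = 9 (gene series) and k₂ = 8 (pathway series) are
the values selected on the original benchmark; the smallest real substructure
has 9 protein-coding genes, which motivates the k₁ range.

**Pathway sub-vector.**  Pathways are ordered lexicographically by id and cut
into T = 30 consecutive groups, the first T − 1 of size ⌊M/T⌋ and the
remainder in the last (with the real catalog scale M = 303 this is 29 groups
of 10 plus one of 13).  A pathway's status is 1 when the disease's gene set
is enriched in it by Fisher's exact test at α = 0.05.  The test is two-sided
by default (matching the generic exact-test routine the construction is built
on); a right-tailed variant is available, since enrichment semantics favor
it.  No multiple-testing correction is applied: the threshold produces a
feature encoding, not a discovery list.  The disease-gene count n is taken
*within* the test universe (the union of pathway genes, or the catalog for
substructure tests), which guarantees a valid contingency table.

The exact test is implemented with integer arithmetic over the
hypergeometric support: the two-sided p-value sums the probabilities of all
tables with the observed margins that are at most as likely as the observed
one, with ties decided by exact integer comparison.  This makes the
implementation bit-reproducible and lets the test suite demand exact
agreement with a brute-force enumeration oracle over every margin
configuration with universe size A ≤ 60.

## Disease similarity

For a pair of diseases the principal angle between the chromosome-entropy
vectors (simGe) and between the pathway-entropy vectors (simPe) are combined
as Sim = exp(−[θ·simGe + (1−θ)·simPe]) with θ = 0.8 by default.  When either
vector of a component has zero norm the component angle is defined as 0 — the
literal reading of the defining equations, which makes two geneless diseases
maximally similar; a `strict` flag instead returns similarity 0 for such
degenerate pairs.  Whole-series baselines apply the same angle→exponential
pipeline to the raw concatenated 0/1 series; they exist to quantify how much
the substructure-wise entropy encoding ("the parts") gains over the
undivided series ("the whole").

The benchmark ROC protocol scores gold-standard similar disease pairs
against n = 560 randomly sampled non-benchmark pairs, repeated 100 times
(sampling without replacement within a repeat, seeded).  AUC uses the
rank-sum formulation with ties counted ½.  The *average* AUC is the mean over
repeats; the *overall* AUC pools all repeats' scores.

## Pair features

* sf1/sf2 — the disease's two entropy sub-vectors (45 + 30 dims).
* sf3 — lncRNA sequence k-mer frequencies, k = 3 (64 dims), sliding window
  step 1; windows containing non-ACGT characters are dropped from numerator
  and denominator so the vector stays a probability vector; U → T on load.
* sf4 — the lncRNA's expression profile (16 tissues by default), values used
  as provided.
* sf5 — max, min and mean Spearman correlation between the lncRNA profile
  and the profiles of the disease's genes (genes without expression are
  skipped; a zero-variance profile contributes correlation 0; a disease with
  no expressed genes gets (0, 0, 0) with a warning).  Batch computation uses
  a centered-rank matrix product that is exactly the pairwise Spearman
  correlation; unit tests cross-check it against `scipy.stats.spearmanr`.

Feature type W ∈ {0…7} selects the optional blocks (sf2, sf4, sf5) on top of
the always-present sf1 + sf3; type 0 is 109-dimensional, type 7 is
158-dimensional at the default configuration.  No standardization is applied
before the SVM — the published pipeline describes none — but all blocks are
kept on comparable numeric scales by construction of the inputs.

## PU learning

Bagging SVM: V rounds (default 10); each round draws an unlabeled subsample
of size R (default |PO|) *without replacement* — this guarantees a nonempty
out-of-bag set every round; a with-replacement flag exists.  The per-round
score f_b(x) is the SVM decision-function value (signed margin): averaging
continuous margins preserves ranking information, unlike hard labels.
Default classifier: RBF kernel, C = 2³, γ = 2⁻⁵, feature type 7 — the
published final configuration.

Baseline selection draws |PO| provisional negatives at random (default 100
repeats), runs stratified 5-fold CV per grid point (C and γ exponents
−8…8) and feature type, and maximizes the positive-class F1 averaged over
folds and repeats.  Folds are reshuffled per repeat; ties break toward the
lowest (kernel, C-exponent, γ-exponent, feature type) in grid order, making
selection deterministic under a fixed seed.

**LOOCV.**  Each positive pair is moved into the unlabeled set in turn and
scored by a bagging run on the remaining positives (R then defaults to the
training-positive count).  The pooled AUC compares the held-out scores with
unlabeled-pair scores from a single full-positive bagging run; this keeps the
protocol at |PO| + 1 bagging runs instead of |PO| full rescorings while
using the same scoring rule everywhere.  In the rare event that a held-out
pair lands in every bag, one extra round scores it directly.

**LODOCV.**  For each disease, all its positives are hidden, the model is
retrained, and the AUC compares the hidden positives with that disease's
unlabeled pairs; diseases holding every positive, or with no candidate
lncRNAs, are skipped with a warning.

## Synthetic universes

The generator plants, at desk scale, the three structures the method
exploits.  Defaults: 900 genes spread evenly over the 45 default
substructures (20 per substructure, so k₁ = 9 leaves 12 windows), 303
pathways of 25 genes in 30 groups (the real catalog scale, so k₂ = 8 leaves
3 windows per group of 10), 40 diseases × 12 genes, 60 lncRNAs × 400 nt, 16
tissues, 10 % positive pairs.

* **Clustering** — each disease prefers 1–2 substructures and draws a
  binomial(genes_per_disease, clustering_prob) share of its genes from them,
  the rest uniformly.  At clustering_prob = 0.9 a preferred substructure
  holds ≈ 11 of 20 member genes, which the exact test flags at p ≪ 0.05.
* **Pathway planting** — with probability 0.5 a pathway draws 60 % of its
  genes from one disease's neighborhood (its genes plus preferred
  substructures), so disease gene sets enrich a handful of pathways.
* **Expression** — log-normal per tissue: each substructure carries a latent
  log-profile (sd 0.5), diseases scatter around the latent of their first
  preferred substructure (sd 0.15), genes around their primary disease
  (sd 0.25), background genes are independent (sd 0.6).  The moderate
  dispersion emulates normalized relative abundances rather than raw-count
  dynamic range and keeps the expression block from numerically dominating
  the unscaled RBF kernel.
* **Positives and co-expression** — each lncRNA anchors at a random disease
  and its positives are sampled among diseases sharing a preferred
  substructure with the anchor (spilling over randomly when the cluster is
  exhausted).  An associated lncRNA's log-profile is the mean of its
  diseases' gene log-profiles plus N(0, coexpression_noise); unassociated
  lncRNAs are background.  As both the co-expression noise and the
  within-disease gene noise shrink, the planted maximum Spearman correlation
  approaches 1.
* **Benchmark pairs** — all disease pairs sharing a preferred substructure.
* Sequences are i.i.d. uniform ACGT with an optional GC-bias knob (default
  off) for associated lncRNAs.

Everything is drawn from one `numpy` generator in a fixed order, so a seed
reproduces the bundle byte for byte.

What the fixtures do *not* emulate: realistic chromosome lengths and gene
densities, linkage or haplotype structure, pathway overlap topology, sequence
motifs, or the heavy tails and batch effects of real expression atlases.
Passing the planted-signal tests therefore demonstrates that the
implementation recovers the structure the model assumes when it is present —
not that the model captures real disease biology; the published real-data
AUCs require the curated external datasets.

## Problem sizes and numerics

The default test and acceptance runs use the 40 × 60 universe (240
positives, 2160 unlabeled pairs) and V = 10; LOOCV is then 241 bagging runs
(≈ 2 400 SVM fits) and completes in well under a minute per feature type.
The oracle checks run 1 000 random entropy series (lengths 0–60, k ≤ 10) and
every exact-test margin with A ≤ 60 (≈ 1.27 million table evaluations).
Angles are computed as arccos of a clipped cosine; near-parallel vectors
therefore carry an absolute angle error around √ε ≈ 10⁻⁸, which the tests
tolerate explicitly.  All AUCs use the rank-sum formulation with average
ranks for ties.

## Known limitations

* The zero-norm similarity branch rewards shared emptiness (by design, with
  a strict mode as the escape hatch).
* Baseline selection over the full 17 × 17 grid × 8 feature types × 100
  repeats is expensive at realistic scale; the repeats, grid and feature-type
  list are parameters, and the defaults are only sensible for curated runs.
* Expression values are used as provided; no normalization is applied or
  validated.
* Genes exactly on a centromere have no natural arm; the loader requires an
  explicit arm label in the input rather than guessing.
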