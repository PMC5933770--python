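# Methods

## Scope and conventions

`truncvar` scores the disease association of truncating (frameshift and
nonsense) protein variants. The two variant classes are treated
identically throughout: both disrupt everything C-terminal of the
truncation position, so a variant is fully described by its protein and
the 1-based position `k` (counted from the N-terminus, inclusive at both
ends everywhere in the package and its file formats). Structures enter
only as Cα traces; profiles are consumed as already-normalized frequency
vectors (rows off unity by ≤ 1e-3 are renormalized, anything worse is
rejected); amino acids are ordered alphabetically by one-letter code
(`ACDEFGHIKLMNPQRSTVWY`) in every 20-wide block.

Upstream steps that produce these inputs — structure prediction, profile
generation, domain assignment, per-position missense scoring, annotation
transfer — are out of scope; their outputs are inputs here.

## Features

Nine groups, 66 slots in the candidate schema, 46 after the
domain-composition group is removed:

| group | width | definition |
|---|---|---|
| ref_aa | 20 | one-hot of the wild-type residue at `k` |
| contact_comp | 20 | `q(a) = N(a)/Σ_b N(b)` over residues `j ≠ k` with ‖Cα_j − Cα_k‖ ≤ 12 Å |
| domain_comp | 20 | composition of the annotated domain containing `k` (whole protein if none) |
| entropy | 1 | `S_r(k) = S(k) − ⟨S⟩`, `S = −Σ_l f_l ln f_l`, `0·ln 0 = 0` |
| frac_affected | 1 | `(N_r − k)/N_r` |
| essential | 1 | gene-essentiality indicator |
| pathogenicity | 1 | mean over `j > k` of `#{missense scores at j ≥ 0.45}/19` |
| disease | 1 | sum of two disease-annotation indicators (0, 1 or 2) |
| ppi | 1 | raw interaction count |

Choices where the definitions left room:

* The contact set excludes residue `k` itself (its inclusion would add a
  constant) and includes sequence neighbours — they are physically within
  12 Å and their types carry signal. Contacts are unweighted counts. A
  contact-free position yields an all-zero block with a logged warning
  rather than a failure; trees handle the zero block.
* "Positions after the mutation" for the pathogenicity feature means
  strictly `j > k`: a nonsense mutation replaces residue `k` with a stop,
  so the downstream residues are the lost part. `k = N_r` gives 0 (empty
  average).
* Disease involvement is one 0/1/2 integer rather than two binaries, which
  keeps the count of gene-level features at five (46 = 61 − 20 + 5).
* `ppi` is used raw; tree splits are invariant to monotone transforms.
* A missing annotation row degrades to zeros with a warning; a missing
  structure, profile or missense matrix is a hard per-variant failure —
  those features are not imputable.

## Learner

A from-scratch gradient-boosted regression-tree ensemble,
`f(x) = Σ_m ε T_m(x)`, fit stagewise by least squares on 0/1 targets with
`f_0 = 0` (no intercept). Trees are grown greedily by variance reduction;
split candidates are midpoints between consecutive sorted unique feature
values; leaf values are mean residuals; a node is not split when no
candidate strictly reduces the summed squared error or a child would fall
below `min_leaf` samples. Ties in gain break to the lowest feature index,
then the lowest threshold, making training bit-reproducible. When a
midpoint rounds onto the upper of two adjacent floating-point values the
threshold falls back to the lower value so neither child can be empty.

Defaults are the reference protocol's: ε = 0.005, N_tree = 2000, depth 8,
min_leaf 1 (the protocol values are empirical, not optimized). Class
imbalance is handled by the dual balanced protocol: the pathogenic rows
are permuted with the seed and split into halves of ⌈n/2⌉ and ⌊n/2⌋; each
model trains on its half plus all neutral rows; the reported score is the
mean of the two raw scores clipped to [0, 1] (cutoffs are interpreted on
the probability-like [0, 1] scale; the call at a cutoff is inclusive,
score ≥ cutoff).

**Desk-scale configuration.** Test suites and examples run on cohorts of a
few hundred variants, where the full 2000-tree protocol is both slow and
mis-scaled: at N_tree = 200 with ε = 0.005 the additive sum can reach at
most 1 − 0.995²⁰⁰ ≈ 0.63, squeezing scores against the 0.5 cutoff, and
unpruned depth-8 trees memorize protein identity on ~360-sample training
folds. `Hyperparams.desk_scale(n_trees)` therefore sets ε = 10/N_tree —
preserving the full protocol's total shrinkage mass ε·N_tree = 10 — and
min_leaf = 10. Model structure, loss and the dual-pair protocol are
unchanged.

## Evaluation

Metrics follow the standard confusion-matrix definitions with pathogenic
as the positive class; MCC falls back to 0 when any denominator factor
vanishes, F-score to 0 when TP = 0. The ROC sweeps all distinct score
thresholds and is anchored at (0,0) and (1,1).

Homology control: pairwise identity is global Needleman–Wunsch (match +1,
mismatch 0, gap −1 open and extend) with identical aligned positions
divided by the shorter sequence length — the conservative denominator for
leakage control; the identity function is pluggable. Proteins are
clustered by single linkage at a 35 % cutoff (union–find), whole clusters
are dealt to folds round-robin in descending size order after a seeded
shuffle, and cross-validation with k equal to the cluster count reduces to
leave-one-cluster-out.

Feature reduction clusters the training proteins at the identity cutoff,
merges the smallest clusters pairwise down to the requested fold count
(ten by default), and makes a single elimination pass in schema order
against the fixed full-schema baseline: a group is discarded iff its
removal *strictly* improves the pooled leave-one-cluster-out MCC at the
0.5 cutoff.

## Significance layer

Neutral scores are histogrammed (density-normalized, default bin width
0.02 — exposed as an option) and a Gumbel (extreme-value) density
`(1/σ)·exp(z)·exp(−exp(z))`, `z = (μ−x)/σ`, is fitted by least RMSD at the
bin centers. The optimizer is a Nelder–Mead simplex over `(μ, log σ)`
(tolerance 1e-8) started from the method-of-moments estimates
(`mean = μ + γσ`, `var = π²σ²/6`, γ the Euler–Mascheroni constant); the
returned fit is never worse than the start. The p-value of a score is the
null survival function `p(x) = 1 − exp(−exp((μ−x)/σ))` — this reading of
the formula reproduces the published reference p-values (0.039 and 0.096
at the 0.5 cutoff for the two published parameter sets), which the test
suite asserts. p-values come from the fitted null, not the empirical
false-positive rate.

Exome FDR at a cutoff is `p · N_total / N_pred` (capped at 1), with
`N_total` approximating the neutral input count and `N_pred` the calls at
the cutoff. The FDR-versus-cutoff curve is typically non-monotone with an
interior minimum: past some cutoff `N_pred` drops faster than `p`.

## Synthetic cohorts

The generator produces everything the pipeline reads: sequences (uniform
over the 20 residues), Cα traces (self-avoiding random walks, 3.8 Å steps,
3.4 Å clash radius — contact neighbourhoods are non-degenerate but not
native-like), profiles (per-position mixture of a delta on the wild type
and a protein-wide Dirichlet background, mixture weight ~Beta(2,2) acting
as the conservation level), missense matrices (conservation plus
N(0, 0.15) noise, clipped to [0,1]), annotations (Bernoulli flags,
log-normal interaction counts) and labeled variants.

Labels are planted by a logistic model over three standardized feature
directions — position conservation, affected fraction, and combined
annotation score — with effect sizes (2, 4, 2) by default and an intercept
solved so the expected pathogenic fraction matches the requested fraction (0.5 by
default). These are deliberately strong effects: a pathogenic class
clearly enriched for conserved positions, long affected tails and
essential/disease genes, so that recovery failures indicate pipeline
defects rather than weak simulation signal. Zero effect sizes give labels
independent of every feature.

Default cohort geometry: 40 proteins of 100–140 residues with 4 genuine
homolog pairs (~60 % identity). The narrow length band is deliberate:
with the min-length identity denominator, wildly different lengths let
unrelated random sequences exceed the 35 % clustering cutoff, which would
percolate the single-linkage clusters; within this band unrelated pairs
stay below ~0.28 while the homolog pairs cluster correctly.

`generate_null_scores` draws i.i.d. Gumbel scores clipped to [0, 1] and
reports the clipped mass at each end. Note that for null parameters like
(0.07, 0.13) about 18 % of the Gumbel mass lies below zero; the clip
spike this puts in the first histogram bin will distort a subsequent
histogram-RMSD fit, so parameter-recovery checks use unclipped draws, and
realistic null fitting should use actual neutral-variant scores (as in the
README example) rather than clipped synthetic draws.

**What passing tests show — and don't.** The synthetic cohorts exercise
formats, invariants, determinism, signal recovery and null behaviour. They
do not emulate real fold geometry, real conservation patterns, real
annotation co-occurrence, or allele-frequency structure, so test results
quantify the pipeline's correctness, not expected performance on real
cohorts.

## Problem sizes in the test suite

The planted-signal cross-validation checks run a 40-protein / 400-variant
cohort through clustered 10-fold CV with `desk_scale(200)` hyperparameters
(about 20 s per run); the feature-reduction check uses a 30-protein /
240-variant cohort, 6 clusters and 100 trees with min_leaf = 1 — the
unregularized setting is intentional there, because the elimination
procedure exists precisely to catch feature groups that flexible trees
overfit (the domain-composition block, protein-level noise under this
generator, is discarded; every planted-signal group is retained). Gumbel
recovery uses 10 replicates of n = 5000.

## Known limitations

* Greedy trees do not guarantee an exact fit of n ≤ 2^depth distinct
  samples (splits can be arbitrarily unbalanced); exactness is guaranteed
  only for n ≤ depth + 1, which is what the tests assert alongside
  brute-force split-search equivalence.
* The two balanced halves are split by plain randomization, not stratified
  by gene.
* One full-length Cα model per protein is assumed; mapping variants onto
  per-domain models, genomic-to-protein coordinate mapping and
  multi-isoform handling are out of scope.
* Score "probabilities" are clipped sums, not calibrated posteriors; the
  significance layer exists precisely because of that.
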