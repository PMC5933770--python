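# truncvar

Disease-association prediction for **truncating protein variants** —
frameshift and nonsense (stop-gain) mutations that destroy everything
C-terminal of a position `k` in a protein of `N_r` residues.

Exome sequencing of a single patient yields thousands of variants, of which
truncating ones are disproportionately likely to be pathogenic — but most
are still neutral. This package scores a truncating variant's probability
of disease association from features of the affected protein and position,
and attaches a p-value and an exome-scale false-discovery-rate estimate to
every call. It is aimed at method developers and analysts who want a fully
inspectable, from-scratch implementation of this class of classifier,
together with a synthetic cohort generator that makes the entire pipeline
testable without any external data.

## The model

Each variant `(r, k)` is described by 46 features in the final schema
(66 in the candidate schema before feature reduction):

* **ref_aa** (20) — one-hot of the wild-type residue at `k`;
* **contact_comp** (20) — amino-acid composition `q(a) = N(a) / Σ_b N(b)`
  of residues whose Cα lies within 12 Å of position `k`'s Cα in the
  (predicted) structure;
* **domain_comp** (20, candidate schema only) — composition of the
  annotated domain containing `k`;
* **entropy** (1) — conservation `S_r(k) = S(k) − ⟨S⟩`, with
  `S = −Σ_l f_l ln f_l` from the position's amino-acid frequency profile
  and `⟨·⟩` the protein-wide mean;
* **frac_affected** (1) — fraction of structure lost, `(N_r − k)/N_r`;
* **essential**, **disease**, **ppi** (3) — gene essentiality flag,
  disease-involvement count over two annotation sources (0–2), and
  protein–protein-interaction count;
* **pathogenicity** (1) — mean, over positions `j > k`, of the fraction of
  the 19 possible missense substitutions at `j` scoring ≥ 0.45 on a
  supplied per-position missense pathogenicity matrix.

The scorer is a gradient-boosted regression-tree ensemble,

```
f(x) = Σ_{m=1}^{N_tree} ε · T_m(x),
```

fit stagewise by least squares on 0/1 class targets (defaults: shrinkage
ε = 0.005, N_tree = 2000, maximum depth 8). Because pathogenic variants
outnumber neutral ones roughly two to one in training cohorts, **two**
models are trained on complementary balanced halves (each a random half of
the pathogenic variants plus all neutral ones); a prediction is their
average, clipped to [0, 1], called disease-associated at a default cutoff
of 0.5.

Evaluation is homology-aware: proteins sharing ≥ 35 % sequence identity
(single linkage) are confined to the same cross-validation fold, and the
feature-reduction procedure drops a feature group whenever removing it
strictly improves leave-one-cluster-out MCC.

Scores are calibrated against an extreme-value (Gumbel) null fitted to
neutral-variant scores by least histogram RMSD; the p-value of a score `x`
is `p(x) = 1 − exp(−exp((μ−x)/σ))`, and for a whole exome the FDR of the
calls at a cutoff is estimated as `p · N_total / N_pred`.

## Worked example

```python
import numpy as np
from truncvar import (CohortSpec, FeatureSchema, GumbelNullModel, Hyperparams,
                      TruncatingVariantModel, generate_cohort, crossvalidate)

cohort = generate_cohort(CohortSpec(seed=7))           # 40 proteins, 400 variants
schema = FeatureSchema.final46()
hp = Hyperparams.desk_scale(200)                       # reduced tree count

cv = crossvalidate(cohort.proteins, cohort.variants, schema,
                   k=10, seed=1, hyperparams=hp)
print(cv.report.summary())

neutral = cv.scores[np.array(cv.labels) == "neutral"]
null = GumbelNullModel(neutral).fit()                  # extreme-value null
print(null.summary())
```

prints (about half a minute on one CPU):

```
Evaluation report
-----------------
MCC                      0.620
Sensitivity              0.688
Specificity              0.918
F-score                  0.779
False positive rate      0.082
False discovery rate     0.102
Counts                TP=141 FP=16 TN=179 FN=64
ROC AUC                  0.910

Extreme-value null fit (least histogram RMSD)
---------------------------------------------
n scores             195
bin width          0.020
mu               -0.0097
sigma             0.0393
fit RMSD           0.871
p(score=0.5)      0.0000
```

The cohort generator plants pathogenic labels on conserved positions, large
affected fractions and essential/disease genes; the clustered 10-fold MCC
of 0.62 (AUC 0.91) shows the pipeline recovers that signal out of fold,
while a label permutation drives the MCC to ≈ 0 (see the test suite). The
null fit then turns any score into a p-value — here a score of 0.5 is far
outside the neutral score distribution.

The same steps are available from the shell:

```sh
truncvar --seed 7 simulate --out cohort/
truncvar featurize --fasta cohort/proteins.fasta --structures cohort/structures \
    --profiles cohort/profiles --annotations cohort/annotations.tsv \
    --variants cohort/variants.tsv --missense cohort/missense --out features.tsv
truncvar --seed 1 train --features features.tsv --ntree 200 --lr 0.05 --out model.json
truncvar predict --model model.json --features features.tsv --out predictions.tsv
truncvar evaluate --predictions predictions.tsv --labels cohort/variants.tsv --out metrics.tsv
```

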