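# raacfam

Reduced amino-acid alphabet (RAAC) k-mer classification of protein
families, with a complete train/evaluate/predict pipeline and a synthetic
benchmark generator.

## The problem

Enzyme superfamilies such as the 2-oxoglutarate/Fe(II)-dependent (2OG)
oxygenases are hard to recognise from sequence alone: family membership is
carried by a short conserved catalytic core (the HxD...H iron-binding
triad) and by broad physicochemical composition, not by high overall
sequence identity.  A practical screen is a binary classifier over
sequence composition features.  Working on the raw 20-letter alphabet, the
k-mer feature space (20^k) is large and noisy; rewriting sequences over a
*reduced* alphabet — a partition of the 20 amino acids into s groups of
like physicochemical character — shrinks it to s^k and suppresses
conservative-substitution noise.  This package implements that strategy
end to end for any two-class protein task.

## The method

Given a reduction scheme with s groups and k-mer order k ∈ {1,2,3}, a
sequence P = R₁R₂…R_L is rewritten group-by-group and encoded as the
frequency vector of its overlapping k-mers,

    d_i = n_i / (L − k + 1),   i = 1 … s^k,

so each row sums to 1.  Features are ranked by the two-group one-way
ANOVA F statistic (between-class mean square over pooled within-class
mean square), and incremental feature selection (IFS) scores nested
prefixes of the ranking by cross-validated accuracy to pick the best
dimension.  The classifier is an RBF-kernel SVM; C and γ are chosen by an
exhaustive grid search over a geometric lattice inside 2⁻⁵ < C < 2¹⁵ and
2⁻¹⁵ < γ < 2³, scored by stratified 10-fold cross-validation.
Performance is reported as Sn, Sp, F1, Acc, MCC and the rank-statistic
(Mann–Whitney) AUC.

The 18 schemes of the type-33 reduction family (sizes 2–19, a nested
hierarchy whose first split separates polar from hydrophobic residues,
with cysteine kept apart) ship built in; arbitrary RAACBook-style
catalogs load from a plain-text scheme file.

Because the curated training corpora of published 2OG-oxygenase models
are not redistributable, the package includes a first-class synthetic
generator: positives carry one conserved `HxD-H`-style motif on a
polar-tilted background, negatives are background only, so the whole
pipeline is exercised and tested without any download.

## Worked example

```python
import numpy as np
from raacfam import ProteinFamilyModel, SimulationConfig, SVMConfig, generate

config = SimulationConfig(seed=7)          # 240 positives, 240 negatives
pos, neg, manifest = generate(config)
records = pos + neg
labels = np.array([1] * config.n_pos + [0] * config.n_neg)

model = ProteinFamilyModel.from_sequences(records, labels, scheme_size=15, k=2)
results = model.fit(ifs_step=15, svm_config=SVMConfig(seed=0))
print(results.summary())

queries = results.predict([("query_pos", pos[0][1]), ("query_neg", neg[0][1])])
print(queries[["id", "label", "probability"]].to_string(index=False))
```

prints

```
        Protein Family RAAC-SVM Classification Results
================================================================
Alphabet:        type 33, 15 groups (S-T-A-N-D-G-RQ-EK-H-P-IV-L-M-WYF-C)
K-mer order:     2   (encoding dimension 225)
Samples:         480 (240 positive, 240 negative)
Selected:        120 features (IFS best dimension, step 15)
SVM:             RBF kernel, C = 4, gamma = 4
CV:              10-fold stratified, seed 0, pooled out-of-fold scoring
----------------------------------------------------------------
Confusion:       TP=209  TN=219  FP=21  FN=31
Accuracy (Acc):   0.8917
Sensitivity:      0.8708
Specificity:      0.9125
F1 score:         0.8894
MCC:              0.7840
AUC:              0.9570
================================================================
       id  label  probability
query_pos      1     0.990495
query_neg      0     0.027024
```

The summary is the pooled 10-fold cross-validation of the selected
120-feature dipeptide model over the size-15 alphabet: the classifier
recovers the planted family signal at ~89–93% accuracy depending on the
simulation seed, and the two query sequences (one from each class) are
assigned confidently to their classes.  Feature ranking is re-learned
inside each training fold when computing these numbers, so they are free
of feature-selection bias.

## Command line

```bash
raacfam simulate --out-dir data/            # synthetic two-class FASTA
raacfam scan --pos data/positives.fasta --neg data/negatives.fasta \
        --out scan.tsv                      # (scheme, k) accuracy grid
raacfam train --pos data/positives.fasta --neg data/negatives.fasta \
        --size 15 -k 2 --ifs-step 15 --out model.joblib
raacfam predict --model model.joblib --fasta queries.fasta --out pred.tsv
raacfam evaluate --pred pred.tsv --truth data/truth.tsv
```

Every run logs its seed, config hash and version to stderr, and every
stochastic stage (simulation, fold assignment, grid search) is
bit-reproducible under a fixed seed.

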