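# peprank

Ranking-based convolutional models with attention for allele-specific
peptide–MHC class I binding prioritization.

## The problem

MHC class I molecules present short intracellular peptides (8–15 residues)
on the cell surface; predicting which peptides an allele binds is central
to epitope discovery and vaccine design. Binding data (e.g. IEDB exports)
mix quantitative IC50 measurements in nM with qualitative five-tier
binding calls. In practice the question is rarely "what is the exact
IC50?" but "which peptides should be assayed first?" — a *ranking*
problem. `peprank` treats it as one: instead of regressing affinities it
learns a scoring function `S(p)` whose order reproduces the order of
binding strength, using pairwise hinge objectives.

## The models and objectives

Affinities are normalized to `b = clamp(1 − log₅₀₀₀₀ x, 0, 1)` so stronger
binders score near 1, and mapped to levels 5 (positive-high, ≤100 nM)
through 1 (negative, >5000 nM). Duplicate measurements are consolidated by
majority vote over levels; unresolvable conflicts are dropped.

**ConvM** scores a peptide from a feature matrix whose column *j* is
`f_j = [e_j; o_j; o_{−j}]` — the residue encoding (BLOSUM62 row, one-hot,
and/or a learned 20-dim table) plus two learned position vectors indexed
from either end, so variable lengths share end-anchored positions. A 1-D
convolution with `d_r` kernels of width `k` produces one embedding per
k-mer (batch-norm + ReLU), a self-attention layer pools them,

    w_i = softmax(v · tanh(W r_i + b)),   c = Σ w_i r_i,

and a fully-connected head maps `c` to the scalar score. **SpConvM** adds
`d_g` global kernels spanning the whole middle-padded 15-column encoding
(MHCflurry padding convention: `GGFVPNMLSV → GGFVXXPNXXXMLSV`) and scores
from `[c; g]`.

Training minimizes one of four objectives on peptide pairs of one allele:

* `Hv = max(0, c + (b_i − b_j) − (S_i − S_j))` for `l_i > l_j` — margin
  grows with the affinity gap;
* `Hl = max(0, r·(l_i − l_j) − (S_i − S_j))` — margin per level gap;
* `Hi` — `Hl` across levels plus `max(0, |S_i − S_j| − r)` within a level;
* `MS` — piecewise squared error on sigmoid-normalized scores (the
  regression baseline objective).

SGD starts at lr 0.05; the learning rate decays by 10% after 5 epochs
without validation improvement and training stops after 20. Evaluation
uses average rank and hit rate of the promising set (IC50 < 100/500 nM),
pairwise AUC, early-retrieval ROC₅/ROC₁₀, and a hybrid metric `H`
combining all seven for model selection in 5-fold cross-validated grid
search. With `k = 1` the attention weights are per-residue and can be
pooled into a position × amino-acid matrix (`SMM_l`) that anticorrelates
with SMM-style scoring matrices when a motif is recovered.

Everything — the networks, backpropagation, losses and schedule — is
implemented in NumPy and validated against finite differences.

## Worked example

Peptides are scored with scikit-learn-style estimators. On a synthetic
allele whose affinity is planted at the two classic anchor positions
(position 2 and the C-terminal residue):

```python
import numpy as np
from peprank import ConvMRanker, auc
from peprank.preprocessing import consolidate_entries
from peprank.simulate import anchor_recovery_dataset

raw, truth, allele = anchor_recovery_dataset(2000, seed=1)
entries, _ = consolidate_entries(raw)
order = np.random.default_rng(1001).permutation(len(entries))
train = [entries[i] for i in order[400:]]
test = [entries[i] for i in order[:400]]

model = ConvMRanker(kernel_size=1, loss="hv", random_state=2001,
                    max_epochs=300).fit(train)
peps = [e.peptide for e in test]
scores = model.predict(peps)
print(round(auc(scores, np.array([e.b for e in test])), 3))

from peprank.experiments import anchor_attention_ratio
print(round(anchor_attention_ratio(peps, model.attention(peps)), 1))
```

This prints a held-out AUC of `0.969` — the model separates binders
(IC50 < 500 nM) from non-binders on unseen peptides — and an anchor
attention ratio of `9.8`: averaged over held-out peptides, the attention
weight at position 2 and the terminal position is about ten times the
weight elsewhere, i.e. the attention layer found the planted anchors.

The same pipeline is available from the shell:

```bash
peprank simulate --n-peptides 1000 --seed 1 --out data.tsv --truth truth.tsv
peprank preprocess --input data.tsv --out clean.tsv
peprank train --data clean.tsv --allele "SYN-A*01:01" --arch convm \
              --loss hv --seed 2 --out model.json
peprank predict --ckpt model.json --peptides peps.fasta --out scores.tsv
peprank evaluate --pred scores.tsv --truth clean.tsv
```

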