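# Methods

## Affinity preprocessing

Quantitative IC50 measurements `x` (nM) are normalized with
`b = clamp(1 − log₅₀₀₀₀ x, 0, 1)`; the base 50 000 nM is the conventional
reporting ceiling, so `b` spans (0, 1) exactly on x ∈ (1, 50000) and the
map inverts exactly there (`x = 50000^(1−b)`), which the synthetic
generator exploits. The five-tier level bands are half-open toward the
stronger-binding side — 5 = (0, 100], 4 = (100, 500], 3 = (500, 1000],
2 = (1000, 5000], 1 = (5000, ∞) nM — because the printed ranges overlap at
their endpoints and assigning a boundary IC50 to the stronger level is the
single consistent rule.

Qualitative records carry a level but no `x`; where a numeric `b` is
needed (MS-loss targets, value-hinge margins, consolidated
qualitative-only groups) the level's representative threshold is
normalized instead, with thresholds {5: 100, 4: 500, 3: 1000, 2: 5000,
1: 5000} nM. For a positive level this is the band's *upper* IC50 bound,
i.e. the guaranteed lower bound on `b`; the negative level shares the
5000 nM boundary, used as an upper bound on `b`. Duplicated
(allele, peptide) measurements are consolidated by majority vote over
levels: a unique plurality wins, its `b` is the normalized mean of the
winning level's quantitative IC50s (threshold-derived when the winners are
all qualitative), and any tie marks the pair as conflicting and removes
it. The vote average deliberately uses quantitative members only:
threshold-imputed values are bounds, not measurements, and mixing them
into a mean would bias it toward band edges.

## Peptide representation

Residue encodings are 20-dim per component — the raw BLOSUM62 row (no
rescaling; any scale is absorbed by the first convolution and batch norm),
a one-hot indicator, and/or a learned 20×20 table — concatenated in the
declared order. Each position carries two learned `d_o`-dim vectors, one
indexed by the offset from the start of the string and one by the offset
from the opposite end, both from 15-row tables shared across lengths. The
dual indexing is what lets models generalize position information across
peptide lengths: "second residue" and "terminal residue" are consistent
features regardless of n. The input string is indexed left-to-right as
positions 1…n; the dual-end tables make the representation symmetric to
which terminus the data provider wrote first. Position tables are owned by
each allele's model, consistent with allele-specific training.

For global kernels, peptides are middle-padded to 15: the first and last
four residues keep terminal slots and the middle block is surrounded by
`floor(pads/2)` pad characters left and the remainder right
(`GGFVPNMLSV → GGFVXXPNXXXMLSV`). Pad slots are all-zero columns rather
than a learned pad embedding, and position vectors are omitted from the
padded matrix — the global kernel spans all 15 columns, so absolute
position is implicit in its weights.

## Architectures

ConvM: valid 1-D convolution (`d_r` kernels, width `k`) over the feature
matrix → batch normalization over channels → ReLU → self-attention pooling
(`d_a` hidden units, elementwise tanh) → fully-connected head. The head is
one hidden layer of width `d_r` with ReLU followed by a linear scalar; no
dropout anywhere. SpConvM adds `d_g` global kernels of shape d_e × 15,
each yielding one ReLU-activated scalar (no batch norm on this path), and
feeds the concatenated local–global vector to the same head. Models
trained with the MS loss pass the score through a sigmoid; the hinge
losses use the unbounded score, since their margin constants absorb scale.

Defaults: k = 1, d_r = 16, d_a = 8, d_o = 4, d_g = 8. These are modest
because per-allele data is small and the planted-signal studies in this
repository need minutes, not hours; every dimension is a constructor
argument.

All layers are NumPy with hand-written backpropagation; tests verify the
full gradient against central finite differences to 1e-4 relative error.
Batch normalization uses per-batch statistics (biased variance, eps 1e-5)
during training and running averages (momentum 0.1) in evaluation, so an
evaluation-mode score is independent of batch composition.

## Losses and pair construction

The value hinge `Hv`, level hinge `Hl` and constrained level hinge `Hi`
are as defined in the README; margins default to c = r = 0.2. For
qualitative entries the margin's `b` is the threshold-derived value — the
same convention the MS loss prescribes — because the hinge needs *some*
numeric affinity and the threshold is the only defensible one. Batch
aggregation is the arithmetic mean over pairs (entries for MS), keeping
gradient magnitude independent of batch size.

Training batches sample `batch_size` peptides without replacement and
draw ranking pairs uniformly from the valid pairs within the batch
(cross-level only for Hv/Hl, same-level allowed for Hi). The default is
eight pairs per batch peptide: with only one pair per peptide the
pair-sampled gradient is noisy enough that, at the fixed 0.05 initial
learning rate, validation loss fails to improve within the 5-epoch decay
patience during early training, the rate decays geometrically, and the
run stalls before the attention layer locks onto informative positions.
Eight pairs per peptide stabilize the gradient at negligible cost (pair
losses act in score space; each peptide is still scored once).

## Schedule

Plain SGD (no momentum, as specified by "stochastic gradient descent"
alone), initial learning rate 0.05. After every epoch the validation loss
(evaluation-mode, averaged over all valid validation pairs, or entries for
MS) is compared against the running best with a relative tolerance of
1e-4 — improvements smaller than float jitter do not reset patience. Five
stale epochs decay the rate by 10% (again at 10, 15, …); twenty stale
epochs stop training; the parameters of the best-validation epoch are
returned. The validation split (10% by default) is disjoint from training,
and cross-validation folds are split by peptide so no peptide appears on
both sides of any boundary.

A known property of this fixed schedule at small data sizes: training has
a two-stage character — convolution features must first become
discriminative before the attention layer gains signal to concentrate —
and on datasets of a few hundred peptides the validation loss can wander
within the patience window long enough for the decay to strangle the run
in the pre-convergence plateau. At the study scale used here (2000
peptides per allele) the schedule converges for the large majority of
seeds; occasional stalled replicates are the reason the recovery
assertions are phrased over multiple seeds.

## Evaluation

AR_h and HR_h are computed over the promising set P_h = {IC50 < h nM}
(h = 100 and 500); ranks are 1-based with 1 the highest score, ties broken
by input order with a warning since the definitions presume a total order.
AUC is the strict pairwise win rate over positive × negative pairs at the
500 nM threshold, and ROC_t counts wins against only the t top-scoring
negatives, normalized by |P₅₀₀|·t; ties earn no credit in either (the
strict indicator as printed — all-tied scores give 0, not 0.5). The hybrid
selection metric is

    H(Y) = Σ_mtrc I(↓mtrc) · (mtrc(Y) − best(mtrc)) / best(mtrc)

with I = +1 for the AR metrics (smaller better) and −1 otherwise, and
`best` the best-performing value over the grid — the minimum for AR
metrics, the maximum for the rest. Reading `best` as a plain maximum for
all metrics would make H negative for configurations *better* than the
best on AR, contradicting its role as a nonnegative regret minimized at 0;
the best-performing reading is the only self-consistent one, and is what
is implemented. Metrics whose preconditions fail (single-class folds,
empty promising sets, too few negatives) raise an undefined-metric signal
and surface as NaN in report tables.

## Attention-motif analysis

With k = 1 the attention weights are per-residue. Summing them by
(amino acid, position) over a peptide set gives
`SMM_l(a, j) = Σ_p 1(a at j) · w_j(p)`, comparable to an SMM scoring
matrix after a sign flip (SMM entries are energy-like: smaller means
preferred). Mixed-length sets can be pooled in the middle-padded 15-slot
frame; single-length analyses use the raw frame. The matrix is computed
over the *promising* peptides (IC50 < 500 nM): among strong binders the
residues occupying anchor positions are exactly the preferred ones, so
attended counts encode the motif. Over all peptides the anchor columns
would accumulate near-uniform residue counts and carry position
information only.

## Synthetic data

The generator emulates an IEDB-style per-allele table: peptides uniform
over the 20-letter alphabet with lengths 8–15 (mode at 9–11, matching the
empirical length distribution of class-I binding data), a planted 20 × 15
scoring profile with nonzero entries only in the anchor columns (position
2 and the terminal slot; the terminal residue of any length reads column
15), Gaussian noise on the normalized-affinity scale (default sd 0.05), a
qualitative fraction (default 0.2) and a conflict-injection rate (default
0.05, emitted as an unresolvable two-way level vote so consolidation must
drop the pair). The profile score is affinely calibrated per dataset so
that ~30% of peptides fall below 500 nM, keeping both AUC classes
populated; IC50s are emitted through the exact inverse of the
normalization, so the round trip recovers the true `b` wherever unclamped.
The anchor-recovery study conditions are 2000 peptides, noise 0.05, and a
clean table (no qualitative entries or conflicts).

What the generator does not emulate: real allele motifs (anchor residue
preferences are random draws, not biological), sequence composition bias,
inter-allele sharing, or mass-spectrometry-style decoy imbalance. Passing
recovery tests therefore demonstrates that the architecture and losses
can find planted position-specific signal under realistic noise and data
mixing — not that any particular real allele is predicted well.

## Problem sizes and runtime

The reference study trains on 1600 peptides (400 held out) for up to 300
epochs; one replicate takes well under a minute on one CPU. The acceptance
script aggregates three replicates by the median, damping the occasional
stalled-schedule seed. Cross-validated grid search is quadratic in nothing
worse than |grid| × folds trainings and is exercised in tests with small
grids.

## Known limitations

* The MS baseline under the fixed 0.05-lr schedule plateaus at this data
  scale (held-out AUC ≈ 0.6 vs ≈ 0.98 for the value hinge on identical
  data); the hinge objectives' larger early gradients are what carry them
  through the schedule. Comparisons between losses at this scale chiefly
  reflect that interaction.
* Scores of different alleles' models are not calibrated against each
  other; only within-allele order is meaningful.
* Tie handling in ranks is deterministic but arbitrary (input order);
  metrics on heavily tied score vectors should be interpreted with care.
* The NumPy implementation is single-threaded and CPU-oriented; it is
  sized for per-allele datasets (10²–10⁴ peptides), not proteome-scale
  scans.
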