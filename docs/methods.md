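# Methods

## Problem setting

Each subject is observed as one ROI time-series matrix per
brain-parcellation scale (t time points × n ROIs; by default t = 175
with a 200-ROI fine scale and a 116-ROI coarse scale). The task is
binary graph-level classification: build a functional-connectivity
network (FCN) per subject per scale and predict the subject's class
from the multi-scale bundle.

## Connectivity construction

* **Pearson** (default): edge weight e_ij is the correlation of the two
  ROI signals; the diagonal is 1 and entries lie in [−1, 1]. The node
  feature matrix X keeps the signed correlations (row i is ROI i's
  profile), while the adjacency takes magnitudes, A = |X|: positive and
  negative coupling are treated as equally strong connections, which
  keeps the adjacency non-negative as the graph convolution assumes.
* **Sparse representation**: each z-scored ROI signal is regressed on
  all the others under an L1 penalty, `min_w ½‖s_i − S_{−i}w‖² +
  λ‖w‖₁`, solved by cyclic coordinate descent (tolerance 1e-6, 1000
  iterations; failure to converge is an error naming the ROI). The
  coefficient matrix is symmetrized as (|W| + |Wᵀ|)/2, so the result is
  non-negative with zero diagonal and grows sparser as λ grows.
* **Proportional thresholding**: keep the ⌈f·m⌉ largest upper-triangle
  entries by magnitude (m = n(n−1)/2), zero the rest, mirror to keep
  symmetry; the diagonal is untouched and f = 1 is the identity. Ties
  at the boundary are broken by (|weight| descending, row, column), so
  the operation is deterministic. Thresholding is applied per subject,
  to the connectivity *before* X and A are formed, so a zeroed edge
  vanishes from features and adjacency alike. Thresholding magnitudes
  rather than signed weights matches the strength reading of the
  adjacency; both choices were open and are fixed here once.

## Network architecture

Per scale, two graph-convolution layers with the self-looped symmetric
normalization Â = D̃^{−1/2}(A+I)D̃^{−1/2} (Â = I for an empty graph) and
ReLU activations, widths 32 and 32, no biases. The normalized form is
used inside both layers; writing the propagation with the raw self-looped
adjacency would let high-degree nodes dominate and is read here as
shorthand for the normalized operator. A readout concatenates the
node-wise mean and node-wise max of the embedding (mean block first),
giving 64 dimensions per scale. With K scales, block k is rescaled by
K·α_k (α ≥ 0, Σα = 1; equal weights leave blocks unchanged) and the
blocks are concatenated — 128 dimensions for two scales. The head has
three fully-connected ReLU layers and a 2-class softmax; widths are
(input, 32, 16) for fused inputs — 128→128→32→16→2 — and the narrower
64→64→16→8→2 for single-scale models. Dropout (0.5) acts after each
hidden dense layer at training time only; the convolution layers carry
no dropout. Handcrafted baselines share the head recipe with widths
316→316→32→16→2 and dropout 0.2, consuming degree centrality (node
strength), Onnela geometric-mean local clustering (weights rescaled by
the graph maximum; 0 for nodes with fewer than two neighbors), or
closeness centrality on inverse-weight shortest paths. Closeness uses
the Wasserman–Faust component-scaled form (r/(n−1))·(r/Σd), which
equals (n−1)/Σd on connected graphs and gives isolated nodes 0 —
avoiding infinities after aggressive thresholding. These weighted
definitions were otherwise open choices; all three are standard and
checkable against an independent graph library.

Weights are Glorot-uniform, drawn from a seeded generator; the forward,
backward and Adam steps are implemented in NumPy (the networks are
small enough that full-batch CPU training is fast, and the first-hop
product ÂX is constant per subject, so it is precomputed once).
Training tensors are float32; the algebraic operations default to
float64.

## Training and evaluation protocol

Full-batch Adam (learning rate 0.01, coupled L2 weight decay 1e-5,
β = 0.9/0.999), cross-entropy loss, 50 epochs. After each epoch the
validation accuracy is measured with dropout off; the retained
parameters are those of the best validation epoch, later epochs winning
ties. A non-finite loss aborts with diagnostics.

Splits are repeated random partitions with train = ⌊0.8n⌋,
validation = ⌊0.1n⌋, test = the remainder, unstratified. A repetition
whose train, validation or test set misses a class is redrawn; when a
part is too small to ever hold both classes (e.g. a one-subject
validation set), the requirement falls back to the training set only,
and the fallback is logged. All compared methods receive bit-identical
index sets. Metrics use positive class = 1: accuracy, recall,
precision, F1 from the confusion counts (precision and F1 are 0 when
their denominators vanish), and AUC as the midrank Mann–Whitney
statistic on the predicted class-1 probability, recorded as missing for
single-class test sets and excluded from the mean. Reported SDs are
sample SDs over repetitions (0 by convention for a single repetition).

Two ablations mirror the protocol: the edge-retention sweep rebuilds
graphs at retention fractions {1.0, 0.9, 0.8, 0.7, 0.6} and re-runs the
protocol on shared splits (no monotone trend is asserted — performance
need not degrade monotonically with sparsification), and the
fusion-ratio sweep varies the first scale's weight α over 0.1–0.9 with
the second receiving 1−α. The rescale-by-K·α_k fusion is one of several
possible ratio mechanisms; it is differentiable and reduces exactly to
plain concatenation at equal weights.

## Synthetic cohort generator

The generator emulates the statistical skeleton of a two-atlas rs-fMRI
cohort, not its physiology. Within a class, subjects' fine-scale series
are i.i.d. zero-mean multivariate normal draws; the base covariance is
a seeded random 10-factor correlation matrix, and class 1 adds a signed
perturbation of magnitude `effect_size` (default 0.6) on a seeded
random `effect_edge_fraction` (default 10 %) of off-diagonal entries.
Both covariances are projected to the positive-definite cone by
clipping eigenvalues at 1e-4 and re-symmetrizing — the simplest
reproducible projection. White observation noise (SD 0.25, small
against unit signal variance) is added per sample; signals are
zero-mean because Pearson correlation is scale- and location-invariant,
so amplitude heterogeneity would be invisible anyway. Coarse-scale
series are exact means of disjoint contiguous groups of fine ROIs
(seeded grouping, fixed per cohort) rather than independently
simulated: real atlas scales view the same underlying activity, and
this linkage gives the cross-scale redundancy-plus-complementarity that
multi-scale fusion exploits. All randomness descends from one root seed
through named substreams, so cohorts are bit-reproducible.

Two caveats follow from this design. First, an aggressive sparse
perturbation is far from positive definite, so the projection spreads
part of the effect onto unperturbed edges; the planted set still
carries clearly more between-class displacement, but the effect is not
surgically confined. Second, the generator omits autocorrelated noise,
hemodynamics, site effects and realistic atlas geometry — passing tests
demonstrate that the pipeline recovers planted covariance structure
under the stated model, not performance on real scanner data.

Default study conditions for the recovery checks: 200 subjects, 50/50
classes, effect 0.6 on 10 % of fine-scale edges, 20 protocol
repetitions — accuracy is essentially perfect there, while the
matching null cohort (effect 0) stays inside a 99 % binomial band
around chance. These sizes keep the full check within minutes on one
CPU while leaving the per-edge effect many times the sampling noise of
a 175-point correlation estimate.

## Numerical and degenerate-input conventions

Zero-variance (constant) ROI signals are a hard error naming the
column. Connectivity matrices must be symmetric to within 1e-10.
Softmax is computed with max-subtraction; cross-entropy clamps
probabilities at 1e-12. `effect_edge_fraction = 0` with a positive
effect size degenerates to a null cohort and warns. Model parameters
serialize to a single `.npz` with a format-version tag.

## Known limitations

* Training is full-batch; mini-batching across subjects is unnecessary
  at these sizes and unimplemented.
* All subjects at a scale must share the same ROI count.
* The GCN needs a reasonably strong effect to beat simple strength
  features at small sample sizes; with weak, diffuse effects the degree
  baseline can win, which is expected behavior of a 50-epoch
  small-sample deep model rather than a defect.
* Attention-based fusion and explicit spectral decompositions are out
  of scope; the convolution uses only the one-hop normalized operator.
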