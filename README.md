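# msgcn — multi-scale graph networks for functional-connectivity classification

`msgcn` classifies subjects from resting-state functional-connectivity
networks (FCNs) built at two (or more) brain-parcellation scales. It is
aimed at researchers studying connectome-based diagnosis — for example
separating autism-spectrum cases from controls using ROI time series
extracted with a coarse atlas (116 parcels) and a fine atlas (200
parcels) — and at methodologists who need a controlled synthetic test
bed for such pipelines.

## The model

For each subject and scale, the FCN edge weight between ROIs *i* and *j*
is the Pearson correlation of their BOLD time series,

    e_ij = (s_i − s̄_i)ᵀ(s_j − s̄_j) / ( ‖s_i − s̄_i‖ · ‖s_j − s̄_j‖ ),

giving the signed node-feature matrix `X` (row *i* = subject *i*'s
correlation profile) and the non-negative adjacency `A = |X|`.
Optionally the network is sparsified by proportional thresholding (keep
the top fraction of edges by |weight|), or built by sparse
representation (per-ROI lasso regression) instead of correlation.

Each scale's graph is encoded by a two-layer spectral graph convolution
with the self-looped symmetric normalization Â = D̃^{−1/2}(A + I)D̃^{−1/2}:

    f(X, A) = ReLU( Â · ReLU( Â X W⁽⁰⁾ ) · W⁽¹⁾ ),   W widths 32, 32

followed by a mean‖max readout over nodes (64 dimensions per scale).
The per-scale representations are fused by ratio-weighted concatenation
(equal weights by default; 128 dimensions for two scales) and classified
by three fully-connected ReLU layers (128, 32, 16) with dropout 0.5 and
a softmax output. Handcrafted baselines replace the learned encoder
with degree centrality, Onnela local clustering, or closeness
centrality per node, concatenated across scales (316 dimensions) into a
dense head (316, 32, 16, dropout 0.2). All networks train full-batch
with Adam (learning rate 0.01, L2 weight decay 1e-5, 50 epochs,
cross-entropy), keeping the best-validation-accuracy checkpoint.

Evaluation uses repeated random 80/10/10 splits; accuracy, recall,
precision, F1 and AUC are reported as mean ± SD over repetitions, with
every compared method consuming bit-identical splits.

## Worked example

```python
from msgcn import CohortSpec, generate_cohort, ConnectomeClassifier

cohort = generate_cohort(CohortSpec(n_subjects=60, seed=3))       # planted effect
model = ConnectomeClassifier.from_cohort(cohort, method="multiscale_gcn")
res = model.fit(reps=10, seed=3)
print(res.summary())
```

prints

```
Connectome classification protocol (multiscale_gcn)
  subjects: 60   repetitions: 10   seed: 3
  metric       mean      sd
  accuracy     1.000   0.000
  recall       1.000   0.000
  precision    1.000   0.000
  f1           1.000   0.000
  auc          1.000   0.000
```

The synthetic cohort plants a covariance perturbation of magnitude 0.6
on 10 % of the fine-scale ROI pairs of class 1, which is a strong,
cleanly separable effect — the protocol recovers it perfectly, while a
null cohort (`effect_size=0`) stays at chance. `res.metrics` is the
same table as a DataFrame, `res.records` holds one row per repetition,
and `res.plot_roc()` overlays the per-repetition ROC curves.

The same protocol runs from the shell:

```sh
msgcn simulate --subjects 60 --seed 3 --out cohort/
msgcn train --cohort cohort/ --method multiscale_gcn --reps 10 --seed 3 --out metrics.tsv
msgcn compare --cohort cohort/ --methods multiscale_gcn,gcn_coarse,dc --reps 10 --seed 3 --out-dir runs/
msgcn sweep --kind sparsity --cohort cohort/ --reps 10 --seed 3 --out sweep.tsv
```

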