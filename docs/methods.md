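# Methods

This note documents the models and procedures the package implements,
the parameter choices that matter, and the limits of what the synthetic
experiments demonstrate.

## Graph compilation

The input hierarchy is a DAG of child→parent pathway relations (the
Reactome relation-file dialect, distributed as `(parent, child)` rows and
flipped internally) plus a protein→pathway membership table. Compilation
proceeds as: (1) subset the DAG to the upward closure of the pathways the
supplied proteins map to; (2) attach a virtual output, one node per
class, to every root (out-degree 0 in the child→parent direction);
(3) traverse backwards from the output for `n_hidden` layers, assigning
each pathway to the layer given by its *shortest* distance from the
output; (4) pad pathways with no predecessor in the adjacent lower layer
with chains of one-in/one-out copy nodes down to the first hidden layer;
(5) remove pathways never reached within `n_hidden` steps; (6) connect
each protein to every first-hidden-layer node whose source pathway it
maps to.

Three points are interpretations the upstream description leaves open,
fixed here for reproducibility:

* **Single layer per pathway.** A pathway reachable at several depths is
  placed once, at its shortest backward distance. A consequence is that a
  DAG edge whose endpoints land in non-adjacent layers cannot exist in a
  strictly sequential network and is dropped; the child still reaches the
  output through its own layer position.
* **Copy chains for stranded nodes.** Besides true terminals, a pathway
  whose every child was assigned to a non-adjacent layer is also padded
  with a copy chain; afterwards any node without input support or a path
  to the output is pruned (iterated to a fixed point). Every surviving
  input→output path then has exactly `n_hidden + 1` edges, which the
  tests verify by explicit path enumeration.
* **All-levels membership.** Protein attachment assumes the mapping file
  lists memberships at every hierarchy level (Reactome "All_Levels"
  dialect); a flat lowest-level mapping can be expanded by ancestor
  closure with `expand_flat_mapping=True`, and the expansion is logged.

Node order within a layer is lexicographic by source id with copies after
originals, so serialized specs are byte-identical across runs.

## Network and training

Each interface applies `x W ⊙ M + b` (mask `M` from the graph), batch
normalization, tanh, then dropout. Normalization is placed before the
saturating activation — the stable default where the block order is
otherwise a free choice. A dense auxiliary head follows every hidden
layer; the prediction is the arithmetic mean of the per-head activated
outputs (logistic for one output unit, softmax for ≥ 2 classes, averaged
after activation). The mean is taken over the actual number of heads,
`N` for `N` hidden layers. The top hidden layer's head doubles as the
final output interface, so its weight count equals the root→output mask.

Masked entries are exactly zero at initialization, gradients are masked,
and the optimizer re-applies the mask after every step;
`assert_sparsity` verifies exact zeros at any point of training.

Training minimizes the cross-entropy of the averaged prediction with
Adam. Defaults (all configurable in `TrainConfig`):

| parameter | default | rationale |
|---|---|---|
| initial learning rate | 1e-3 | standard for these cohort sizes; 1e-2 suits shallow targeted panels |
| weight decay (L2, W/U only) | 1e-3 | regularization against small-n overfitting |
| dropout rate | 0.2 | unspecified upstream; common default |
| batch size | 32 | enough optimizer steps per epoch on cohorts of a few hundred samples |
| plateau schedule | factor 0.5, patience 10, min 1e-6 | conventional reduce-on-plateau |
| early stopping patience | 20 epochs | halting criterion; `max_epochs` = 1000 is a safety cap, not the intended stopper |
| k (cross-validation) | 3, stratified | stratification protects small imbalanced cohorts |

With a validation subset the plateau/stopping monitor is the validation
loss; without one (interpretation mode, fitting on the complete dataset
before attribution) it is the *eval-mode* training loss recomputed at
each epoch end — monitoring the dropout-noisy running loss instead makes
early stopping fire essentially at random. Best-so-far weights are
restored on stop. Preparation imputes missing values as 0 and then
standardizes each protein to mean 0 / variance 1; the scaler is fit on
the training fold by default (`paper_scaling=True` fits on the whole
dataset for strict replication of whole-cohort scaling).

## Attribution

Importances are computed with the DeepLIFT rescale rule against a
background sample set — the multiplier calculus Deep SHAP applies to
feed-forward networks. Linear pieces (masked linear maps, eval-mode
batch normalization, head maps) propagate multipliers exactly; each tanh
distributes its output difference in proportion to its input difference,
falling back to the local derivative when |Δ| < 1e-9. Attribution
explains the **head logits**: on the logit scale a linear model's
attribution is the exact Shapley value `w_i · x_i` (zero background), and
completeness `Σ attr = f(x) − E_bg(f)` holds to machine precision per
head and per layer. A node in layer `l` is attributed through every head
downstream of it and the per-head values are averaged, mirroring the
averaged prediction; multi-class models get one attribution channel per
class. The default background is the complete dataset.

Raw importance is `S_n` = mean over samples of |attribution|, per class
plus a class-mean column — the standard sign-free summary. Corrections:

* `log_subgraph` (default): `f(S_n) = S_n / max(1, ln N_SG_n)` with
  `N_SG_n` the size of the node's complete subgraph (all predecessors and
  successors, the node itself included — inclusion is harmless under the
  clamp and stated for reproducibility). The clamp avoids amplifying
  nodes with subgraphs smaller than e.
* `degree_threshold`: `S_n / d_tot_n` only where `d_tot_n > μ + 5σ`,
  with μ, σ computed over the total degrees of **all** nodes of the
  layered network (the simplest global reading; the scope is otherwise
  unspecified).
* `none`: identity.

Sankey export assigns each node an outgoing flow equal to its adjusted
importance, split across outgoing edges **proportionally to the target
nodes' adjusted importance** (equal split when all targets are zero).
Edge-level flows are not defined upstream; this proportional rule is one
consistent realization, and node-level flows are independent of it. The
top-k nodes per layer are labeled, the rest pool into an "Other
connections" node, and pooled-only links can be dropped for display.

## DE score, subgraphs, panels

Differential expression fits each protein by OLS on a group indicator —
computed as the algebraically identical pooled two-sample t-test —
over detected values only (imputed zeros would fabricate signal);
proteins with fewer than two detected values in a group are flagged with
undefined p. Multiple testing uses the two-stage Benjamini–Hochberg
step-up (statsmodels `fdr_tsbh`). The matrix is assumed log2 scale, so
the fold change is a difference of group means. The DE score uses
|log2 FC| (the volcano x-axis is symmetric; sign handling is otherwise
unspecified) and the natural log of p — any base cancels in the ratio.

Subgraph queries return the successor closure (downstream), predecessor
closure (upstream) or their union (complete) of an anchor node in the
layered graph, with adjusted importances attached and optional collapsing
of copy chains for display.

Panel evaluation selects the top-m proteins (default 20) by importance
or DE score, standardizes the abundances per protein (columns; scaling
rows instead is a documented alternative), Ward-clusters the samples on
Euclidean distances, cuts at k = number of classes, and reports the
unadjusted Rand index (the adjusted Rand index is emitted alongside,
clearly labeled).

## Synthetic data

The generator emulates a normalized log-scale protein matrix: a balanced
pathway tree (default 2 levels, branching 3) with a single root, proteins
dealt round-robin to the leaves, all-levels memberships; per-protein
baselines ~ N(12, 2) with per-sample noise SD 1 on the log scale; a
planted pathway shifts a chosen fraction of its proteins by δ SD in the
non-reference classes, before standardization. Missingness is
missing-at-random at a configurable rate, **default 0**: because the
pipeline imputes missing as 0 before standardization, a MAR-deleted
raw-scale entry becomes a ~7σ outlier, a distortion real DIA data does
not show (its missingness is abundance-dependent and low-signal, which
this generator deliberately does not model). The default study condition
is therefore a fully observed matrix; nonzero rates exercise the
detection mask and filtering paths.

What the synthetic experiments show: the compiled network learns a
planted 10-protein/1-pathway effect (δ = 2, n = 200) to near-perfect
3-fold ROC-AUC, recovers the planted pathway at the top of its layer by
adjusted importance across seeds, and stays at chance on null cohorts.
What they do not show: robustness to batch effects, abundance-dependent
missingness, correlated proteins within pathways, or realistic pathway
topologies with heavy fan-in — conclusions about real cohorts require
the real data.

## Numerical choices and limitations

* Zero-variance proteins standardize to zero (guarded divide).
* Batch-norm uses ε = 1e-5, running-stat momentum 0.1; batches of one
  sample are skipped (batch statistics are undefined).
* A non-finite training loss raises immediately with the epoch context.
* p-values are clipped at 1e-300 before logs in the DE score.
* Exact Shapley enumeration is out of scope; the rescale rule is the
  approximation, exact for linear chains.
* Parameter counts report weights and biases separately
  (`count_edges`), so either counting convention can be compared.
* The evaluation harness accepts class-probability matrices from any
  scorer (`classification_metrics`); re-implementations of reference
  classifiers (SVM, kNN, random forest, boosted trees) are not included.
* Figures-ready artifacts are data exports (Sankey JSON, TSV tables);
  no plotting code is shipped.
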