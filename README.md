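# oncograph

End-to-end graph-convolutional prediction of anticancer molecules from their
gene targets on a protein–protein interaction (PPI) network — with the
network-propagation baseline it is measured against, an integrated-gradients
interpretability layer, and a synthetic-data generator so the whole pipeline
runs and tests at desk scale with no downloads.

**Who it is for.** Computational biologists asking whether a molecule — an
approved drug, or a bioactive food constituent — acts on the genome the way
approved anticancer drugs do. Gene-target lists are sparse and cancer
genotypes heterogeneous, so raw target overlap is a poor similarity measure;
the signal lives in the *gene modules* (pathways) a molecule perturbs on the
interactome.

## The model

A molecule is a binary signal **x** ∈ {0,1}^|V| on a shared graph
G = (V, E) (x_j = 1 iff gene j is a target). K graph-convolution layers with
d = 8 hidden units learn how that signal spreads:

* GCN: H⁽ˡ⁺¹⁾ = σ(D̃^{-1/2} Ã D̃^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾), with Ã = A + I
* GraphSAGE (mean variant): Ĥ = D̃^{-1}Ã H⁽ˡ⁾W⁽ˡ⁾, rows L2-normalized
* ChebNet: σ(Σ_{n<N} Y_n W_n), Y_n the Chebyshev recursion in
  L̂ = 2L/λ_max − I, L = I − D^{-1/2}AD^{-1/2}

Layer outputs are concatenated (jumping knowledge) into Z, reduced by a
learned linear readout z = Z·W_fc (or pathway-pooled, ẑ = (P·Z)·W_fcp, with
P the binary pathway-membership matrix), and classified by a 2-layer MLP
with softmax. Training is end-to-end: class-weighted cross-entropy
(w_c = n/2n_c — positives are ~10% of drugs), Adam, batch size 16, ≤ 100
epochs, early stopping on validation loss (window 20, min delta 1e-4),
5-fold stratified cross-validation. Trained fold models are ensembled into
an **anticancer likeness** score for unlabeled molecules (mean predicted
probability; ≥ 0.9 flags a candidate).

The baseline is the two-stage alternative: random walk with restart
p ← (1−r)Wp + re produces an unsupervised diffusion profile per molecule,
then a class-weighted linear SVM classifies the profiles.

For interpretability, integrated gradients
a_j = (x_j − x′_j)·∫₀¹ ∂F(x′ + α(x − x′))/∂x_j dα attribute a prediction to
input genes against the zero-target baseline x′; attribution rankings are
tested for pathway over-representation with an in-repo preranked enrichment
(running-sum statistic, permutation null, FDR), and the **attribution recall
score** is the fraction of cancer-flagged pathways recovered at FDR 25%.

The neural layers and their gradients are implemented directly in
NumPy/SciPy (models this size need nothing more) and are verified against
dense linear-algebra and spectral oracles in the test suite.

## Worked example

```python
import dataclasses
from oncograph import (SyntheticConfig, generate_all, build_spectral_operators,
                       stratified_splits, train_model, TrainingConfig, init_model)
from oncograph.attribution import (average_positive_attributions,
                                   preranked_enrichment, attribution_recall)

cfg = SyntheticConfig(n_genes=300, n_drugs=400, seed=1)   # ~10% positives
graph, pathways, drugs, foods, _ = generate_all(cfg)
ops = build_spectral_operators(graph)
plan = stratified_splits(drugs.labels, k=5, seed=1)

arch = init_model(n_nodes=graph.n_genes, kind="cheb", n_conv_layers=2,
                  cheb_n=4, dropout_layers=2, seed=11, gene_ids=graph.gene_ids)
result = train_model(drugs, ops, arch, TrainingConfig(seed=11), plan.folds[0])
m = result.metrics
print(f"fold 0: AUPR {m.aupr:.1f}%  F1 {m.f1_positive:.1f}%  "
      f"balanced accuracy {m.balanced_accuracy:.1f}%  "
      f"(stopped at epoch {result.stop_epoch})")

single = dataclasses.replace(plan, folds=[plan.folds[0]])
ranking = average_positive_attributions([result.model], drugs, ops, single,
                                        graph.gene_ids, steps=64)
enrich = preranked_enrichment(ranking, pathways, weight_exp=0.0,
                              n_perm=500, seed=1, gene_ids=graph.gene_ids)
print(f"attribution recall at FDR 25%: "
      f"{attribution_recall(enrich, pathways, fdr_threshold=0.25):.2f}")
```

prints

```
fold 0: AUPR 98.0%  F1 81.8%  balanced accuracy 97.2%  (stopped at epoch 36)
attribution recall at FDR 25%: 1.00
```

AUPR is area under the precision–recall curve (average precision), the
headline metric for a 10:1-imbalanced task; the recall of 1.00 says all four
planted cancer pathways are significantly enriched among the genes the
trained model attributes its anticancer calls to — i.e. the model makes its
decisions from the planted mechanism, not from target counts.

The same steps are available from the shell on the emitted text formats
(edge-list TSV, GMT, target/label TSVs):

```
oncograph synth --out data --seed 1
oncograph train --graph data/edges.tsv --targets data/targets.tsv \
    --labels data/labels.tsv --layer cheb --k 2 --out models
oncograph predict --models models --graph data/edges.tsv --foods data/targets.tsv
oncograph attribute --models models --graph data/edges.tsv \
    --targets data/targets.tsv --labels data/labels.tsv \
    --gmt data/pathways.gmt --flags data/cancer_flags.tsv --out attr
oncograph baseline --graph data/edges.tsv --targets data/targets.tsv \
    --labels data/labels.tsv --out rwr
```

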