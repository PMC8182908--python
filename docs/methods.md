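# Methods

## Problem and model

Every molecule (an approved drug or a food constituent) is encoded as a
binary signal **x** ∈ {0,1}^|V| on one shared protein–protein interaction
graph G = (V, E): gene j carries a 1 iff the molecule targets its protein.
Anticancer prediction is graph classification: the label says whether the
drug is approved against cancer, and the model must decide from where on the
interactome the molecule acts, not merely from how many genes it touches.

The classifier stacks K graph-convolution layers (d = 8 hidden units each,
no bias, ReLU), concatenates all layer outputs per node (jumping knowledge),
reduces the |V| × (d₁+…+d_K) representation with a learned linear readout —
either per node, z = Z·W_fc, or per pathway after pooling with the fixed
binary membership matrix P, ẑ = (P·Z)·W_fcp — and classifies with a 2-layer
MLP (32 hidden units, softmax over two classes). Three convolution operators
are supported:

* **GCN** — H⁽ˡ⁺¹⁾ = σ(D̃^{-1/2} Ã D̃^{-1/2} H⁽ˡ⁾ W⁽ˡ⁾), Ã = A + I, D̃ its
  degree matrix;
* **GraphSAGE** (GCN-style mean aggregator) — Ĥ = D̃^{-1} Ã H⁽ˡ⁾ W⁽ˡ⁾
  followed by row-wise L2 normalization, σ applied after; rows with norm
  < 1e-12 pass through as zero (the continuous limit — the quotient is
  undefined there);
* **ChebNet** — σ(Σ_{n<N} Y_n W_n) with Y₀ = H, Y₁ = L̂H,
  Y_n = 2L̂Y_{n-1} − Y_{n-2}, where L̂ = 2L/λ_max − I and
  L = I − D^{-1/2} A D^{-1/2}. Degrees for L intentionally come from A
  *without* self-loops and degrees for the GCN/SAGE operators from Ã *with*
  them; each formula is followed literally. λ_max is computed by dense
  eigendecomposition up to |V| = 2000 and by power iteration (tol 1e-7,
  ≤ 10 000 iterations) above; a `fixed2` mode assumes the normalized-Laplacian
  upper bound λ_max = 2.

All layers, backpropagation, Adam (β = 0.9/0.999) and the input gradients
needed for attribution are implemented directly in NumPy/SciPy; at d = 8 and
K ≤ 3 the models are small enough that a tensor framework would add nothing
but a dependency. Gradients are verified against central finite differences
in the test suite's oracles, and each layer against a dense linear-algebra
oracle (for ChebNet, the spectral definition Y_n = T_n(L̂)·H).

Node order is lexicographic on gene identifier everywhere — matrices,
signals, checkpoints (which record the gene list and refuse mismatched
graphs) — so runs and I/O round-trips are deterministic.

## Training protocol

Class-weighted cross-entropy (w_c = n/(2n_c), per-sample weighting rather
than resampling), Adam with L2 weight decay on weight matrices only, batch
size 16, at most 100 epochs, early stopping when the validation loss fails
to improve by ≥ 1e-4 for 20 consecutive epochs, with best-validation weights
restored. Validation loss uses the same class weights as training (one
objective throughout). Splits are 5-fold stratified cross-validation: per
class, indices are shuffled by the seed and dealt round-robin into test
folds (20% each); 10% of each fold's remainder, stratified, forms the
validation set. One master seed fans out to split, init and batch-shuffle
streams.

Two choices the layer equations leave open are made explicit: batch
normalization (when enabled) acts on pre-activation node features with
statistics over the batch × node axes; dropout (rate 0.5) is applied after
the MLP's hidden ReLU (1 layer) and additionally to the readout vector
(2 layers). "Feature normalization" divides x by max(1, Σx), the natural
per-molecule scaling for an indicator signal. ChebNet's filter size N is
the number of polynomial terms (its "n-hops" values 2/4/6 map to N).
Weight init is seeded Glorot uniform.

Because the input has a single channel (d₀ = 1), first-layer Glorot draws
are high-variance and occasionally kill most ReLU paths. The benchmark
protocol therefore trains each fold from 3 seeded restarts and keeps the one
with the lowest validation loss — the selection never sees test data. For
the same reason hyperparameters (learning rate 5e-4/5e-3, 1 or 2 dropout
layers at desk scale; the full grid mirrors the searched space including L2,
depth, normalizations) are selected on the validation split; per-fold and
global (select-on-first-fold) modes are both available.

## Baseline and ablations

The comparison method is unsupervised network propagation followed by a
supervised classifier: random walk with restart, p ← (1−r)·W·p + r·e with W
the column-normalized adjacency (no self-loops by default; row normalization
and self-loops behind flags) and e the uniform distribution over the
molecule's targets. The update rule is the standard restart iteration; the
fixed point equals r(I − (1−r)W)^{-1}e, which the tests verify. The restart
probability is selected on validation AUPR over
[0.001, 0.01, 0.1, 0.2, …, 0.9], the classifier is a class-weight-balanced
linear SVM with C ∈ {0.01, 0.1, 1, 10} selected the same way. No-propagation
ablations: raw x into the linear SVM, and raw x into a 32-unit MLP
(scikit-learn's implementation; it is an ordinary dense model, not part of
the contribution).

## Attribution and the recall score

Integrated gradients attribute the anticancer probability F(x) along the
straight path from the all-zero baseline (no targets) to x, with the binary
indicators relaxed to [0,1] on the path. The integral uses the trapezoid
rule (default 128 steps; exact for linear F at any steps ≥ 2, and halving
the quadrature bias of a left Riemann sum at equal cost). The sensitivity
axiom holds exactly — a_j = 0 wherever x_j equals the baseline — and the
completeness axiom (Σa → F(x) − F(x′)) is tested to < 1 % at 256 steps.

Attribution vectors of held-out molecules each fold's model classifies as
anticancer (argmax) are averaged within and then across folds, and the
resulting gene ranking is tested for pathway over-representation with an
in-repo preranked enrichment: the classical Kolmogorov–Smirnov running sum,
a seeded gene-permutation null (default 1000 draws), sign-matched normalized
scores and FDR q-values. The **attribution recall score** is the fraction of
cancer-flagged pathways that are positively enriched at q < 0.25.

One deliberate deviation from the usual weighted statistic: IG's sensitivity
axiom makes every non-target gene score *exactly* zero, so at desk scale the
ranking is zero-inflated and the score-weighted running sum (weight
exponent 1) saturates — any gene set touching the nonzero head reaches
|ES| ≈ 1 and the permutation p-value carries no information. The recall
workflow therefore defaults to the unweighted statistic (weight exponent 0),
which stays calibrated for sparse rankings; the weighted form remains the
per-operation default and both are exposed. The null-calibration test
(nominal p uniform under random scores) covers the statistic actually used.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the structural features the method relies on, at a
size that trains in seconds: a connected preferential-attachment interactome
(heavy-tailed degrees; a stochastic block model is available for
planted-module work), pathways covering ~30 % of genes (matching the real
annotation's partial coverage), a group of mutually overlapping
cancer-flagged pathways grown as one graph-local module around a high-degree
seed (shared 50 % core), ~10.2 % positive drugs, and target placement:
each of a molecule's Poisson-distributed targets (mean 5, truncated ≥ 1,
one resample on zero) falls into the cancer-gene pool with probability
p_cancer_target for positives (0.6 by default) and p_background (0.02) for
negatives and background foods. Food molecules mix the two mechanisms; the
generating mechanism is recorded as ground truth for ranking evaluation
only. Everything is deterministic given (config, seed) down to the emitted
bytes.

What passing tests on this generator show: the layers, training loop,
propagation baseline, attribution and enrichment machinery recover a planted
modular signal end-to-end. What they do not show: performance on real
interactome data. Two desk-scale caveats matter. First, under this
placement mechanism the label's log-odds are *linear* in x, so a linear
classifier on raw targets is already near Bayes-optimal and graph
convolution has no structural advantage to exploit — on real data the
advantage claimed for spectral convolution rests on correlations this
generator does not simulate. Second, with ~8 test positives per fold,
fold-level metric variance is large; benchmark numbers are reported as
means over 5 folds and 3 seeds and still carry ~±10 pp of spread.

## Numerical choices and degenerate inputs

Cross-entropy clamps probabilities at 1e-12. RWR raises on zero-target
molecules (no seed distribution) and on non-convergence (L1 change < 1e-8,
≤ 10 000 iterations). Zero-target molecules are allowed by the readers
(flagged with a warning) and dropped by the benchmark before profiling.
Pathways with fewer than 3 members in a ranking are skipped with a warning.
Ties in attribution rankings break by gene id; equal validation losses in
the grid break toward higher validation AUPR, then grid order. Connected
components tie-break to the component containing the lexicographically
smallest gene id. Edge weights are binarized on input unless explicitly
kept.

## Benchmark problem sizes

The reproduction script runs, per seed: the generator at 300 genes /
400 drugs / 24 pathways (4 cancer-flagged), a 2×2 hyperparameter grid on
the first fold, 5 folds × 3 restarts of ChebNet (K = 2, N = 4, d = 8), the
three baselines on the same folds, and attribution with 64 IG steps and
500 permutations — about 3 minutes per seed on one CPU, three seeds in
total. These sizes are the package's desk-scale defaults; all of them are
configurable.

## Known limitations

No GPU path, no sparse-minibatch engineering beyond what |V| ≈ 15k needs
(operators are scipy.sparse; dense eigendecomposition is avoided above
2000 nodes), no attention/learnable pooling, no identifier mapping for real
STRING/DrugBank inputs, and no attempt to match real interactome topology
beyond heavy-tailed degrees.
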