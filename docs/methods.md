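# Methods

`citecca` clusters paired single-cell count data — CITE-seq RNA + surface
protein (ADT) by default — by learning one latent space per omics with a
count-likelihood autoencoder, coupling the two spaces with a canonical
correlation objective, fusing them with learned convex weights, and carving
the fused space into clusters with a Cauchy–Schwarz (CS) divergence head.

## Model

**Inputs.** Raw count matrices `X_rna` (cells × genes) and `X_protein`
(cells × proteins) over the same cells.  Encoder inputs are gene-wise
z-scored `log1p` of size-factor-normalised counts; the likelihoods always
see the raw counts.  Size factors are per-cell library size divided by the
per-omics median library size, so the median size factor is 1.

**Autoencoders.** Each omics has an MLP encoder to a shared latent
dimension d and a mirrored decoder ending in parallel heads that
parameterise a count distribution per cell and feature:

* RNA: zero-inflated negative binomial (ZINB) with mean
  `mu = size_factor * exp(clamped linear head)`, dispersion
  `theta = clamped softplus`, and dropout weight `pi = sigmoid`.  The
  zero-inflation mass models technical dropout zeros.
* Protein: negative binomial (NB) — ADT counts are denser and need no
  zero inflation.  A configuration switch (`protein_likelihood="zinb"`)
  turns the second branch into a ZINB too, for paired
  transcriptome–chromatin assays (SNARE/SHARE-style) where both modalities
  are sparse.

The autoencoder loss `L_AE` is the sum over omics of the mean-per-cell
negative log-likelihood (features summed).  Likelihoods are evaluated
through log-gamma functions; mean and dispersion activations are clamped
(`mu` pre-factor in [1e-5, 1e6], `theta` in [1e-4, 1e4], `pi` in
(1e-6, 1-1e-6)) so the objective stays finite for any latent.

**CCA coupling.** With latents stacked as d × n views `H_r`, `H_p`,
covariances are estimated with ridge regularisers `r1 = r2 = 1e-3`
(configurable), and the total canonical correlation is the trace (nuclear)
norm of `T = S11^{-1/2} S12 S22^{-1/2}`, computed from the eigenvalues of
`T'T` with an eigenvalue floor of 1e-12 before the square root.  An
optional `cca_top_k` sums only the largest k singular values, a remedy for
the numerical instability the full spectrum can exhibit; the default uses
all components.  The correlation is *maximised*: the training objective
subtracts it (`- delta * L_cca`), and logs report the positive correlation
value.

**Fusion.** `z = w_rna * z_rna + w_protein * z_protein` with
`(w_rna, w_protein) = softmax(two free logits)`, so the weights stay on the
simplex after every optimizer step.  The fused latent feeds only the
clustering head, hence the fusion logits receive gradients exclusively from
the clustering terms — they track how much each omics contributes to the
clustering objective, not to reconstruction.

**Clustering head.** A linear layer (width 100) with batch normalisation
(no affine; running statistics at inference) and ReLU produces the hidden
features `h` used by the Gaussian kernel
`K_ij = exp(-||h_i - h_j||^2 / 2 sigma^2)`; a softmax layer on top yields
the n × K soft assignment matrix A.  Three terms drive clustering:

* `L1` — the sample-based CS divergence between cluster "densities":
  `(1/K) * sum_{i<j} (a_i' K a_j) / sqrt((a_i' K a_i)(a_j' K a_j))` over
  column pairs of A.  Each summand is a kernel cosine similarity, hence in
  [0, 1] by the Cauchy–Schwarz inequality on a PSD kernel, bounding L1 by
  (K-1)/2.  Minimising it separates and compacts clusters.
* `L2` — the same functional applied to `m_{a,j} = exp(-||alpha_a - e_j||)`
  (unsquared Euclidean distance from each assignment row to each simplex
  corner), pulling assignments toward one-hot vectors.  A config flag can
  square the norm for ablation.
* `L3` — the sum of strictly-upper-triangular entries of `A'A`, divided by
  the batch size so the value is batch-size-free (the raw sum is available
  via `l3_normalize=False`); it pushes assignment vectors of different
  cells toward orthogonality.

The kernel bandwidth is relative: `sigma = sigma_rel * median pairwise
distance` within the batch (default `sigma_rel = 0.15`), recomputed each
step with no gradient through sigma, with a floor of 1e-6 when all points
coincide.  A relative bandwidth makes the "adequate interval" for sigma
scale-free.  The kernel can alternatively be computed on the fused latent
itself (`kernel_on="fused"`).

**Total objective.** `gamma * L_AE - delta * L_cca + (L1 + L2 + L3)` with
defaults `gamma = 1`, `delta = 0.1`.  Performance is insensitive to gamma
over a wide range because Adam normalises per-parameter gradient scales.

## Training schedule

1. **Pretraining** (default 120 epochs, Adam, lr 1e-3, batch 256): L_AE
   alone.  This is where the latents acquire cluster structure; on the
   simulated designs below, k-means on the fused latent typically reaches
   ARI ≈ 1 after pretraining.
2. **Head warm-up with restarts** (default 4 restarts × 40 epochs at
   3× learning rate): encoders frozen (their latents are precomputed), only
   the clustering head and fusion logits train on L1+L2+L3.  The restart
   with the lowest full-data clustering loss is kept and polished for
   another 40 head-only epochs.  CS-divergence clustering is decentralized
   — there are no cluster centroids to initialise — so restart selection by
   the unsupervised training loss is the natural defence against
   merged-cluster local optima; in our runs the loss ranks restarts in the
   same order as their (unseen) ARI.
3. **Joint phase** (default 60 epochs): the full objective over all
   parameters.  `delta` ramps linearly over the first 10 joint epochs so
   the CCA term never acts on unsettled latents.  The CCA and kernel terms
   are computed per minibatch; batches smaller than `2 d` cells are skipped
   so covariance estimates stay well-conditioned.

All randomness (initialisation, batch order, restarts) derives from the
single `seed`; runs are bit-reproducible at fixed thread counts.  Model
parameters are float32 — the pipeline is matmul-bound on CPU and single
precision halves the cost; likelihood evaluation upcasts to float64 where
the raw counts enter.

### Architecture defaults and why

RNA encoder widths (256, 64), protein encoder (64, 32), shared latent
d = 16, ELU activations; decoders mirror the encoders.  d = 16 concentrates
the cluster signal: with wider latents the autoencoder keeps more
non-cluster variance and the kernel's pairwise contrast between
within-cluster and between-cluster distances degrades.  The protein encoder
is wider than its 75-dimensional input strictly needs because the NB branch
converges slowly with a narrow bottleneck.  The head width (100) with batch
norm + ReLU follows the standard construction of divergence-based deep
clustering.  All of these are `ModelConfig` fields.

## Synthetic data generator

`sim.simulate_cite` emulates the Splatter family of gamma-Poisson
simulators for paired modalities:

* base feature means ~ Gamma(shape 0.6, rate 0.3);
* per cluster, each feature is differentially expressed with probability
  `de_prob` (independently per omics); DE features get a log-normal factor
  (location 0.5, scale 0.4), up- or down-regulated with equal probability;
* cluster profiles are normalised to proportions and scaled by per-cell
  log-normal library sizes (RNA location 9.0/scale 0.25, protein 8.0/0.2 —
  protein libraries are relatively larger per feature, making ADT counts
  dense);
* counts are gamma-Poisson (NB) with per-omics dispersion (RNA theta 2,
  protein theta 4);
* RNA counts are additionally thinned by a Bernoulli dropout with
  probability `logistic(-shape * (log mu - midpoint))` — low-expression
  genes lose counts preferentially, producing zero inflation; proteins get
  no dropout.

The default design mirrors the simulation study this package targets:
equal-size clusters, 2500 genes, 75 proteins, DE probability 0.15 for RNA
and 0.7 for protein — the protein panel is the more informative modality,
and the learned fusion weights reflect that.  What the generator does *not*
emulate: batch effects, doublets, ambient contamination, mean-variance
trends fitted from real data, or Splatter's exact RNG streams.  Passing
tests on these simulations therefore demonstrate correctness of the method
under its own generative assumptions, not performance on any real tissue.

## Evaluation and cluster-number selection

ARI and NMI wrap scikit-learn (the test suite cross-checks them against
textbook contingency/entropy formulas).  `select_k` pretrains with L_AE
only, standardises the fused latent, runs k-means (greedy k-means++, fixed
per-repeat seeds, best SSE of `repeats` restarts, monotone envelope over K)
for each candidate K, and picks the K with the largest second-order forward
difference of the SSE curve.  Elbow strength is that curvature divided by
the curve's mean slope; below 1.0 the curve is declared elbow-free (a
warning, `has_elbow=False`) and the smallest candidate is returned.  The
"inflection point" rule is verbal in the literature; the second-difference
detector and its threshold are this package's own operationalisation.

## Scales used by the shipped checks

The acceptance script and end-to-end tests run the cluster-number
experiment at desk scale — 150 cells/cluster and 800 genes (K ∈ {4, 8},
three seeds each) instead of 500 cells/cluster and 2500 genes — and the
remaining behavioural checks (fusion-weight tracking, K selection,
determinism) at a few hundred cells.  These sizes keep a full run on one
CPU core in minutes while leaving the conclusions unchanged at the larger
design in spot checks.

## Known limitations

* The CS clustering terms operate on a single global kernel bandwidth;
  strongly anisotropic latents or clusters of very different spread can
  still merge (visible as occasional ARI ≈ 0.85 runs at K = 8).  More
  restarts or a larger `sigma_rel` help.
* The trace-norm CCA backward pass regularises eigenvalue gaps; nearly
  degenerate canonical correlations produce small but biased gradients.
  `cca_top_k` is the documented escape hatch.
* Mini-batch CCA estimates are biased for batches not much larger than the
  latent dimension; the trainer enforces batch ≥ 2d.
* `select_k` inherits the elbow method's coarseness: candidate ranges much
  wider than the true K, or unequal cluster separations, can shift the
  detected bend by one.
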