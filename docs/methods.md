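# Methods

## Generative view and model structure

The model treats an observed count Xᵢⱼ as the outcome of three stacked
processes: a biological mean expression μᵢⱼ produced by a small number of
latent expression programs, negative-binomial (Gamma–Poisson) sampling
around that mean driven by transcriptional bursting, and a technical
dropout event that replaces the draw with zero. Depth differences between
cells act multiplicatively at the observation layer (Poisson thinning), so
they are factored out with size factors sᵢ = rowsumᵢ / median(rowsums)
rather than entangled with μ. Cells with a zero row sum make sᵢ = 0 and the
reconstruction degenerate, so the loaders reject them outright with the
offending cell named — failing fast was preferred over propagating NaNs.

The biological mean is μ = W⁺H⁺ with W⁺ row-stochastic (each cell is a
probability mixture over k modules) and H⁺ ≥ 0 (module expression
profiles). Supervision enters by linear shrinkage: labeled rows of W⁺ are
the equal-weight average of the one-hot label encoding and the softmax of
ReLU(W), and H⁺ is the average of ReLU(H) with prototype profiles H_prior
computed as raw-count means per labeled type. Unlabeled cells fall back to
the pure softmax row and are excluded from the classification loss and from
the prototype means, so partial labels degrade gracefully toward the
unsupervised model. H_prior is computed on raw counts exactly as the
prototype-mean definition is written, without depth normalization; with
strongly unbalanced depths across types this biases prototypes toward
deeper cells, a known trade-off of taking the definition literally.

When k exceeds the number of labeled types C, the extra "anonymous"
modules get zero columns in P and global-mean rows in H_prior; k < C is a
configuration error.

### Dropout and dispersion parameterization

The dropout probability is one free logit per gene, πⱼ = σ(ρⱼ), broadcast
over cells. Dropout propensity in real data is predominantly gene-driven
(a function of expression level and transcript capture efficiency), and a
per-gene parameterization keeps the parameter count at O(m) rather than
O(nm). Dispersion is a single shared scalar θ = softplus(θ_raw) + 10⁻⁴;
the floor prevents the NB likelihood from degenerating as θ → 0.

### Batch correction

The per-(gene, batch) factor κ is estimated by moments before training —
the log of the batch's mean depth-normalized expression per gene, centered
per gene across batches so that κ has unit geometric mean (the
identifiability constraint) — and held fixed. The trainable set is
{W, H, ρ, θ_raw, w_c, b}; folding κ into it would make the batch factors
compete with H⁺ for the same variance on small data.

## The four loss terms

* **Reconstruction**: ‖X − μ̂‖_F / (nm), the Frobenius *norm* (not its
  square) divided by the entry count. μ̂ is the depth-adjusted mean
  sᵢκμᵢⱼ so the comparison happens on the observation scale.
* **ZINB likelihood**: mean negative log-likelihood of
  ZINB(x; μ̂, θ, π). The likelihood mean is also the depth-adjusted μ̂ —
  the likelihood compares against observed counts, and thinning places
  capture effects at the observation layer. Means are clipped below at
  10⁻⁸ (ReLU can output exact zeros, where the ZINB is undefined); the
  zero branch is a log-sum-exp of the inflation mass and the NB zero
  probability, and the positive branch uses log-Gamma functions.
* **z-score consistency**: mean squared difference between per-cell
  standardized rows of X and of μ̂, with the population standard deviation
  (divisor m) and ε = 10⁻⁸ guarding constant rows. Because the z-score is
  per row, per-cell scale factors cancel: the term constrains each cell's
  *relative* expression shape. On data that were already normalized per
  cell this term is largely redundant and can be switched off.
* **Classification**: cross-entropy of a linear probe
  softmax(W⁺ᵢ w_c + b) averaged over labeled cells. The probe both tests
  and enforces that cell identity is linearly decodable from the module
  mixture, eliminating degenerate factorizations that reconstruct well but
  scramble identity.

Each weight λ is a binary switch in {0, 1}; fractional weights are
rejected, matching the definition of the switches. The total is the
switched sum; gradients of switched-off terms are not accumulated, so
parameters unique to a disabled term (the probe, when λ_class = 0) are
provably untouched by training.

## Optimization

All gradients are derived analytically (chain rule through the softmax,
ReLU masks, the ZINB branches and the z-score normalization) and verified
against central finite differences at relative error < 10⁻⁴ in the test
suite; Adam (β₁ = 0.9, β₂ = 0.999, ε_adam = 10⁻⁸) takes full-batch steps
with the step-decayed rate η_t = η₀ γ^⌊t/T⌋. Training stops when the
relative change of the total loss stays below ε_loss for `patience`
consecutive epochs, or at `max_epochs`. Defaults: η₀ = 0.01, γ = 0.95,
T = 200, ε_loss = 0.001, patience = 10, max_epochs = 2000 — conservative
values that converge on desk-scale matrices and are all overridable in the
run configuration. The plateau test uses the training objective; a holdout
variant is intentionally out of scope. A near-zero previous loss
(|L| < 10⁻¹²) counts as zero relative change, so the all-switches-off
configuration stops after patience + 1 epochs rather than dividing by
zero.

W and H initialize uniform(0, 0.1) — small and nonnegative so every ReLU
unit starts active — from a caller-supplied seed; the probe starts at
zero. Runs are bitwise reproducible given identical inputs and seed on the
same platform, and every pipeline invocation records seed, config, input
digests and stop reason in a manifest.

## Imputation semantics

Only zero entries are replaced, with the depth-adjusted mean μ̂ᵢⱼ;
observed nonzero counts are trusted measurements and pass through exactly.
Reporting imputed values on the observation scale (including sᵢ and κ)
keeps them commensurate with the retained raw counts within the same cell;
mixing biological-scale means with raw counts would break within-cell
comparability. No rounding and no small-value thresholding are applied —
users can post-filter. The stochastic observation noise of the generative
view is not sampled at inference: imputation is the conditional
expectation, and dispersion lives in the ZINB term.

## Synthetic data generator

The generator realizes the model's own generative assumptions with known
ground truth: cells are assigned to k types multinomially; each type's
profile is a shared log-normal base-mean vector (median 1, log-σ 1) with an
exclusive block of marker genes up-regulated by a configurable fold change
(default 8×, 20% of genes split across types) so that leakage and recovery
have unambiguous truth; per-cell depths are log-normal (σ = 0.3); counts
are Gamma–Poisson with shared dispersion θ (default 2, a typical UMI-scale
overdispersion); and dropout zeroes entries by independent Bernoulli
draws. The default dropout rate is logistic-decreasing in log1p of the
true mean — lowly expressed genes drop out more, which is precisely what
makes a technical zero statistically distinguishable from a biological one
— with a constant-rate option for controlled experiments. A cell zeroed
out entirely by dropout has its largest true entry restored so that size
factors stay defined. Default shape is 300 cells × 150 genes, 3 types.

What the generator does *not* emulate: ambient RNA contamination, doublets,
gene–gene regulatory correlation beyond the type structure, cell-cycle
variation, and realistic gene-count scales (real matrices have 10⁴ genes).
Passing recovery tests on this fixture shows the estimator recovers the
model's own data-generating process under heavy dropout; it does not
certify performance on real tissue data.

The label-degradation protocols mirror the robustness analyses: stratified
retention of a fraction of labels (largest-remainder allocation makes the
retained count exactly round(fraction · n)) and reassignment of
round(noise · n) uniformly chosen cells to a uniformly random *different*
type.

## Evaluation suite

ARI, Hungarian-matched accuracy (rectangular assignment on the negated
contingency table), macro-F1 (after Hungarian mapping by default), macro
one-vs-rest AUC (classes lacking positives or negatives are skipped), and
mean silhouette delegate to scikit-learn/scipy and are pinned by
brute-force oracles in the tests (pair enumeration for ARI, exhaustive
permutation for the assignment, a double-loop for silhouette). Silhouette
uses Euclidean distance on whatever representation the caller provides,
and the evaluation pipeline records that representation (log1p counts by
default) in its output, since the choice is not canonical. CBDir — the
mean cosine between a boundary cell's velocity and its displacement toward
ground-truth target-cluster neighbors, averaged per cell and then over
boundary cells — is implemented directly, reports a missing value (not 0)
when the clusters share no boundary, and consumes externally supplied
coordinates, velocities and neighbor graphs. The correlation-structure
agreement procedure subsamples 20% of cells for 50 iterations (both
configurable, seeded) and reports the upper-triangle Pearson similarity
and Frobenius distance to a reference gene–gene correlation matrix;
zero-variance genes in a subsample contribute zero correlations rather
than NaNs.

The clustering step that precedes the external metrics is deliberately
generic plumbing — seeded k-means on log1p counts — not part of the
method; any partition can be supplied instead.

## Numerical and testing notes

Problem sizes in the tests (up to 300 × 150, three seeds, and a 16-subset
ablation sweep capped at 300 epochs — the sweep trains each configuration
for a fixed epoch budget) were chosen so the whole suite runs in a couple
of minutes on a single CPU while still exercising the model at the
fixture's stated operating point. Two tolerance subtleties are deliberate:
the NB→Poisson limit at θ = 10⁶ is checked at *relative* 10⁻⁴ (the
absolute log-PMF gap in the far tail is O(x²/θ), ~2×10⁻⁴ at x = 20 while
the relative error is ~10⁻⁶), and z-score depth invariance is checked at
10⁻⁶ because the fixed ε = 10⁻⁸ in the standardization denominator breaks
exact scale invariance at the ~10⁻⁹ level.

## Known limitations

The factorization rank k must be pre-specified (labels make k = C the
natural choice); a poor k degrades results. Unsupervised mode is
intrinsically harder — without priors the factorization is underdetermined
under severe dropout — and is expected to improve less than the
prior-guided mode. The per-gene dropout logit cannot express cell-specific
capture failure beyond what size factors absorb. Full-batch training is
simple and exactly reproducible but scales memory as O(nm); very large
atlases would need minibatching, which is not implemented.
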