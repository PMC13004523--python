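# priornmf

Prior-guided nonnegative matrix factorization for imputing dropout in
single-cell RNA-seq count matrices.

## The problem

scRNA-seq count matrices are dominated by zeros, and those zeros mix two
very different things: *biological* zeros (the gene is genuinely silent in
that cell) and *technical* zeros (the transcript was present but lost to
capture failure, i.e. dropout). Imputation methods that smooth every zero
indiscriminately invent expression where none exists; methods that leave
everything alone forfeit real signal. `priornmf` is for analysts who have a
count matrix — and, ideally, cell-type labels for some or all cells — and
want the technical zeros filled in with plausible values while every
observed nonzero count is left untouched.

## The model

Let X ∈ ℕ₀^{n×m} be the counts for n cells and m genes. Per-cell size
factors sᵢ = Σⱼ Xᵢⱼ / medianᵣ Σⱼ Xᵣⱼ absorb library depth at the
observation layer (justified by Poisson thinning: per-molecule capture with
probability pᵢ rescales a Poisson mean multiplicatively). The biological
mean is a rank-k factorization

```
μ = W⁺ H⁺,        W⁺ ∈ ℝ^{n×k} row-stochastic,  H⁺ ∈ ℝ^{k×m} ≥ 0
```

where k is the number of cell types (or latent expression modules). With
labels, both factors are shrunk halfway toward label-derived anchors: the
one-hot encoding P and the cell-type prototype means H_prior,

```
W⁺ = ½(P + softmax(ReLU(W)))    (labeled cells)
H⁺ = ½(H_prior + ReLU(H))
```

which counteracts the non-convexity of NMF and the instability of random
initialization. Without labels the softmax / ReLU factors are used alone.
The observation-scale reconstruction is μ̂ᵢⱼ = sᵢ κ_{j,b(i)} μᵢⱼ (κ an
optional per-gene, per-batch multiplicative correction, zero-mean in log
space).

Training minimizes a switched four-term objective

```
L = λ_nmf ‖X − μ̂‖_F /(nm)  +  λ_zinb L_ZINB  +  λ_z L_zscore  +  λ_c L_class
```

with each λ ∈ {0, 1}: a Frobenius reconstruction term; the negative
log-likelihood of a zero-inflated negative binomial ZINB(μ̂ᵢⱼ, θ, πⱼ) with
shared dispersion θ and per-gene dropout probability πⱼ = σ(ρⱼ); a per-cell
z-score consistency term that preserves each cell's relative expression
shape; and the cross-entropy of a linear probe that requires cell identity
to be linearly decodable from W⁺. All parameters {W, H, ρ, θ, w_c, b} are
fit jointly by full-batch Adam with a step-decayed learning rate
η_t = η₀ γ^⌊t/T⌋, stopping when the relative loss change stays below 10⁻³
for a window of consecutive epochs. Gradients are analytic (verified
against central differences in the test suite), so no autograd framework is
needed.

Imputation then replaces **only the zero entries** of X with μ̂ᵢⱼ; observed
nonzero counts pass through bit-for-bit.

## Worked example

`examples/01_simulate_and_impute.py` simulates 300 cells × 150 genes in 3
types (negative-binomial counts, θ = 2, 50% Bernoulli dropout), fits the
supervised model with the true labels, and imputes:

```
simulated 300 cells x 150 genes, zero fraction 0.71 (dropout produced 0.50 of entries)
training stopped after 170 epochs (plateau); total loss 3.431 -> 2.340
replaced 31826 zero entries; nonzero counts preserved exactly
recovery: Pearson r = 0.927 between log1p model means and log1p true means over dropped-out entries
```

The recovery correlation is measured at exactly the entries the simulator
zeroed out, so r = 0.927 says the model restored most of the signal that
dropout destroyed. Downstream, `examples/02_evaluate_metrics.py` clusters
both matrices with k-means and scores them against the true types:

```
raw      ARI=0.619 ACC=0.860 F1=0.858 silhouette=0.038
imputed  ARI=1.000 ACC=1.000 F1=1.000 silhouette=0.170
gene-level Pearson (raw vs imputed): 0.950
```

Imputation lifts clustering agreement from ARI 0.62 to 1.00 while the
per-gene correlation of 0.95 shows the observed expression structure was
preserved rather than overwritten. The other examples demonstrate the
16-subset loss-switch ablation, the label-fraction / label-noise
robustness protocols, and the CBDir velocity-direction metric.

A thin CLI wraps the same pipeline for shell use:

```
priornmf simulate --out-dir sim --dropout-rate 0.5
priornmf impute --counts sim/counts.csv --labels sim/labels.tsv --out-dir run
priornmf evaluate --raw sim/counts.csv --imputed run/imputed.csv \
    --truth-labels sim/labels.tsv --out metrics.json
```

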