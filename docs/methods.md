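# Methods

## The summary-data training framework

`ldrisk` studies one question: how much of a deep model's predictive
ability for a quantitative trait survives when the model is trained on a
region's LD matrix instead of individual-level genotypes.

**Individual mode.** Dosages are coded additively (0/1/2 minor alleles)
and each SNP column is scaled to mean 0 and standard deviation `1/√p`
(population-style sd, see *Numerical choices*). A model maps one
sample's `p` scaled dosages to one trait prediction and is trained by
minibatch Adam on the mean squared error.

**Summary mode.** The training input is the single matrix
`R_tr = (1/n_tr) G_trᵀ G_tr`. The model's output layer has `n_tr` units
— one per training sample — and the whole phenotype vector is the
target, so the training set contains exactly one example and each
"epoch" is one full-gradient Adam step. The configured batch size is
recorded but has no effect in this mode; this is the only consistent
reading of a one-example training phase, and epochs-as-steps keeps the
published epoch counts meaningful.

**Bootstrap test error.** At test time the model transforms
`R_te = (1/n_te) G_teᵀ G_te` into `n_tr` outputs, but there are only
`n_te` test phenotypes. The estimator draws `n_te` outputs with
replacement, pairs the i-th draw with the i-th test response (the
pairing is exchangeable, so any fixed pairing yields the same law),
records the MSE, repeats `B` times (default `B = 1000`) and averages.
Its exact `B → ∞` limit is the all-pairs mean

    (1/(n_tr n_te)) Σⱼ Σᵢ (Oⱼ − yᵢ)² = Var(O) + Var(y) + (Ō − ȳ)² ,

implemented as `allpairs_oracle` and used to test unbiasedness and the
`1/√B` decay of the Monte-Carlo standard error, which is reported next
to every estimate. A useful corollary: a model whose outputs match the
response distribution (same mean and variance, no individual-level
alignment) has limit ≈ `2·Var(y)`, while a constant output at the
response mean has limit ≈ `Var(y)`.

## Model families and presets

All families share a linear output layer; dropout layers act only while
fitting. Named presets fix the benchmark configurations:

| preset | layers | schedule (epochs / batch / lr / decay) |
|---|---|---|
| `dnn-paper` | dense 231–77–22–5, dropout 0.2 after layer 1 and 0.5 after layer 3 | 100 / 256 / 1e-3 / 0.96 |
| `cnn-sim-s1` / `-s2` | 1-D conv, 50 filters × 500, then 1 or 5 dense-50 layers | 200 / 32 / 0.1 / 0.98 |
| `cnn-sim-s1-2d` / `-s2-2d` | as above with 50×50 2-D filters (summary blocks) | same |
| `cnn-real-s1` / `-s2` | conv 32×5 + pool 2 (+ 3 × conv 64×3 + pool 2), dense head as the sim twins | same |
| `lstm-paper` | 5 LSTM layers × 10 units, dense output | 10 / 256 / 1e-3 / 0.96 |
| `bilstm-paper` | 2 BiLSTM layers × 10 units, dense output | 5 / 256 / 1e-3 / 0.96 |
| `transformer-individual` | per-window encoder (6 heads), window 1,000 / stride 500, feedforward 64 | 10 / 8 / 1e-3 / 0.96 |
| `transformer-summary` | embed 128 + positional encoding, 2 × {6-head attention, dropout 0.1, layer norm}, 2 dense-128 + dropout + layer norm | 10 / 8 / 1e-3 / 0.96 |

Summary-input layouts per family: DNN takes the upper triangle of the LD
matrix as a flat vector (diagonal included by default — the information
content is identical either way); LSTM/BiLSTM take the full matrix as
`p` timesteps of `p` features (row *t* is the step-*t* feature vector);
CNN and transformer take non-overlapping diagonal blocks (the benchmark
block size 193 cuts 8,299 SNPs into exactly 43 blocks). Blocks travel on
the batch axis, so a fitted model accepts any block count; per-block
representations are averaged before the dense head (stated for the
transformer in the source design; adopted for the CNN by analogy — the
alternative of treating blocks as independent examples sharing one
target is not implemented as a preset but is a one-line custom spec).

Design choices where the published description is silent:

- **DNN hidden activation** is ReLU, matching the cited source
  architecture (ReLU is stated explicitly only for the CNN).
- **Individual-mode (Bi)LSTM input** is `p` timesteps × 1 feature; the
  final timestep's hidden state feeds the dense output.
- **Sim CNN presets** use stride 1 and no pooling (none is described);
  the real-data CNN variants keep their published pool-2 layers. The
  real-data structures modify only the convolutional stack, so the dense
  heads of the two sim structures are retained.
- **Transformer embedding** of numeric inputs is a position-wise linear
  map (scalar per SNP in individual mode, one block row per token in
  summary mode) plus sinusoidal positional encoding. The individual-mode
  encoder width is 48 (the published description fixes only 6 heads and
  a 64-unit feedforward); the summary-mode width 128 is as published.
  Attention uses a per-head key dimension of `⌊d_model / heads⌋`, so a
  width that is not a multiple of the head count (128 with 6 heads) is
  handled exactly as in standard Keras attention.
- **Weight initialisation** is Glorot-uniform from a seeded generator;
  LSTM forget-gate biases start at 1.
- **Learning-rate decay** is per epoch, `lr_e = lr₀ · 0.96^e`
  (non-staircase within an epoch); the published decay granularity is
  unstated. No early stopping and no internal validation split.

The engine underneath is a ~400-line reverse-mode autodiff on NumPy
(`ldrisk._nn`): broadcasted arithmetic, matmul, 1-D/2-D valid
cross-correlation, max pooling, softmax, layer norm and the gates needed
for LSTMs. Every op and every composite layer is verified against
central-difference gradients in the test suite. Parameters are float32;
inference runs with graph construction disabled.

## Synthetic cohorts

The generator emulates a 1 Mb common-variant panel without any external
download. Per-SNP MAFs are uniform on `[0.001, 0.5)`. Each of a SNP's
two allele copies is the indicator that a latent standard normal falls
below the MAF quantile; latents share an equicorrelation `r` within
consecutive blocks of `block_length` SNPs and are independent across
blocks. Marginals are exactly Binomial(2, MAF); neighbouring dosages are
positively correlated, mimicking haplotype-block LD. Defaults
`block_length = 20`, `r = 0.7` give local dosage correlations in the
0.4–0.6 range typical of dense panels. SNPs with sample MAF < 0.001 are
removed (full-sample frequency; the training-only alternative matters
little at these sample sizes and is not used).

The trait is `Yᵢ = Σₖ wₖ gᵢₖ + εᵢ` over `K = round(0.3 p)` causal SNPs
drawn without replacement, `wₖ ~ N(0, 0.6²)`, `εᵢ ~ N(0, 1)`. Because
standardized columns have variance `1/p`, the expected phenotype
variance is `1 + 0.3·0.36 ≈ 1.108` regardless of `p` — matching the
variance scale the benchmark tables report. Splits reserve
`floor(0.8·n)` samples for training (1,092 → 873/219).

What the generator does *not* reproduce: real MAF spectra (skewed toward
rare variants), long-range LD and recombination hot-spots, and
population structure. Tests passing on these cohorts therefore validate
the machinery and the statistical identities, not transferability to any
particular real panel; a loader for delimited dosage files and VCF
exists for replication on real genotypes.

## BLUP baseline

`y = 1μ + Zu + ε`, `u ~ N(0, σ²ᵤ I_p)`, `ε ~ N(0, σ²ₑ I_n)`. REML is
profiled over `γ = σ²ᵤ/σ²ₑ` on the spectrum of `K = Z Zᵀ` after
projecting out the intercept, making each likelihood evaluation O(n);
the ratio is optimised on a bounded log grid (`e^{±12}`) by Brent
search, with a Haseman–Elston moment fit as fallback. Predictions
`μ̂ + Z_te Zᵀ_tr (K + λI)⁻¹ (y − μ̂)` with `λ = σ²ₑ/σ²ᵤ` are identical to
ridge regression with penalty λ (Woodbury), which the tests assert to
1e-8. On the linear simulated design BLUP is the right model and beats
the constant-mean predictor in ≳90% of repeated splits once the training
set resolves the (LD-reduced) effective dimension.

## Numerical choices

- **Standardization sd** is population-style (divide by n), so the LD
  diagonal equals each column's mean square exactly; `ddof=1` is a flag.
  Scaling uses the full matrix before splitting, as in the benchmarked
  design (train-rows-only scaling is available); consequently the full
  LD matrix is exactly the `n_tr/n`-weighted average of the train and
  test LD matrices.
- **Block partitioning** zero-pads a final short block (flagged) so the
  block tensor stays rectangular; the benchmark's 193 divides 8,299
  exactly and needs no padding.
- **Sliding windows** append one flagged tail interval `[p−w, p)` when
  the stride grid stops short of `p`, so no SNP is silently dropped;
  `strict=True` reproduces the exact published 15-window grid, whose
  final 299 SNPs are uncovered.
- **Causal-count rounding** is round-half-up of `0.3·p`.
- Constant genotype columns abort standardization with the SNP named;
  non-finite training losses abort fitting with the epoch indexed.

## Scale of the shipped experiments

The shipped tests and the acceptance script run the benchmark at n=600,
p=1,000 with one to three repetitions per model — sizes chosen so the
full suite executes on a single CPU in minutes while preserving the
phenotype-variance scale (≈1.11) and the qualitative regimes: recurrent
models near the constant-output plateau (test MSE ≈ Var(y)), summary
models' bootstrap error governed by the all-pairs identity, BLUP best on
the linear design. The full published design (p=8,299 from a public
reference panel, 500 repetitions) is reachable with the same code via
the genotype loaders and `replicate_experiment`; only its structural
constants (block/window/split counts) are asserted directly.

## Known limitations

- Summary mode ships the exact estimator and architectures but no
  shrinkage or reference-panel correction for externally supplied LD
  matrices.
- The transformer consumes considerable memory at full scale; the
  diagonal-block route is the supported path for large p.
- REML assumes homoscedastic i.i.d. random effects; no covariate fixed
  effects beyond the intercept are implemented.
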