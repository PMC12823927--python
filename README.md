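# ldrisk

Genetic risk prediction with deep models when only linkage-disequilibrium
(LD) summary matrices are available.

Individual-level genotype data is often locked behind data-sharing
restrictions, while aggregate summaries of a genetic region — in
particular the LD matrix `R = (1/n) Gᵀ G` of standardized dosages — can
usually be shared. `ldrisk` implements and benchmarks a framework for
training deep regression models *directly on the LD matrix*: the model
maps one summary input to `n_tr` outputs `O_1, …, O_{n_tr}`, one per
training sample, fitted by minimising

    L(O, Y) = (1/n_tr) Σᵢ (Oᵢ − Yᵢ)² ,

and its test error is approximated by a bootstrap: feed the *test* LD
matrix to the trained model, resample `n_te` of the `n_tr` outputs with
replacement, pair them with the test phenotypes, and average the MSE over
`B` rounds,

    TÊ = (1/B) Σⱼ TEⱼ .

The exact `B → ∞` limit of TÊ is the all-pairs mean
`Var(O) + Var(y) + (mean O − mean y)²`, which the package exposes as an
oracle and uses to validate the resampler.

The toolkit is aimed at statistical geneticists who want to quantify how
much predictive performance survives the switch from individual-level to
summary-level inputs. It provides:

- **six model families** (fully connected DNN, 1-D/2-D CNN, LSTM, BiLSTM,
  transformer encoder) in both input modes, with named presets
  reproducing the benchmark architectures, built on a small
  gradient-checked NumPy autodiff engine;
- **LD tooling**: scaled Gram matrices, upper-triangle vectorisation,
  diagonal block partitioning (8,299 SNPs at block size 193 → 43 blocks),
  sliding windows (window 1,000, stride 500 → 15 full windows);
- **a synthetic cohort generator** with blockwise LD, MAF filtering,
  `1/√p` column standardization and the sparse linear trait
  `Yᵢ = Σₖ wₖ gᵢₖ + εᵢ` (30% causal SNPs, `wₖ ~ N(0, 0.6²)`,
  `εᵢ ~ N(0, 1)`);
- **a BLUP baseline** (REML variance components on the spectrum of
  `Z Zᵀ`; predictions identical to ridge regression with penalty
  `σ²ₑ/σ²ᵤ`);
- scikit-learn-style estimators (`DeepGenomicRegressor`, `BLUPRegressor`)
  and an `ldrisk` command-line interface.

## Worked example

```python
import numpy as np
from ldrisk import simulate as sim, ld
from ldrisk import DeepGenomicRegressor, BLUPRegressor
from ldrisk.evaluation import bootstrap_test_error

cfg = sim.SimulationConfig(n_individuals=600, n_snps=400, seed=7)
Gstd, pheno, split = sim.simulate_dataset(cfg)
y_tr = pheno.values[split.train_indices]
y_te = pheno.values[split.test_indices]

# summary mode: the model sees only the training LD matrix
ld_tr = ld.compute_ld(Gstd, split.train_indices)
ld_te = ld.compute_ld(Gstd, split.test_indices)
reg = DeepGenomicRegressor(architecture="lstm-paper", mode="summary",
                           random_state=0).fit(ld_tr, y_tr)
est = bootstrap_test_error(reg.predict(ld_te), y_te, B=1000, seed=0)
print(f"summary train MSE {reg.final_train_error_:.3f}")
print(f"bootstrap test error {est.te_hat:.3f} +/- {est.mc_se:.1e}")

# BLUP benchmark on the individual-level data
blup = BLUPRegressor().fit(Gstd.values[split.train_indices], y_tr)
mse = np.mean((blup.predict(Gstd.values[split.test_indices]) - y_te) ** 2)
print(f"BLUP test MSE {mse:.3f}  (phenotype variance {pheno.values.var():.3f})")
```

Output:

```
summary train MSE 1.119
bootstrap test error 1.155 +/- 1.7e-04
BLUP test MSE 1.105  (phenotype variance 1.149)
```

The summary-trained LSTM's bootstrap test error sits at the phenotype
variance — the model has not (in 10 gradient steps) moved far from a
constant predictor, exactly the regime the benchmark reports for the
recurrent families — while BLUP, which matches the linear generative
model, edges below it.

The same pipeline is scriptable:

```bash
ldrisk simulate-data --n 300 --p 400 --seed 1 --out-prefix demo
ldrisk make-ld --genotypes demo.genotypes.tsv --split demo.split.tsv \
               --out-train ld_train.tsv --out-test ld_test.tsv
ldrisk evaluate --ld-train ld_train.tsv --ld-test ld_test.tsv \
                --phenotype demo.phenotype.tsv --split demo.split.tsv \
                --model dnn-paper --report eval.tsv
ldrisk blup --genotypes demo.genotypes.tsv --phenotype demo.phenotype.tsv \
            --split demo.split.tsv --report blup.tsv
```

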