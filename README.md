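# enviropinet

Physics-guided prediction of effluent organic carbon from granular
activated carbon (GAC) drinking-water biofilters.

Biofilter monitoring campaigns are sparse and heterogeneous: a handful of
studies, each covering a narrow slice of design and operating conditions,
measured at lab through full scale. Purely data-driven feature reduction
(PCA, kernel PCA, autoencoders) tends to generalize poorly across that
scale gap. This package instead builds its features from dimensional
analysis: by the Buckingham Pi theorem, `n` variables expressed in `m`
independent base dimensions can be rewritten as `n − m` dimensionless
power-products (π-groups), which are scale-invariant by construction.

For the nine biofilter variables — water temperature `T`, pore size `Pz`,
filter age `A`, influent/effluent organic carbon `IC_org`/`EC_org`, empty
bed contact time `Bt`, GAC particle diameter `P`, filter bed diameter
`C_fit`, ambient temperature `t0` — the exact rational null space of the
dimensional matrix over {mass, length, time, temperature} yields four
independent groups and one dependent group:

    Pz/C_fit,  Bt/A,  P/C_fit,  t0/T      and      EC_org/IC_org

Two model pathways operate on these features:

* **monomial power-law (BP-LR)** — ordinary least squares in log space:

      EC/IC = exp(β₀) · (Pz/C_fit)^β₁ (Bt/A)^β₂ (P/C_fit)^β₃ (t0/T)^β₄

* **feedforward network (BP-NN)** — two ReLU hidden layers, linear
  output, Adam with L2 penalty, 5-fold cross-validation repeated over 7
  seeds, trained on the standardized log π-groups.

A benchmarking harness compares both against PCA / kernel-PCA /
autoencoder reduction (each to 4 features) combined with ridge, gradient
boosting, random forest and RBF support-vector regressors, scoring every
combination with R² and a bounded sMAPE
(`100/n · Σ |y−Y| / (|y|+|Y|)`) on the dimensional effluent
concentration. A synthetic-data module generates biofilter-like tables
with a known monomial ground truth so the whole pipeline is testable
without any external data.

## Worked example

```sh
enviropinet simulate --seed 1 --out obs.csv
enviropinet pigroups --data obs.csv --out pigroups/
```

prints the derived basis:

```
4 independent dimensionless group(s):
  pi_1 = Pz/C_fit
  pi_2 = Bt/A
  pi_3 = P/C_fit
  pi_4 = t0/T
dependent group: EC_org/IC_org
wrote pigroups/pi_features.csv (317 rows, 0 dropped)
```

Fit the monomial model on the training studies (study 3 is held out; 54
of its 116 rows are drawn into training, leaving 62 test rows) and score
it:

```sh
enviropinet train --data obs.csv --model lr --feature-mode pi \
    --holdout-study study_3 --train-quota 54 --out model/
enviropinet evaluate --model-dir model/ --data obs.csv --out eval/
```

```
   model       r2    smape  pearson_r  pearson_p   n
monomial 0.997538 1.847935   0.998769        0.0 317
```

An R² of 0.998 and sMAPE of 1.8% against this synthetic table mean the
fitted exponents recover the generating power law to within the injected
5% log-normal noise. In Python the same fit is three calls:

```python
from enviropinet import *

table = generate(SyntheticConfig(seed=1))
basis = construct_pi_basis(biofilter_specs(), repeating=biofilter_repeating())
pi = evaluate_pi(basis, table)
model = fit_monomial(pi[basis.labels], pi["EC_org/IC_org"])
print(model.beta0, model.exponents)
```

The full comparison grid (4 reducers × 5 regressor families × train/test
× R²/sMAPE) is produced by:

```sh
enviropinet compare --seed 1 --out comparison/
```

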