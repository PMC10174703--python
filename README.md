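# protdpc

Detection probability curves (DPCs) for intensity-dependent missing values
in label-free shotgun proteomics.

Missing peptide or protein intensities in LC-MS/MS data are neither missing
completely at random nor hard-censored at a detection limit: the
probability that a value is reported rises smoothly with its underlying
abundance. `protdpc` models that process explicitly and uses it, instead of
imputation, in downstream inference. It is aimed at statisticians and
computational proteomics practitioners working with wide intensity matrices
(DIA-NN, MaxQuant or similar output, pivoted to features x samples).

## The model

Let y_ij be the log2 intensity of feature i in sample j and d_ij indicate
whether it was detected. The DPC is logit-linear in the underlying
intensity,

    logit p(d_ij = 1 | y_ij) = β0 + β1 · y_ij,

with global coefficients. β1 = 0 is the missing-at-random limit; β1 → ∞ is
left-censoring; real datasets sit in between (β1 ≈ 1 per log2 unit).
Three consequences drive the package:

* **Zero-truncation.** Features missing in every sample never appear, so
  per-feature detected counts d_i follow a zero-truncated binomial
  ZB(n, p_i). Curves are estimated by maximum likelihood under that
  distribution (plain logistic regression overestimates detection at low
  intensity).
* **Exponential tilting.** If observed values are N(μ_obs, σ²), the values
  that went missing are N(μ_obs − β1·σ², σ²) — same variance, mean shifted
  down by β1·σ_obs standard deviations. The marginal detection probability
  is logit p(d=1) = β0 + β1·μ_obs − ½·β1²·σ², which corrects the bias of
  fitting to observed means ("underlying-intensity" DPC). The Fisher
  information in the missingness count relative to the observed
  intensities, I2/I1 = β1²(1−p)σ², quantifies what the missing-value
  pattern can recover.
* **Likelihood-based testing.** For two-group differential expression,
  each observed value contributes a normal density term and each missing
  value contributes p(d=0; μ, σ²) = ∫ N(y; μ, σ²) (1 − logistic(β0+β1 y)) dy
  (Gauss–Hermite quadrature). A likelihood-ratio test against χ²₁ uses all
  samples without imputing anything, and recovers part of the power lost by
  dropping NAs.

A simulator for two-group data with logit-linear missingness, a
moderated-t reference pipeline (empirical-Bayes variance shrinkage,
verified against Bioconductor limma), and a `protdpc` command-line
interface round out the package.

## Worked example

```python
import protdpc as P

ds = P.simulate_dataset(P.SimConfig(seed=1))   # 10k proteins, 2 groups of 6
model = P.DPCModel(ds.observed)
res = model.fit(underlying=True)               # bias-corrected DPC
print(res.summary())
```

```
Detection probability curve (zero-truncated binomial ML)
==========================================================
x variable:        underlying-mean
features used:     9811   samples: 12
log-likelihood:    -15512.9126
converged:         True
----------------------------------------------------------
term              coef     std err
beta0          -5.8989      0.0395
beta1           0.7868      0.0049
```

The simulator injected missingness with (β0, β1) = (−6.0, 0.8); the fit
recovers the curve from the incomplete matrix alone. The tilting formulas
then quantify the missing-value bias and the DPC-aware test uses it:

```python
t = P.tilt_normal(mu_obs=8.0, sigma2=0.09, beta1=res.beta[1])
print(t.mu_mis, t.shift)        # 7.9292  0.236 SDs below the observed mean

de = P.dpc_lrt(ds.observed, ds.group_labels, res.beta)
print(de.summary())
ev = P.evaluate_de(de, ds.de_labels)
print(ev["tpr"], ev["fdr"])     # 0.772  0.0446
```

```
Differential expression (dpc_lrt)
==============================================
features:            10000
tested:              8870
significant (BH<0.05): 808
variance prior s2:   0.0899
```

On the same dataset the moderated t on complete data finds ~99.9% of the
1000 true two-fold changes; dropping missing values costs ~25 points of
power, and the DPC likelihood-ratio test wins a couple of points back while
holding the false discovery rate below the Benjamini–Hochberg 5% target.

The same steps are available from the shell:

```sh
protdpc simulate --n-features 10000 --seed 1 --out sim.tsv
protdpc fit --matrix sim.tsv --underlying --out fit.json
protdpc detest --matrix sim.tsv --groups groups.tsv --method dpc \
    --dpc-fit fit.json --out results.tsv
protdpc tilt --mu-obs 8 --sigma2 0.09 --beta0 -6 --beta1 0.8
```

## Layout

- `src/protdpc/simulate.py` – two-group generator with DPC missingness
- `src/protdpc/ztbinom.py` – zero-truncated binomial distribution
- `src/protdpc/dpc.py` – spline / capped / underlying-intensity DPC fits
- `src/protdpc/tilt.py` – exponential tilting, marginal detection, Fisher information
- `src/protdpc/detest.py` – moderated t and DPC likelihood-ratio test
- `src/protdpc/io.py`, `pipeline.py`, `cli.py` – matrix dialects, runner, CLI
- `docs/methods.md` – modelling assumptions, numerical choices, limitations
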