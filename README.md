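# stripevol

Comparative phylogenetics of white-stripe evolution in clownfishes
(*Amphiprion*).  Adult clownfishes carry 0–3 vertical white stripes; this
package provides the full analytical toolkit for asking how that pattern
evolved on a time-calibrated phylogeny and what it is for:

* **Constrained Mk models** — continuous-time Markov models of the 4-state
  stripe character (and the binary "stripes lost during ontogeny"
  character) with arbitrary constraint structures on the transition-rate
  matrix Q, ML fitting, likelihood-ratio tests and AIC/AICc model tables.
* **Stochastic character mapping** — full character histories sampled
  conditional on tip data and Q (uniformization bridges), with ensemble
  summaries: ancestral-state frequencies, expected transition counts,
  dwell times, and an explicit rule for counting major transitions.
* **MuSSE diversification likelihoods** — the joint likelihood of tree and
  character from the coupled extinction/data ODEs, with speciation and
  extinction shared across states, a global sampling fraction for missing
  species, and the four-model comparison (free / symmetric / no-two-stripe
  jumps / both) that tests whether stripe evolution is stepwise:

      dE_i/dt = μ − (λ + μ + Σ_j q_ij) E_i + λ E_i² + Σ_j q_ij E_j
      dD_i/dt = −(λ + μ + Σ_j q_ij) D_i + Σ_j q_ij D_j + 2 λ E_i D_i

* **PGLS** — phylogenetic regressions of stripe number on ecology and
  morphology (host breadth, body size, elongation, dorsal-fin lobe
  indexes) under Brownian-motion covariance.
* **Community species-recognition test** — polymorphism-aware
  identical-pairs statistics against richness-preserving random
  communities drawn from a regional species pool.
* **Synthetic data generators** — seeded birth–death trees, forward CTMC
  characters with full latent histories, Brownian traits with known
  slopes, and species pools/communities, so every stage runs and is
  validated with no external download.

The API follows the statsmodels convention: a model object is built from
data and `fit()` returns a results object carrying estimates,
uncertainties and a `summary()`.

## Worked example

```python
import numpy as np
import stripevol as sv

# a fully synthetic study at the clownfish scale:
# 27-tip tree, 4-state stripe character, 3 polymorphic species
fx = sv.default_fixture(seed=0)
coding = fx.stripes_true.coding

# equal-rates vs all-rates-different, with a likelihood-ratio test
er  = sv.MkModel(fx.tree, coding, sv.MkModel.er_spec(4)).fit(seed=0)
ard = sv.MkModel(fx.tree, coding, sv.MkModel.ard_spec(4)).fit(seed=0)
stat, df, p = sv.likelihood_ratio_test(er, ard)
print(er.summary())
print(f"LRT: statistic={stat:.2f}, df={df}, p={p:.3f}")

# the four-model MuSSE comparison
table = sv.musse_model_table(fx.tree, coding, f=27/30, n_starts=3, seed=0)
print(table[["model", "lnL", "k", "AICc", "dAICc", "weight"]].to_string(index=False))
```

prints (numbers from this exact run):

```
Mk model fit: ER (equal rates)
  states: 4   tips: 27
  free rate classes: 1
  lnL = -13.3570   AIC = 28.71   AICc = 28.87
  rates (per Myr): q[1]=0.012284
LRT: statistic=7.36, df=11, p=0.769
    model        lnL  k       AICc     dAICc       weight
 model iv -69.097039  5 151.051222  0.000000 9.900238e-01
 model ii -68.750468  8 161.500936 10.449714 5.327446e-03
model iii -68.886735  8 161.773471 10.722249 4.648778e-03
  model i -67.140280 14 197.280560 46.229338 9.058836e-11
```

The constrained stepwise model (iv) wins on AICc with an Akaike weight of
0.99: under its generating conditions (rates 0.123, 0.103, 0.052 /Myr
between adjacent stripe counts) the looser models gain at most ~2 lnL
units, nowhere near justifying their extra parameters.  The Mk LRT on the
same 27-tip character is non-significant — at this sample size ER is not
rejected — which is exactly why the model comparison is run at the
diversification level with AICc.

Downstream stages hang off the fitted objects:

```python
ens  = ard.simulate_histories(n_maps=10_000, seed=0)   # stochastic maps
summ = sv.summarize(ens)                               # node freqs, dwell, counts
res  = sv.pgls_fit(fx.tree,
                   {s: float(st[0]) for s, st in coding.states.items()},
                   {r["species"]: (r["l1"] - r["l2"]) / r["L"]
                    for _, r in fx.traits.iterrows()})
print(res.summary())
```

A command-line interface mirrors the stages (`stripevol simulate`,
`fit-mk`, `simmap`, `fit-musse`, `pgls`, `community-test`, `run-all`); see
`stripevol --help`.

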