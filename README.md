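# wrenfit

Marker-based relatedness, reproductive-value-weighted fitness, and
hurdle-model inference for cooperatively breeding bird populations.

## The problem

In many socially monogamous birds most offspring are sired outside the
pair bond.  Whether females gain *indirect* (genetic) benefits from this
extra-pair paternity (EPP) is a long-standing question; one candidate
benefit is **inbreeding avoidance**: in highly philopatric species such
as red-winged fairy-wrens (*Malurus elegans*), limited dispersal makes
social pairings between close relatives common, and a female paired to a
relative can produce outbred young by mating outside the pair.  Testing
this requires three quantitative ingredients, all provided here:

1. **Relatedness from markers.**  Pairwise relatedness r estimated from
   hypervariable microsatellites with Wang's moment estimator; the
   offspring inbreeding coefficient is f = r/2 of its genetic parents and
   the social-pair kinship is k = r/2 of the partners.  Values are binned
   (0.25, 0.1875, 0.125, 0.0625, 0, ≤ −0.0625 with upper-inclusive edges
   at 0.22/0.16/0.10/0.04/−0.02); f or k above 0.10 counts as highly
   inbred / close kin.
2. **An integrated fitness measure.**  Individual fitness over the first
   three years of life, weighting survival and offspring production by
   state- and sex-specific reproductive values v from a two-sex
   stage-structured matrix model (fledgling / subordinate / dominant ×
   sex), scaled so the dominant female has v = 1:

   W = J₍₀₋₃₎ · v(state at t₃) + ½ Σₜ Σ_y J_y · v(state_y)

3. **Inference for a bimodal response.**  A two-part hurdle model
   (logistic mixed model for W = 0 vs W > 0; Gaussian mixed model for
   positive W) with nest-within-mother random intercepts, joint
   likelihood, and AICc all-subset model selection in which a
   covariate's linear and threshold forms never co-occur; plus binomial /
   Gaussian / zero-inflated-Poisson GLMMs for the separate fitness
   components and Wilcoxon signed-rank contrasts of maternal half-sibs.

A seeded synthetic-population generator (`wrenfit.simdata`) produces
territory-structured populations with dominant pairs and 0–8 helpers,
~58% baseline EPP rising with social-pair kinship, ~70% whole-brood nest
predation, Mendelian microsatellite genotypes, and configurable threshold
inbreeding depression — with full pedigree ground truth, so the whole
pipeline can be validated end to end.  See `docs/methods.md` for the
models, conventions, and known limitations.

## Worked example

```python
import warnings
from wrenfit.simdata import inbreeding_depression_config
from wrenfit.pipeline import run_pipeline

# a population with a 75% threshold fitness cost for offspring of f > 0.10
cfg = inbreeding_depression_config(0.75, seed=3)
warnings.simplefilter("ignore")
report = run_pipeline(cfg, out_dir="run3")
for key in ("n_offspring", "epp_rate", "pct_close_kin_pairs",
            "pct_inbred_offspring", "mean_f_epo", "mean_W_inbred",
            "mean_W_noninbred", "inbred_fitness_ratio", "best_model_terms"):
    print(key, "=", report[key])
```

prints (exactly, for this seed):

```
n_offspring = 1195
epp_rate = 0.6267782426778242
pct_close_kin_pairs = 9.969788519637463
pct_inbred_offspring = 6.02510460251046
mean_f_epo = 0.015472112884166228
mean_W_inbred = 0.0
mean_W_noninbred = 0.09596497342686645
inbred_fitness_ratio = 0.0
best_model_terms = ['f', 'year_mean']
```

Reading it: of 1195 genotyped offspring, 63% were extra-pair and 10% of
social pairs were close kin; extra-pair offspring are essentially outbred
(mean f̂ = 0.015).  In this replicate no offspring classified inbred
(f̂ > 0.10) achieved any fitness, so the estimated inbred/non-inbred
fitness ratio is 0 (the injected truth is 0.25; the estimate is noisy
because only ~70 offspring are inbred), and the top hurdle model retains
an inbreeding predictor — here the linear form of f — plus year quality.
Stage outputs (`offspring_f.csv`, `pairs_k.csv`, `rv.csv`, `fitness.csv`,
`covariates.csv`, `selection_fitness.csv`, `report.json`) are written to
`run3/`.

The same stages are available from the shell:

```bash
wrenfit simulate --out data --seed 11
wrenfit relatedness --data data --out rel
wrenfit rv --data data --out rv
wrenfit fitness --data data --rv rv/rv.csv --out fit
wrenfit run --out full --seed 11          # everything end to end
```

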