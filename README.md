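# survtg

Time-dependent **total gain** statistics — `TG(t)` and `TG_STD(t)` — for
quantifying the predictive ability of survival models, built on the
predictiveness curve, together with the comparator R²-type measures
(`R²_BS(t)`, `R²_PM`, `R²_D`, `ρ²_W`) and a full Monte-Carlo study of their
behaviour under censoring, skewed covariates, influential observations,
non-proportional hazards and covariate categorisation.

## Who this is for

Biostatisticians and prognostic-model developers who need to answer *"how
much does this model actually help predict survival at time t\*?"* — a
question that p-values and hazard ratios do not address. Classical R²-type
measures for survival models are mostly whole-follow-up summaries, and many
are distorted by random censoring. The standardised total gain is a
time-anchored measure that is essentially censoring-independent and applies
to any model that orders patients by risk, including models with
time-dependent (crossing-hazards) covariate effects.

## The statistic

For a fitted model with prognostic index PI = β'z and predicted survival
probabilities S(t\*|z), the *predictiveness curve* at time t\* plots

    R(υ; t*)  against  υ = F(β'z) ∈ (0, 1],

the predicted survival probability of the subject at proportional PI rank υ.
With π₀(t\*) the pooled Kaplan–Meier survival estimate, the **total gain** is
the area between the curve and the horizontal anchor,

    TG(t*) = ∫₀¹ |R(υ; t*) − π₀(t*)| dυ,

estimated by the equal-weight mean over subjects. TG is bounded above by
2·π₀(t\*)(1 − π₀(t\*)) ≤ 0.5, which standardises it to

    TG_STD(t*) = TG(t*) / [2 π₀(t*) (1 − π₀(t*))] ∈ [0, 1],

0 for an uninformative model, 1 for a perfect step-function curve. The
squared-error analogue `R²_Pepe(t*)` and the binary-outcome Schemper V are
provided, along with the IPCW-Brier `R²_BS(t)` (its nonparametric
counterpart) and the whole-follow-up measures `R²_PM`, `R²_D`, `ρ²_W`.

Both TG statistics depend on the model only through the *ranking* of the
prognostic index and the predicted probabilities, so they are invariant
under monotone transformations of the PI.

## Worked example

```python
import numpy as np
from survtg import Scenario, gen_exponential_ph, fit_cox, kaplan_meier
from survtg import build_curve, total_gain, total_gain_std, bootstrap_ci

# a 500-subject cohort: exponential event times, hazard ratio 2 per SD of z
ds = gen_exponential_ph(Scenario(name="demo", n=500, beta=np.log(2), seed=1), 0)

model = fit_cox(ds)
t_star = 34.66                       # median of the marginal event-time law
curve = build_curve(
    model.predict_survival(ds, t_star),
    model.prognostic_index(ds),
    kaplan_meier(ds, t_star),
    t_star,
)
print(f"TG({t_star}) = {total_gain(curve).value:.3f}")
print(f"TG_STD({t_star}) = {total_gain_std(curve).value:.3f}")

est = bootstrap_ci(ds, "TG_STD", t_star, fit_cox, n_boot=200, seed=1)
print(f"95% bootstrap CI: ({est.ci_low:.3f}, {est.ci_high:.3f})")
```

Output:

```
TG(34.66) = 0.153
TG_STD(34.66) = 0.307
95% bootstrap CI: (0.271, 0.349)
```

Roughly a third of the attainable separation at the median event time is
captured by this single standard-normal covariate with hazard ratio 2; this
particular draw sits a little below the Monte-Carlo mean of ≈ 0.35 for the
design, and its bootstrap interval reflects that.

The same analysis runs from the shell on any delimited dataset:

```sh
survtg estimate --input cohort.csv --time-col time --event-col event \
    --covariates age,nodes,grade --t 2.0 --measures TG,TG_STD,R2_BS \
    --boot 1000 --seed 1
survtg curve --input cohort.csv --t 2.0 --out curve.csv
survtg simulate table1 --replicates 200 --seed 1 --out table1.csv
```

Simulation presets: `table1` (uncensored benchmark grid), `table2`
(censoring invariance), `monotonicity`, `contamination`, `ipass`
(two-arm crossing hazards), `categorise`.

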