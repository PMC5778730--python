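# riskreclass

Does adding a new risk factor to a clinical risk-prediction model actually
improve it — and do the usual performance statistics agree on the answer?

`riskreclass` is a simulation framework for studying that question in the
setting of 10-year major osteoporotic fracture (MOF) risk prediction with a
FRAX®-style model. A synthetic cohort of women aged 50+ carries a baseline
predicted risk probability π_i and a binary fracture outcome D_i. A
simulated binary risk factor — a carrier indicator X_i ~ Bernoulli(p),
independent of both the outcome and the baseline predictions — is added to
the model with an *assumed* relative risk RR, so the new model's prediction
is

    π_i' = π_i · RR^{X_i}          (no cap at 1 by default)

Because X carries no outcome information, this is a pure-noise addition,
and the framework measures what each headline statistic reports about it:

- **ΔAUROC** — change in the Mann–Whitney concordance
  P(π_event > π_non-event) (ties credited ½);
- **ΔCalibration** — change in the observed/expected ratio
  (event fraction ÷ mean predicted risk);
- **NRI** — net reclassification improvement over risk categories defined
  by an intervention threshold t:
  [P(up|D=1) − P(down|D=1)] + [P(down|D=0) − P(up|D=0)];
- **IDI** — integrated discrimination improvement, the change in the
  discrimination slope mean(π'|D=1) − mean(π'|D=0).

Under this model the IDI and calibration shifts have closed forms,

    E[IDI]  = p·(RR−1)·(m_e − m_ne)
    E[ΔCal] = C0 / (1 + p·(RR−1)) − C0,

with m_e, m_ne the group risk means and C0 the baseline calibration ratio;
at p = 1 the multiplier is common to everyone, so ΔAUROC = 0 exactly. These
closed forms are the built-in oracles against which every simulated grid
cell is checked.

## Worked example

```
$ python analysis/01_generate_cohort.py --seed 0 --out-dir results
cohort: n = 31,999, events = 3,529 (11.0%)
predicted risk, events:     16.3 +/- 9.6 %
predicted risk, non-events: 10.5 +/- 6.8 %

$ python analysis/02_baseline_performance.py --out-dir results
baseline AUROC       = 0.701
baseline calibration = 0.990
```

The cohort reproduces the summary structure of a provincial bone-density
registry study population: the group-conditional risk moments, a baseline
AUROC near 0.706, and a baseline observed/expected ratio of 0.990 (outcomes
are drawn at the 10-year-incidence scale that ratio implies).

```
$ python analysis/03_risk_factor_grid.py --out-dir results
--- varying rr (others held constant) ---
rr                  1.25   1.50   1.75   2.00   2.25   2.50   2.75   3.00   3.25   3.50
nri                0.022  0.028  0.033  0.032  0.028  0.020  0.013  0.007  0.002 -0.006
idi                0.005  0.010  0.015  0.019  0.024  0.029  0.034  0.039  0.044  0.049
delta_auroc       -0.002 -0.008 -0.015 -0.022 -0.028 -0.035 -0.040 -0.045 -0.050 -0.054
delta_calibration -0.076 -0.141 -0.198 -0.248 -0.291 -0.330 -0.365 -0.396 -0.424 -0.450
...
```

Reading the row for RR = 2.0, prevalence = 1/3, threshold = 20%: the
reclassification statistics call the noise factor an improvement
(NRI = +0.032, IDI = +0.019) while discrimination and calibration both
degrade (ΔAUROC = −0.022, ΔCalibration = −0.248). The NRI rises to a
maximum at moderate RR and then falls, going negative by RR = 3.5; the IDI
grows linearly in RR; ΔCalibration follows C0/(1+p(RR−1)) − C0 exactly.
That disagreement between measure families — not any single number — is
the phenomenon under study.

```
$ python analysis/04_oracle_comparison.py --out-dir results
largest |simulated - expected| / SE across all conditions: 2.35
```

Every simulated IDI and ΔCalibration cell sits within 3 Monte-Carlo
standard errors of its closed form.

The same machinery is scriptable (`riskreclass table2 --seed 0 --out
table2.csv`, `riskreclass expect --rr 2 --prev 0.3333`, `riskreclass
reproduce --config study.yaml`) and importable (`generate_cohort`,
`run_grid`, `compare_models`, ...). See `docs/methods.md` for the model,
its assumptions and the numerical choices.

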