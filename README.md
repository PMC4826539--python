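# glucotime

Distributional analytics for the **timeliness** of inpatient point-of-care
blood-glucose (BG) monitoring. Hospital protocols for patients eating
regular meals call for BG checks four times a day — before the three meals
(around 08:00, 12:00, 18:00) and at bedtime (around 22:00). Electronic
meter records carry a timestamp for every measurement, so each ward's daily
*distribution of measurement times* is itself a quality-of-care signal:
an adherent ward produces a tight four-modal daily pattern, while complete
non-adherence is indistinguishable from times scattered uniformly over the
24-hour day. `glucotime` turns that observation into a surveillance
pipeline for ward-level adherence, aimed at hospital quality teams and
biostatisticians working from de-identified laboratory extracts.

## The method

For each ward-day with timings `y_1..y_n` (decimal hours):

1. **Uniformity test.** A one-sample Kolmogorov–Smirnov test of the day
   against Uniform(0, 24). The effect size is
   `D = sup_y |F_n(y) − y/24|`; `p < 0.05` is evidence of *adherence*
   (deviation from the non-adherence null). Wards are ranked by the
   proportion of significant days (ties: median p), and
   `−log10(p)` is meta-regressed on z-standardized `D` and `n` with
   interaction to quantify what drives the daily evidence.
2. **Simulated power.** Small wards can fail to reject for lack of data
   alone. Each day's empirical CDF is linearly interpolated and inverted;
   `B = 5000` synthetic days of the same size are drawn from it
   (`t = t1 + (t2 − t1)(u − F(t1))/(F(t2) − F(t1))`, `u ~ U(0,1)`), and the
   day's power is the fraction rejecting uniformity. A ward whose mean *or*
   median daily power is ≥ 90 % is adequately powered; two-day pooling
   windows rescue moderately powered wards.
3. **Transition surveillance.** Consecutive days are compared with a
   two-sample KS test. A window with a significant 2S-KS p-value and
   *exactly one* significant 1S-KS day flags a potential transition to or
   from non-adherence.
4. **Mixture de-convolution.** All of a ward's timings are fit with a
   K-component normal mixture whose means/SDs are day-constant while the
   mixing probabilities follow a multinomial logit on day indicators
   (a concomitant-variable model):
   `h(y_ij) = Σ_k π_k(w_ij, α) N(y_ij; μ_k, σ_k²)`.
   K is selected by the integrated classification likelihood
   (`ICL = −2 logL + ν log n + 2·entropy`). Exactly four *narrow*
   components (SD < 1 h) centred before mealtimes and near bedtime is the
   signature of an adherent ward.

A synthetic-panel generator reproduces the statistical structure the
method assumes (four narrow components plus a wide background, day-varying
mixes, daily counts of 59–103), so the full pipeline is testable without
any hospital data.

## Worked example

```bash
glucotime simulate --scenario adherent --wards 2 --days 8 --seed 4 \
    --out panel.csv
glucotime ks --panel panel.csv --out ks1.csv --out2 ks2.csv
glucotime power --panel panel.csv --iters 200 --seed 1 --out power.csv
```

which prints

```
wrote 1302 timings over 2 wards x 8 days to panel.csv
1S-KS on 16 ward-days -> ks1.csv
2S-KS on 14 windows -> ks2.csv
ward  mean_power  median_power  high_power  n_days_evaluated  n_iterations  window
 W01       0.995           1.0        True                 8           200       1
 W02       1.000           1.0        True                 8           200       1
```

Every one of the 16 simulated ward-days rejects uniformity (all 1S-KS
p-values are far below 0.05 in `ks1.csv`) and both wards have simulated
power ≈ 1, i.e. their daily sample sizes are ample for adherence
assessment. Fitting the mixture for one ward,

```bash
glucotime mixture --panel panel.csv --ward W01 --kmin 4 --kmax 5 \
    --starts 2 --seed 0 --out model.json
# -> selected K=5 (ICL=2859.2) -> model.json
```

the selected model contains four narrow components near 7.2, 11.4, 17.2
and 21.9 h — measurements concentrated shortly *before* the 8/12/18 h
mealtimes and around the 22 h bedtime — plus a wide background component,
matching the generator's truth. `glucotime watch` combines `ks1.csv` and
`ks2.csv` into transition flags (none here: the ward is stably adherent),
and `glucotime report` composes the p-value boxplots, daily CDF panels and
component-interval figures with the cross-ward summary table.

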