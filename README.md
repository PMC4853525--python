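# mediareach

Estimation of population exposure to tobacco and alcohol content in
online music videos, for public-health researchers quantifying substance
imagery in digital media.

The pipeline combines three inputs:

1. **Interval-coded content** — each video scored in successive 10 s
   windows for presence/absence of substance content (actual use, implied
   use, paraphernalia, brand; visual and lyric channels). A *content
   class* (e.g. alcohol) unions its flags per window, giving the class's
   interval count `I_c`.
2. **Ever-seen survey** — respondents report whether they have ever
   watched each surveyed video. Per stratum *g* (age band × gender) the
   weighted mean proportion of videos viewed is
   `p̄_g = Σ_r w_r f_r / Σ_r w_r`, with a normal-approximation 95% CI
   using the Kish effective sample size `n_eff = (Σw)² / Σw²`.
3. **Census mid-year population** `N_g` (millions) per stratum.

The estimand is **gross impressions** — person × content-interval ×
ever-seen-video exposure events, counting one viewing per person per
video:

```
G_{g,c}  = p̄_g × N_g × I_c          (millions)
PC_{g,c} = G_{g,c} / N_g = p̄_g × I_c   (per capita)
```

CI endpoints of `p̄_g` propagate linearly through the deterministic
multipliers `N` and `I`; aggregates over disjoint strata sum gross values
and CI endpoints. Because one `p̄_g` multiplies every class's interval
count, `G_tobacco / G_alcohol = I_tobacco / I_alcohol` exactly within a
stratum — a structural identity the test suite exploits.

The surveyed microdata behind the published UK study of the 32 most
popular content-bearing videos (821 intervals: 233 alcohol, 47 tobacco,
6 e-cigarette) are not public, so the package ships a seeded synthetic
generator emulating the study conditions — ~2068 adolescent and ~2232
adult respondents, a logistic ever-seen model declining with age, higher
for females, with per-video popularity effects — plus the published
summary figures (`mediareach.reference_data`) for arithmetic-identity
checks.

## Worked example

`python examples/03_full_pipeline.py` runs the full estimator on a
synthetic study (seed 7) and prints:

```
stratum  population_millions  proportion_viewed  gross_alcohol  percapita_alcohol  gross_tobacco  percapita_tobacco
  11-18                 5.91               0.21         309.21              52.32          56.33               9.53
    19+                49.20               0.06         706.88              14.37         128.78               2.62
  Total                55.11               0.07        1016.09              18.44         185.12               3.36

intervals used: {'alcohol': 247, 'tobacco': 45}
```

Reading the first row: 21% of 11–18-year-olds have seen the average
video, so the 247 realised alcohol intervals deliver
0.21 × 5.91 M × 247 ≈ 309 million gross alcohol impressions to
adolescents — about 52 per adolescent. The Total row aggregates the
adolescent and adult rows (gross and CI endpoints sum; per-capita is the
population-weighted combination).

`python examples/04_published_identities.py` re-derives the published
per-capita cells from the published gross and population figures, e.g.
adult alcohol 695.09 / 49.20 = 14.13 per capita, matching the printed
value exactly.

Other entry points: `examples/01_interval_coding.py` (coding semantics),
`examples/02_survey_reach.py` (stratified reach with CIs), and a thin CLI:

```
mediareach simulate --seed 1 --out sim/
mediareach code-summary --coding sim/coding.csv
mediareach reach --survey sim/survey.csv --strata 11-18,19+
mediareach report --in sim/ --out report/
```

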