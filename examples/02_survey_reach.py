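"""Survey-weighted reach: what share of each age group has seen the videos?

Generates a synthetic ever-seen survey (the real panel microdata are not
public) and estimates the weighted mean proportion of the 32 videos viewed
per stratum, with Kish-effective-sample-size standard errors and 95% CIs.
"""

from mediareach import ADOLESCENTS, ADULTS, mean_proportion_viewed
from mediareach.survey import Stratum
from mediareach.synthetic_data import GeneratorConfig, generate_scenario

scn = generate_scenario(GeneratorConfig(seed=42))
video_ids = [v.video_id for v in scn.videos]

print(f"{'stratum':<14}{'p_bar':>7}{'95% CI':>18}{'n':>7}{'n_eff':>9}")
for s in (ADOLESCENTS, ADULTS, Stratum(11, 19, "female"), Stratum(11, 19, "male"), Stratum(55, None)):
    e = mean_proportion_viewed(scn.respondents, video_ids, s)
    ci = f"({e.ci_low:.3f}, {e.ci_high:.3f})"
    print(f"{s.label:<14}{e.p_bar:>7.3f}{ci:>18}{e.n_respondents:>7}{e.n_effective:>9.1f}")

# p_bar is the weighted mean over respondents of the fraction of the 32
# videos they have ever seen: ~0.22 for adolescents, ~0.06 for adults,
# declining steeply with age and higher for females.
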