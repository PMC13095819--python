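"""Pain-diary analytics: pain volume, period tables and mixed models.

Simulates six subjects' daily diaries (one-month baseline, four study
weeks) with per-period multipliers on paroxysmal pain volume and a
log-normal random subject intercept, then reproduces the outcome
analyses: per-period quartile tables with percent variation vs baseline,
and a random-intercept linear mixed model of the daily percent variation
on study phase (REML, Wald z, ML likelihood-ratio test).
"""

import warnings

import mibci
from mibci.synth import PainSimConfig

cfg = PainSimConfig(n_subjects=6, subject_sd=0.3, seed=5)
diaries = mibci.generate_pain_diaries(cfg)
print(f"{len(diaries)} subjects, {len(diaries[0].days)} diary days each")

table = mibci.summarize_periods(diaries, measure="volume", grouping="pooled")
print("\npooled paroxysmal pain volume (NRS.hours) per period:")
print(table.to_string(index=False,
                      formatters={"variation_pct": "{:+.2f}".format}))

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    res = mibci.fit_phase_lmm(diaries, response="volume_variation")
print("\nmixed model of daily % variation vs baseline (random subject "
      "intercepts):")
print(res.coefficients.round(3).to_string())
print(f"random-intercept variance {res.re_variance:.1f}; "
      f"LRT chi2({res.lrt_df}) = {res.lrt_stat:.1f}, p = {res.lrt_p:.3g}")
print("negative phase coefficients = reduction in paroxysmal pain burden "
      "relative to the pre-intervention month")
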