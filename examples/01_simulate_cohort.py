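"""Generate a synthetic two-time-step heart-failure cohort and inspect it.

The development preset emulates a single-centre registry: 562 patients,
19 candidate covariates (14 invariant, 5 measured at admission and
discharge), ~15% all-cause mortality over a staggered-entry follow-up.
"""

from trajsurv import default_development_config, generate_cohort

config = default_development_config(seed=42)
cohort, true_log_risk = generate_cohort(config)

print(f"patients:        {cohort.n_patients}")
print(f"deaths:          {cohort.n_events} "
      f"({cohort.n_events / cohort.n_patients:.1%})")
print(f"mean follow-up:  {cohort.time.mean():.1f} months "
      f"(sd {cohort.time.std():.1f})")
print(f"covariates:      {len(cohort.specs)} "
      f"({sum(s.timing == 'time_varying' for s in cohort.specs)} time-varying)")
print(f"missing cells:   {cohort.mask.mean():.1%}")

# The generator also returns each patient's true log-risk, the oracle any
# fitted model is trying to recover; higher means earlier expected death.
print(f"true log-risk:   mean {true_log_risk.mean():+.2f}, "
      f"sd {true_log_risk.std():.2f}")
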