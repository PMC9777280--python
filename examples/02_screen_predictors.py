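"""Screen candidate predictors on a development cohort.

The pipeline drops covariates with >20% missingness, mean/mode-imputes
the rest, keeps covariates flagged by either the univariate Cox screen
(p < 0.05) or the cross-validated LASSO Cox screen, thins collinear
columns (|r| >= 0.60, keeping the more prognostic member) and records
Z-score parameters for later reuse on validation data.
"""

from trajsurv import default_development_config, generate_cohort, select_candidates

cohort, _ = generate_cohort(default_development_config(seed=7))
candidates, report = select_candidates(cohort, seed=7)

print(f"candidates ({len(candidates)}): {', '.join(candidates)}")
print("\nper-column univariate hazard ratios (selected columns):")
for col in sorted(report.univariate_significant):
    r = report.univariate_results[col]
    print(f"  {col:<18} HR {r['hazard_ratio']:.2f} "
          f"({r['ci_lower']:.2f}-{r['ci_upper']:.2f})  p = {r['p']:.4f}")
print(f"\nLASSO kept: {', '.join(report.lasso_selected) or '(none)'}")
for kept, dropped, r in report.dropped_collinear:
    print(f"collinear: dropped {dropped} (|r| = {r:.2f} with {kept})")

# a hazard ratio > 1 marks a risk factor (e.g. age, NYHA class), < 1 a
# protective factor (e.g. higher eGFR or blood pressure at discharge)
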