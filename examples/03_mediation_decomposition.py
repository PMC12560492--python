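"""Two-way and four-way mediation decomposition for one analysis cell.

The outcome follows a log-link model with Poisson working likelihood and
sandwich standard errors (risk ratios without a rare-outcome
approximation); the binary mediator follows a logistic model.  Effects
are conditioned at the covariate means of the analysis table.
"""

import seqmediate as sm
from seqmediate.study_pipeline import covariate_means

cohort = sm.generate_cohort(sm.calibrated_config(n_participants=120_000, seed=2))
table = sm.build_analysis_table(cohort, "mi", "abuse", "ever_smoking")

covariates = ("baseline_age", "sex_female", "center", "education_years")
pair = sm.fit_mediation_models(table.df, "y", "a", "m", covariates)
spec = sm.MediationSpec(c=covariate_means(table.df, covariates))

two = sm.two_way_decomposition(pair, spec)
print(f"abuse -> ever smoking -> MI   (n = {len(table)}, "
      f"{int(table.df['y'].sum())} cases)")
for label, e in [("total effect  RR", two.rr_te), ("pure direct   RR", two.rr_pde),
                 ("total indirect RR", two.rr_tie)]:
    print(f"  {label:<18s} {e.estimate:5.2f} [{e.lower:.2f}; {e.upper:.2f}]")
print(f"  proportion mediated {100 * two.pm.estimate:6.2f}% "
      f"[{100 * two.pm.lower:.2f}; {100 * two.pm.upper:.2f}]")

four = sm.four_way_decomposition(pair, spec)
print("\nexcess relative risk, split four ways (sums to RR_TE - 1):")
for label, e in [("controlled direct (CDE)", four.err_cde),
                 ("reference interaction", four.err_intref),
                 ("pure indirect (PIE)", four.err_pie),
                 ("mediated interaction", four.err_intmed)]:
    print(f"  {label:<24s} {e.estimate:+7.4f} [{e.lower:+.4f}; {e.upper:+.4f}]")
total = (four.err_cde.estimate + four.err_intref.estimate + four.err_pie.estimate
         + four.err_intmed.estimate)
print(f"  sum {total:+.4f} = RR_TE - 1 = {two.rr_te.estimate - 1:+.4f}")
print("\na large CDE share means the exposure acts mostly independent of the")
print("mediator; the PIE share is the risk transmitted by shifting smoking")
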