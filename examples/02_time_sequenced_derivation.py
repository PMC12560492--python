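"""Derive a disease-specific analysis table with mediator timing rules.

A mediator only counts if its event is dated strictly before the age at
first diagnosis (cases) or the baseline age (non-cases): a smoker who
started after the MI cannot have mediated it.  The exclusion ledger
accounts for every dropped row by a single reason.
"""

import seqmediate as sm

config = sm.calibrated_config(n_participants=30_000, seed=13)
# inject missingness and time-sequence violations to exercise the rules
config.missingness.cts = 0.05
config.missingness.dx_age = 0.10
config.timing.init_after_dx_fraction = 0.15
cohort = sm.generate_cohort(config)

table = sm.build_analysis_table(cohort, "mi", "abuse", "ever_smoking")
print(f"input rows {table.ledger.n_input}, retained {table.ledger.n_retained}")
print("exclusions:", dict(table.ledger.counts))
print(f"ever smoked (raw)            : {100 * cohort['ever_smoked'].mean():.2f}%")
print(f"smoked before MI (derived)   : {100 * table.df['m'].mean():.2f}%")
print("the derived fraction is lower because initiation after the diagnosis,")
print("injected in 15% of smoking cases here, is coded 0 by the timing filter")

current = sm.build_analysis_table(cohort, "mi", "abuse", "current_smoking")
print(f"\ncurrent-smoking variant: {current.ledger.counts.get('quit_before_diagnosis', 0)} "
      "smokers excluded for quitting before the diagnosis")
print("(never smokers stay the reference group in both variants)")
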