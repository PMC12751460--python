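"""Run the complete pipeline on the default synthetic study cohort.

125 workers (2 one-piece species x 25, 3 forager species x 25), 60 min at
5 fps each.  The pipeline segments bouts per species, fits the duration
families, scores zone occupancy, and tests every response between nesting
types with a nested mixed model (1 | species/colony).
"""

from nestmove import StudyConfig, default_cohort_spec, run_pipeline

config = StudyConfig(cohort=default_cohort_spec())
result = run_pipeline(config, seed=1)

print(result.report)
# The headline check: foragers travel significantly farther (standardized
# by body length), occupy the outer region more, and cross the inner region
# faster and straighter than one-piece nesters.
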