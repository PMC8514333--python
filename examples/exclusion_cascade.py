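"""Show the cohort exclusion cascade on generated encounters.

The generator deliberately plants pre-viable stays, late admissions,
congenital-anomaly codes and data-entry errors; the cascade removes each
at its first failing rule, producing a study-flow-diagram style log.
"""

from nicuvalue.cohort import CohortConfig, apply_exclusions
from nicuvalue.simulate import SimConfig, generate

encounters, _, _ = generate(SimConfig(n_hospitals=6, patients_per_hospital=200,
                                      seed=5))
cohort, log = apply_exclusions(encounters, CohortConfig(min_hospital_volume=100))
print(log.to_frame().to_string(index=False))
print(f"\nanalytic cohort: {len(cohort)} of {len(encounters)} encounters "
      f"at {cohort['hospital_id'].nunique()} hospitals")
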