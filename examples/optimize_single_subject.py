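"""Personalized montage optimization on one synthetic head model.

Builds a single spherical-head subject with a left-prefrontal target patch
(target En 0.25 V/m, weight 10; 0 V/m, weight 2 elsewhere), runs the genetic
electrode-subset search with SLSQP current solves under safety constraints
(<= 2 mA per electrode, <= 4 mA total injected, <= 8 electrodes, balanced),
and prints the optimal montage with its fitness.
"""

import numpy as np

from tesgroup import CohortSpec, OptimizationConfig, generate_cohort, ga_optimize, mean_en

subject = generate_cohort(CohortSpec(n_subjects=1, seed=42, compute_features=False))[0]

config = OptimizationConfig(ga_population=200, seed=42)
result = ga_optimize(subject, config=config)

print(f"subject {subject.subject_id}: optimized in {result.generations_run} generations")
print("montage (mA):")
for lab, cur in sorted(result.montage.currents.items()):
    print(f"  {lab:>4s}: {cur:+.3f}")
print(f"  implicit Cz return: {result.montage.reference_current:+.3f}")
anodal = sum(max(c, 0.0) for c in result.montage.currents.values())
anodal += max(result.montage.reference_current, 0.0)
print(f"total injected (anodal) current: {anodal:.3f} mA")
print(f"NERNI = {result.objective:.4f}  (1 = perfect fit, 0 = no stimulation)")
print(f"<En> on target = {mean_en(result.montage, subject):.4f} V/m "
      f"(target level 0.25 V/m)")
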