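"""Generate a small synthetic saliva-Raman cohort and describe it.

The generator emulates a three-group study (healthy controls, PD, AD):
Lorentzian bands at the canonical salivary peak positions, group-
specific intensity effects, per-subject variability, fluorescence
background, cosmic-ray spikes, and PD clinical scores (UPDRS III, H&Y,
LEDD) tied to a latent disease severity.
"""

import numpy as np

from ramanfp import SyntheticConfig, simulate_cohort

config = SyntheticConfig(n_ctrl=8, n_pd=6, n_ad=4,
                         spectra_per_subject=(5, 8), seed=1)
cohort = simulate_cohort(config)

groups = {}
for record in cohort.subjects.values():
    groups.setdefault(record.group, []).append(record)

print(f"{len(cohort.subjects)} subjects, {len(cohort.spectra)} spectra "
      f"on a {len(cohort.grid)}-point grid "
      f"({cohort.grid[0]:.0f}-{cohort.grid[-1]:.0f} cm^-1)")
for group, records in sorted(groups.items()):
    ages = [r.age for r in records]
    print(f"  {group}: n={len(records)}, age {np.mean(ages):.1f} "
          f"+/- {np.std(ages):.1f}")
pd_scores = [r.updrs3 for r in groups["PD"]]
print(f"  PD UPDRS III scores: {np.round(pd_scores, 1)}")
print("Only PD subjects carry clinical scores; spectra of one subject "
      "share that subject's latent spectral effects.")
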