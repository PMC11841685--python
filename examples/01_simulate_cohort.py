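"""Generate a synthetic ICU cohort and inspect its structure.

Builds a 1000-subject cohort with the default study conditions (22% in-ICU
mortality, severity-linked physiology and chest X-ray findings, surrogate
report/image embeddings) and saves it to disk.
"""

import numpy as np

from icusurv import CohortConfig, generate_cohort, save_cohort

config = CohortConfig(n_subjects=1000, seed=0)
cohort = generate_cohort(config)

print(f"subjects:             {len(cohort)}")
print(f"observed event frac:  {cohort.event_fraction:.3f}  (target {config.target_event_fraction})")
print(f"SAPS-II score:        mean {cohort.saps_scores.mean():.1f}, "
      f"range [{cohort.saps_scores.min()}, {cohort.saps_scores.max()}]")
print(f"abnormal chest X-ray: {(1 - cohort.labels[:, -1]).mean():.2%}")
print(f"median observed time: {np.median(cohort.times):.0f} h")

rec = cohort[0]
print(f"\nfirst subject: id={rec.subject_id}, SAPS-II={rec.saps_score}, "
      f"findings={int(rec.labels[:13].sum())}, tokens={rec.token_embeddings.shape[0]}")

out = save_cohort(cohort, "scratch/example_cohort")
print(f"\nwrote cohort to {out}/ (cohort.csv, embeddings.npz, config.json)")
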