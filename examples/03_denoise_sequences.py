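"""Filter noise diagnoses out of sequences with the attention denoiser.

Trains the semi-supervised double-attention module on a synthetic cohort:
positions whose code is in the influenza-like noise list are labeled 1,
trigger/target positions 0, everything else unlabeled. After training, a
position is kept when its dense score f_s exceeds theta = 0.5. The printed
before/after pair shows noise codes (marked *) being removed.
"""

import numpy as np

from emrbert.pipeline import (PipelineSettings, denoise_cohort, fit_denoiser,
                              prepare_cohort)
from emrbert.synthetic import (CohortConfig, default_noise_codes,
                               default_trigger_spec, generate_cohort)

records, gt = generate_cohort(CohortConfig(n_patients=300), seed=1)
settings = PipelineSettings(spec=default_trigger_spec(),
                            noise_codes=tuple(default_noise_codes()), seed=1)
art = prepare_cohort(records, settings)
model, trace = fit_denoiser(records, art, settings)
print(f"denoiser loss: {trace[0]:.3f} -> {trace[-1]:.3f} "
      f"over {len(trace)} epochs")

denoised = denoise_cohort(records, art, model, settings)
noise = set(default_noise_codes())

kept = dropped_noise = total = total_noise = 0
for r in records:
    raw, dn = art.sequences[r.patient_id], denoised[r.patient_id]
    total += len(raw.D)
    total_noise += sum(c in noise for c in raw.D)
    kept += len(dn.D)
    dropped_noise += (sum(c in noise for c in raw.D)
                      - sum(c in noise for c in dn.D))
print(f"kept {kept}/{total} positions; removed {dropped_noise}/{total_noise}"
      " noise positions")

# show one patient with a decent amount of noise
rec = max(records, key=lambda r: sum(gt.noise_flags[r.patient_id]))
raw = art.sequences[rec.patient_id]
dn = denoised[rec.patient_id]
mark = lambda c: f"{c}*" if c in noise else c
print("\nbefore:", " ".join(mark(c) for c in raw.D[:18]), "...")
print("after: ", " ".join(mark(c) for c in dn.D[:18]), "...")
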