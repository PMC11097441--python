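"""End-to-end disease prediction with and without denoising.

Generates a cohort with a planted rule — patients whose trigger
(hypertension, 401.9) has occurred twice develop a target comorbidity
within one year with 70% probability — then runs the full pipeline
(denoiser -> masked-code + next-sentence pretraining -> fine-tuning) and
the same pipeline with denoising disabled, scoring both on a held-out
split against the generator's ground-truth labels. Takes a few minutes on
one CPU.
"""

from emrbert.pipeline import PipelineSettings, denoising_ablation
from emrbert.synthetic import (CohortConfig, default_noise_codes,
                               default_trigger_spec, generate_cohort)

records, gt = generate_cohort(CohortConfig(n_patients=400), seed=1)
labels = {pid: v for pid, v in gt.nsp_labels.items() if v is not None}
print(f"{len(records)} patients, {len(labels)} scoreable, "
      f"{sum(labels.values())} positive")

settings = PipelineSettings(spec=default_trigger_spec(),
                            noise_codes=tuple(default_noise_codes()), seed=1)
result = denoising_ablation(records, labels, settings)

for name, metrics in (("with denoising", result["denoised"]),
                      ("without denoising", result["raw"])):
    print(f"\n{name}:")
    for k, v in metrics.items():
        print(f"  {k:<10} {v:.3f}" if v is not None else f"  {k:<10} n/a")
print("\nRecall is the headline metric: filtering the influenza-like codes"
      "\nkeeps the trigger history inside the encoder window, so fewer"
      "\ntrue future comorbidity cases are missed.")
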