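# Default trigger/target configuration: unspecified essential hypertension
# (401.9) as the trigger, its six most related chronic conditions as targets.
trigger: "401.9"
targets:
  - "402.9"   # unspecified hypertensive heart disease
  - "414.9"   # chronic ischemic heart disease, unspecified
  - "250.0"   # diabetes mellitus without mention of complication
  - "413.9"   # other and unspecified angina pectoris
  - "272.4"   # other and unspecified hyperlipidemia
  - "401.1"   # benign essential hypertension
k: 2
horizon_days: 365
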