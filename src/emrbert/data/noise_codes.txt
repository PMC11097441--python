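# Influenza-like diseases treated as noise diagnoses (ICD-9), one code per line.
079.89
079.99
460
462
464.00
464.10
464.20
465.0
465.8
465.9
466.0
466.11
466.19
478.9
480.0
480.1
480.2
480.8
480.9
484.8
485
486
487.0
487.1
487.8
490
780.6
784.1
786.2
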