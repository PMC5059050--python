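# ICD-10 prefix or prefix range -> cardiovascular comorbidity flag.
# Ranges ("I20-I25") expand over the numeric part at 3-character level.
I48	atrial_fibrillation
I50	heart_failure
I20-I25	ischemic_heart_disease
I60-I69	stroke_tia
G45	stroke_tia
E10-E11	diabetes
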