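term	agency
diarrhoea	fda
weight decreased	fda
nausea	fda
insomnia	fda
headache	fda
decreased appetite	fda
dizziness	fda
tremor	fda
back pain	fda
anxiety	fda
suicidal ideation	fda
depression	fda
abdominal pain upper	fda
muscle spasms	fda
atrial fibrillation	fda
rash	fda
influenza	fda
nasopharyngitis	fda
neoplasm malignant	fda
lung neoplasm malignant	fda
diarrhoea	canada
weight decreased	canada
nausea	canada
insomnia	canada
headache	canada
decreased appetite	canada
dizziness	canada
tremor	canada
back pain	canada
anxiety	canada
suicidal ideation	canada
depression	canada
abdominal pain upper	canada
muscle spasms	canada
atrial fibrillation	canada
rash	canada
malaise	canada
nervousness	canada
sleep disorder	canada
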