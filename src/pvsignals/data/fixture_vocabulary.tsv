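pt	soc
diarrhoea	gastrointestinal disorders
nausea	gastrointestinal disorders
vomiting	gastrointestinal disorders
abdominal pain upper	gastrointestinal disorders
abdominal discomfort	gastrointestinal disorders
gastritis	gastrointestinal disorders
weight decreased	investigations
heart rate increased	investigations
weight increased	investigations
insomnia	psychiatric disorders
anxiety	psychiatric disorders
depression	psychiatric disorders
suicidal ideation	psychiatric disorders
suicide attempt	psychiatric disorders
nervousness	psychiatric disorders
sleep disorder	psychiatric disorders
depressed mood	psychiatric disorders
headache	nervous system disorders
dizziness	nervous system disorders
tremor	nervous system disorders
dyspnoea	respiratory, thoracic and mediastinal disorders
cough	respiratory, thoracic and mediastinal disorders
chronic obstructive pulmonary disease	respiratory, thoracic and mediastinal disorders
bronchitis chronic	respiratory, thoracic and mediastinal disorders
respiratory distress	respiratory, thoracic and mediastinal disorders
malaise	general disorders and administration site conditions
asthenia	general disorders and administration site conditions
condition aggravated	general disorders and administration site conditions
feeling abnormal	general disorders and administration site conditions
chest pain	general disorders and administration site conditions
influenza like illness	general disorders and administration site conditions
application site pain	general disorders and administration site conditions
drug ineffective	general disorders and administration site conditions
decreased appetite	metabolism and nutrition disorders
back pain	musculoskeletal and connective tissue disorders
muscle spasms	musculoskeletal and connective tissue disorders
myalgia	musculoskeletal and connective tissue disorders
atrial fibrillation	cardiac disorders
tachycardia	cardiac disorders
palpitations	cardiac disorders
rash	skin and subcutaneous tissue disorders
pruritus	skin and subcutaneous tissue disorders
psoriasis	skin and subcutaneous tissue disorders
skin exfoliation	skin and subcutaneous tissue disorders
dermatitis contact	skin and subcutaneous tissue disorders
urticaria	skin and subcutaneous tissue disorders
skin burning sensation	skin and subcutaneous tissue disorders
skin discoloration	skin and subcutaneous tissue disorders
urinary tract infection	infections and infestations
influenza	infections and infestations
nasopharyngitis	infections and infestations
neoplasm malignant	neoplasms benign, malignant and unspecified (incl cysts and polyps)
lung neoplasm malignant	neoplasms benign, malignant and unspecified (incl cysts and polyps)
off label use	injury, poisoning and procedural complications
intentional product misuse	injury, poisoning and procedural complications
medication error	injury, poisoning and procedural complications
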