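variant	canonical
diarrhea	diarrhoea
dyspnea	dyspnoea
influenza-like illness	influenza like illness
upper abdominal pain	abdominal pain upper
weight loss	weight decreased
copd	chronic obstructive pulmonary disease
off-label use	off label use
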