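chronic obstructive pulmonary disease
bronchitis chronic
psoriasis
off label use
off-label use
intentional product misuse
medication error
product use in unapproved indication
drug exposure during pregnancy
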