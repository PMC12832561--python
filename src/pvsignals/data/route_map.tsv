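raw	normalized
oral	oral
po	oral
per os	oral
oral, unspecified	oral
topical	topical
cutaneous	topical
transdermal	topical
dermal	topical
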