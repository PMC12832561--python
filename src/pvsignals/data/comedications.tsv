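formoterol
budesonide/formoterol
mometasone/formoterol
fluticasone/formoterol
budesonide/formoterol/glycopyrrolate
fluticasone/umeclidinium/vilanterol
umeclidinium
vilanterol
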