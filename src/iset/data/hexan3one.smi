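CCC(=O)CCC 3-hexanone
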