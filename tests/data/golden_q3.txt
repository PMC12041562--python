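A female patient who is suspected of having a autosomal recessive disease, presented with these clinical symptoms: short stature, seizures. Rank these genes according to their association with the symptoms of the patient: GENEA, GENEB. In the case of insufficient information, still try to rank these genes by using function, site of expression or information from animal models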