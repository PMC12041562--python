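A patient presented with these clinical symptoms: [phenotypes]. Rank these genes according to their association with the symptoms of the patient: [genes]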