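# Check-COVID: claim verification against scientific literature.
trustworthy_set: ["Support"]
misinformation_set: ["Refute"]
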