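# ESOC COVID-19 misinformation dataset: every category is a misinformation type.
trustworthy_set: []
misinformation_set: ["Conspiracy", "Fake remedy", "False reporting"]
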