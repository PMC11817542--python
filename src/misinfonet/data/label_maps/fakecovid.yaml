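# FakeCOVID: multi-source fact-check verdicts; only verdicts with clear
# polarity are mapped, everything else stays unlabeled.
trustworthy_set:
  - Correct
  - Mostly true
  - "True"
  - News
  - True but
  - Half truth
  - Half true
misinformation_set:
  - Fake
  - Fake news
  - "False"
  - False and misleading
  - Mostly false
  - Misinformation / Conspiracy theory
  - Misleading
  - Misleading/False
  - Not true
  - Scam
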