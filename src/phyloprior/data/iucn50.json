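{
  "LC": 0.00005,
  "NT": 0.004,
  "VU": 0.05,
  "EN": 0.42,
  "CR": 0.97
}
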