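{
  "a": 20.22483,
  "b": -330.5077,
  "c": 33.46082,
  "d": -3.93825,
  "e": -1.322272,
  "ratio_lo": 1.1435899240288547,
  "ratio_hi": 8.878974805766143
}
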