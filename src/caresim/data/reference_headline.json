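{
  "total_cost_billion_usd_2016": 323.0,
  "total_cost_billion_usd_2043": 361.0,
  "informal_cost_billion_usd_2016": 93.1,
  "informal_cost_billion_usd_2043": 103.3
}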