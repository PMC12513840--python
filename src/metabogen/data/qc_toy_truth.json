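{
 "retained": [
  "v0",
  "v1",
  "v2",
  "v3"
 ],
 "excluded": {
  "v4": "missingness",
  "v5": "missingness",
  "v6": "missingness",
  "v7": "allele_balance",
  "v8": "allele_balance",
  "v9": "missingness"
 }
}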