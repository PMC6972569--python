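{
 "table2_elements.tsv": "86d7fb263bf25a4d7902f7c788d5512350c1e59f8177802271f2e47e870f6308",
 "table3_features.tsv": "8cfbf0ddb51947a18d1707af8e6502d3ccc4031a58bce0ec19bc41b02dc8208f"
}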