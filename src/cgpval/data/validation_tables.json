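{
  "description": "Printed concordance counts from the assay validation study (test vs reference method; no true-negative universe).",
  "snv": {"tp": 2957, "fp": 10, "fn": 19},
  "indel": {"tp": 661, "fp": 1, "fn": 12},
  "cna": {"tp": 98, "fp": 0, "fn": 2},
  "fusion": {"tp": 114, "fp": 2, "fn": 5},
  "msi": {"n_concordant": 210, "n_total": 212},
  "snv_truth_n": 2976
}
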