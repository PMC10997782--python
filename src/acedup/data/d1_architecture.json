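{
  "comment": "D1 duplication architecture on chromosome 2R (AgamP4 frame, 1-based inclusive). The region block is the desk-scale simulation window; junction_pcr gives the layout of the diagnostic PCR spanning the amplicon junction (primer sequences are derived from the template at run time).",
  "reference": "2R",
  "region": {"start": 3340001, "end": 3740000},
  "breakpoints": {"five_prime": 3436927, "three_prime": 3639836},
  "amplicon_size_bp": 202910,
  "ace1_gene": {"start": 3484107, "end": 3495790},
  "junction_pcr": {"product_size_bp": 460, "primer_length": 20},
  "read_params": {"read_length": 150, "insert_mean": 350, "insert_sd": 50}
}
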