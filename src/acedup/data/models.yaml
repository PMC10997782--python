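# Canonical ace-1 allele models.  Copy classes: R (G119S resistant copy),
# S (generic susceptible copy), S_D1 (susceptible copy carrying the AvaI
# site diagnostic of the D1(S) sequence).  A heterogeneous duplication
# couples one R and one susceptible copy in tandem amplicons.
models:
  A:                      # basic phenotyping: 3 classes, 3 alleles
    d1_test: false
    alleles:
      - {name: R,  copies: [R]}
      - {name: S,  copies: [S]}
      - {name: D,  copies: [R, S]}
  B:                      # D1 test added: 5 classes, 4 alleles
    d1_test: true
    alleles:
      - {name: R,    copies: [R]}
      - {name: S,    copies: [S]}
      - {name: S_D1, copies: [S_D1]}
      - {name: D1,   copies: [R, S_D1]}
  C:                      # at least one further D allele: 5 classes, 5 alleles
    d1_test: true
    alleles:
      - {name: R,    copies: [R]}
      - {name: S,    copies: [S]}
      - {name: S_D1, copies: [S_D1]}
      - {name: D1,   copies: [R, S_D1]}
      - {name: Di,   copies: [R, S]}
  RS:                     # two-allele Hardy-Weinberg null (LRT baseline)
    d1_test: false
    alleles:
      - {name: R, copies: [R]}
      - {name: S, copies: [S]}
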