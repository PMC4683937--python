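# 167-sample validation cohort composition for the alpha-globin copy-number
# assay. Copy pairs are in assay coordinates: the hybrid -a3.7 fusion gene
# types as an HBA1 copy (3'-anchored primers), so e.g. -a3.7/-a3.7 is (2,0).
# n_pregenotyped counts the samples whose genotype was known before the run;
# the remainder were typed blind.
rows:
  - {genotype: "aa/aa",                 hba1_copies: 2, hba2_copies: 2, count: 54, n_pregenotyped: 30}
  - {genotype: "aa/-a3.7",              hba1_copies: 2, hba2_copies: 1, count: 48, n_pregenotyped: 29}
  - {genotype: "-a3.7/-a3.7",           hba1_copies: 2, hba2_copies: 0, count: 36, n_pregenotyped: 20}
  - {genotype: "aa/-a4.2",              hba1_copies: 2, hba2_copies: 1, count: 2,  n_pregenotyped: 2}
  - {genotype: "-a4.2/-a4.2",           hba1_copies: 2, hba2_copies: 0, count: 1,  n_pregenotyped: 1}
  - {genotype: "-a3.7/-a4.2",           hba1_copies: 2, hba2_copies: 0, count: 3,  n_pregenotyped: 3}
  - {genotype: "-a3.7/--SEA",           hba1_copies: 1, hba2_copies: 0, count: 6,  n_pregenotyped: 3}
  - {genotype: "aa/--Med",              hba1_copies: 1, hba2_copies: 1, count: 2,  n_pregenotyped: 2}
  - {genotype: "aa/--Fil",              hba1_copies: 1, hba2_copies: 1, count: 2,  n_pregenotyped: 2}
  - {genotype: "-(a)20.5",              hba1_copies: 2, hba2_copies: 1, count: 1,  n_pregenotyped: 1}
  - {genotype: "aa/aaa-anti3.7",        hba1_copies: 2, hba2_copies: 3, count: 2,  n_pregenotyped: 2}
  - {genotype: "-a3.7/aIcaria-a",       hba1_copies: 2, hba2_copies: 1, count: 1,  n_pregenotyped: 1}
  - {genotype: "aa/aPolyA1-a",          hba1_copies: 2, hba2_copies: 2, count: 2,  n_pregenotyped: 2}
  - {genotype: "aa/aPolyA2-a",          hba1_copies: 2, hba2_copies: 2, count: 1,  n_pregenotyped: 1}
  - {genotype: "-a3.7/aPolyA1-a",       hba1_copies: 2, hba2_copies: 1, count: 4,  n_pregenotyped: 4}
  - {genotype: "aa/aConstantSpring-a",  hba1_copies: 2, hba2_copies: 2, count: 1,  n_pregenotyped: 1}
  - {genotype: "aCS-a/aCS-a",           hba1_copies: 2, hba2_copies: 2, count: 1,  n_pregenotyped: 1}
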