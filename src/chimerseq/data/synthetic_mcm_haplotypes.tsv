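haplotype_name	allele_name
M1	I-M1-a
M1	I-M1-b
M1	I-M1-c
M1	I-s12
M1	I-s71
M1	II-M1-a
M1	II-M1-b
M2	I-M2-a
M2	I-M2-b
M2	I-M2-c
M2	I-s12
M2	I-s23
M2	II-M2-a
M2	II-M2-b
M3	I-M3-a
M3	I-M3-b
M3	I-M3-c
M3	I-s23
M3	I-s34
M3	II-M3-a
M3	II-M3-b
M4	I-M4-a
M4	I-M4-b
M4	I-M4-c
M4	I-s34
M4	I-s45
M4	II-M4-a
M4	II-M4-b
M5	I-M5-a
M5	I-M5-b
M5	I-M5-c
M5	I-s45
M5	I-s56
M5	II-M5-a
M5	II-M5-b
M6	I-M6-a
M6	I-M6-b
M6	I-M6-c
M6	I-s56
M6	I-s67
M6	II-M6-a
M6	II-M6-b
M7	I-M7-a
M7	I-M7-b
M7	I-M7-c
M7	I-s67
M7	I-s71
M7	II-M7-a
M7	II-M7-b
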