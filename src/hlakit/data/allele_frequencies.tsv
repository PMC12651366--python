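# Illustrative class I allele frequencies used by the synthetic-cohort
# generator. These are plausible magnitudes for common alleles, NOT population
# estimates; per-gene frequencies sum to 1. Editable.
gene	allele	frequency
A	A*02:01	0.28
A	A*01:01	0.15
A	A*03:01	0.13
A	A*24:02	0.12
A	A*11:01	0.08
A	A*26:01	0.05
A	A*29:02	0.04
A	A*30:01	0.03
A	A*31:01	0.03
A	A*32:01	0.03
A	A*68:01	0.03
A	A*23:01	0.03
B	B*07:02	0.14
B	B*08:01	0.11
B	B*44:02	0.10
B	B*44:03	0.08
B	B*35:01	0.08
B	B*15:01	0.07
B	B*40:01	0.07
B	B*18:01	0.06
B	B*51:01	0.06
B	B*27:05	0.05
B	B*57:01	0.05
B	B*14:02	0.04
B	B*38:01	0.04
B	B*49:01	0.05
C	C*07:01	0.15
C	C*07:02	0.15
C	C*04:01	0.12
C	C*06:02	0.10
C	C*03:04	0.09
C	C*05:01	0.08
C	C*03:03	0.07
C	C*08:02	0.06
C	C*12:03	0.06
C	C*01:02	0.05
C	C*02:02	0.04
C	C*16:01	0.03
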