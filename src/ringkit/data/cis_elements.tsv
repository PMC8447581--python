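name	category	pattern
G-box	light response	CACGTG
GT1-motif	light response	GGTTAA
Box 4	light response	ATTAAT
ABRE	hormone response	ACGTG
TGACG-motif	hormone response	TGACG
CGTCA-motif	hormone response	CGTCA
O2-site	growth and development response	GATGAYRTGR
CAT-box	growth and development response	GCCACT
ARE	stress response	AAACCA
LTR	stress response	CCGAAA
MBS	stress response	CAACTG
TC-rich repeats	stress response	ATTTTCTTCA
WUN-motif	stress response	AAATTTCCT
TATA-box	enhanced promoter cis-acting	TATAA
CAAT-box	enhanced promoter cis-acting	CCAAT
W box	binding site cis-acting	TTGACC
MYB	binding site cis-acting	CAACCA
MYC	binding site cis-acting	CATTTG
circadian	other functional cis-acting	CAANNNNATC
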