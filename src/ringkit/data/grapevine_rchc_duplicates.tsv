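gene_a	gene_b	ka	ks	dup_class
VvRCHC5	VvRCHC7	0.143	0.674	tandem
VvRCHC6	VvRCHC5	0.146	0.341	tandem
VvRCHC6	VvRCHC2	0.093	0.191	tandem
VvRCHC7	VvRCHC6	0.080	0.277	tandem
VvRCHC7	VvRCHC2	0.106	0.285	tandem
VvRCHC5	VvRCHC2	0.226	1.102	tandem
VvRCHC23	VvRCHC22	0.017	0.040	tandem
VvRCHC24	VvRCHC23	0.019	0.020	segmental
VvRCHC64	VvRCHC44	0.166	0.929	segmental
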