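gene	dhs_id	cs	faire	h3k4me1	h3k27ac	gata1	nfe2	minp	klfp_k562	klfp_hela	klfp_hek293
KLF1	I	Y	Y	Y	-	-	-	-	-	-	-
KLF1	II	Y	Y	Y*	Y*	Y	-	Y	Y	-	-
KLF1	III	Y	-	Y*	Y*	Y	-	Y	Y	-	-
KLF1	IV	Y	Y	-	Y*	Y	-	Y	Y	-	-
KLF1	V	-	Y	Y*	Y*	-	Y	Y	Y	-	-
KLF2	I	Y	Y	Y	Y	Y	-	Y	Y	-	Y
KLF3	I	Y	Y	Y	Y*	-	-	-	Y	Y	Y
KLF3	II	Y	Y	Y	Y*	-	-	-	-	-	Y
KLF3	III	Y	Y	Y	Y	-	-	Y	Y	-	Y
KLF6	I	Y	Y	Y	Y	-	-	Y	-	-	-
KLF6	II	-	-	Y	Y	-	-	-	Y	-	-
KLF6	III	Y	-	Y	Y*	-	-	-	Y	-	-
KLF6	IV	Y	-	Y	Y*	-	-	Y	Y	-	-
KLF9	I	-	Y	Y*	Y*	Y	-	Y	Y	-	-
KLF9	II	-	Y	Y	-	Y	-	Y	Y	-	-
KLF10	I	-	-	Y*	-	-	-	Y	-	-	-
KLF11	I	Y	Y	Y	Y*	-	-	Y	Y	Y	-
KLF13	I	-	-	Y*	-	-	-	-	-	-	-
KLF13	II	-	-	Y*	-	-	-	Y	-	-	-
KLF13	III	-	-	Y	-	-	-	-	Y	-	-
KLF16	I	-	Y	Y*	Y*	-	-	Y	-	-	-
KLF16	II	Y	Y	Y	Y	-	-	-	-	-	-
KLF17	I	Y	Y	Y*	Y*	-	-	Y	Y	Y	-
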