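allele_id	cys_codon_start	j_motif_start	reading_frame_offset	cdr1_start	cdr1_end	cdr2_start	cdr2_end
IGHD1-26*01							
IGHD2-2*03							
IGHD2-8*01							
IGHD3-10*01							
IGHD6-6*01							
IGHJ3*02		8	2				
IGHJ4*02		6	0				
IGHJ5*01		7	1				
IGHJ6*01		10	1				
IGHV1-18*01	141			60	84	102	126
IGHV1-18*02	141			60	84	102	126
IGHV1-18*04	141			60	84	102	126
IGHV1-2*01	141			60	84	102	126
IGHV3-23*01	141			60	84	102	126
IGHV4-34*01	141			60	84	102	126
IGHV4-39*01	141			60	84	102	126
IGHV5-51*01	141			60	84	102	126
IGKJ1*01		6	0				
IGKJ2*01		8	2				
IGKJ4*01		7	1				
IGKV1-5*01	141			60	84	102	126
IGKV2-28*01	141			60	84	102	126
IGKV3-20*01	141			60	84	102	126
IGKV4-1*01	141			60	84	102	126
IGLJ1*01		6	0				
IGLJ2*01		8	2				
IGLJ3*01		7	1				
IGLJ3*02		7	1				
IGLV1-40*01	141			60	84	102	126
IGLV1-40*02	141			60	84	102	126
IGLV1-44*01	141			60	84	102	126
IGLV2-11*01	141			60	84	102	126
IGLV3-1*01	141			60	84	102	126
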