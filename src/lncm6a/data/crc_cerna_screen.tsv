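transcript_id	fold_change	regulation	disease
ENST00000515531	50.20	hypomethylated	colon cancer
ENST00000433644	12.21	hypermethylated	CRC
ENST00000572453	11.04	hypomethylated	CRC
NR_122111	8.911	hypermethylated	CRC
ENST00000498432	10.44	hypomethylated	CRC
NR_038407	7.37	hypermethylated	CRC
NR_103553	8.88	hypomethylated	CRC
NR_026788	8.45	hypomethylated	CRC
ENST00000566997	-Inf	down-expression	CRC
ENST00000578293	9.72	down-expression	CRC
ENST00000537616	5.45	down-expression	CRC
ENST00000515403	4.27	down-expression	CRC
NR_001566	3.57	up-expression	colon cancer
ENST00000565519	3.39	up-expression	CRC
NR_024006	3.07	down-expression	CRC
NR_103783	2.79	up-expression	CRC
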