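name	role	sequence	amidated
HIV-TAT	Control(+)	YGRKKRRQRRR	yes
Antennapedia	Control(+)	RQIKIWFQNRRMKWKK	yes
Pep-1	Control(+)	KETWWETWWTEWSQPKKKRKV	yes
negative-1	Control(-)	TCSSNCQTCPCSSNNCQ	yes
negative-2	Control(-)	GLALLGIAVAILVVL	yes
negative-3	Control(-)	PGNIQMMSVVSMSMTITN	yes
peptide-1	Predicted CPP	FKIYDKKVRTRVVKH	yes
peptide-2	Predicted CPP	RASKRDGSWVKKLHRILE	yes
peptide-3	Predicted CPP	KGTYKKKLMRIPLKGT	yes
peptide-4	Predicted CPP	LYKKGPAKKGRPPLRGWFH	yes
peptide-5	Predicted Non-CPP	FFSLPPVTQDWNSD	yes
peptide-6	Predicted Non-CPP	HSPIIPLGTRFVCHGVT	yes
TP13	Known Non-CPP-CPP Analog	LNSAGYLLGKALAALAKKIL	yes
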