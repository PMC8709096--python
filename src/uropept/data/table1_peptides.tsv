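peptide_id	sequence	protein_id	start	stop	avg_rel_abundance
e13403	FLSSLTETIEGVDAEDGHGPGEQQ	CFB	234	257	51.86
e11594	LSSLTETIEGVDAEDGHGPGEQ	CFB	235	256	186.82
e11703	SSLTETIEGVDAEDGHGPGEQQ	CFB	236	257	79.35
e12606	LSSLTETIEGVDAEDGHGPGEQQ	CFB	236	257	876.10
e10517	LTETIEGVDAEDGHGPGEQQ	CFB	238	257	59.02
e08566	TETIEGVDAEDGHGPGEQ	CFB	239	256	434.59
e09682	TETIEGVDAEDGHGPGEQQ	CFB	239	257	109.77
e08161	TLTKAPADLRGVAHNNL	C4B	1201	1217	51.00
e06142	TKAPADLRGVAHNNL	C4B	1203	1217	98.92
e09265	DELPAKDDPDAPLQPVTP	C4B	1423	1440	134.67
e08035	TLTKAPVDLLGVAHNNL	C4A	1201	1217	74.57
e03984	APVDLLGVAHNNL	C4A	1205	1217	22.80
e00117	LGVAHNNL	C4A	1210	1217	116.12
e09429	EGVQKEDIPPADLSDQVP	C3	955	972	882.83
e16041	EGVQKEDIPPADLSDQVPDTESETRIL	C3	955	981	169.49
e17084	EGVQKEDIPPADLSDQVPDTESETRILLQ	C3	955	983	56.92
e18666	EGVQKEDIPPADLSDQVPDTESETRILLQGTPVA	C3	955	988	4.08
e12939	LQGTPVAQMTEDAVDAERLKHL	C3	982	1003	3066.93
e06787	IGGLRNNNEKDMALT	C3	1130	1144	154.90
e14381	LTTAKDKNRWEDPGKQLYNVEAT	C3	1211	1233	79.81
e16109	LTTAKDKNRWEDPGKQLYNVEATSYA	C3	1211	1236	74.69
e09686	QALAQYQKDAPDHQELN	C3	1277	1293	152.22
e08849	YQKDAPDHQELNLDVS	C3	1282	1297	80.10
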