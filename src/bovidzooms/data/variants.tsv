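locus_id	sequence	oh	nominal	prime_nominal
COL1a2 978-990	AGQPGAVGPAGIR	0	1150	1166
COL1a2 978-990	TGQPGAVGPAGIR	0	1180	1196
COL1a2 978-990	IGQPGAVGPAGIR	0	1192	1208
COL1a2 978-990	SGQPGAVGPAGIR	0	1166	1182
COL1a2 375-386	EGPVGLPGIDGR	1	1182	-
COL1a2 375-386	EGPAGLPGIDGR	1	1154	-
COL1a2 375-396	EGPVGLPGIDGRPGPIGPAGAR	1	2056	2072
COL1a2 375-396	EGPAGLPGIDGRPGPIGPAGAR	1	2028	2044
COL1a2 484-498	GIPGEFGLPGPAGAR	2	1427	-
COL1a2 484-498	GIPGEFGLPGPAGVR	2	1455	-
COL1a2 889-906	GEPGPAGAVGPAGAVGPR	1	1532	-
COL1a2 889-906	GEPGPVGAVGPAGAVGPR	1	1560	-
COL1a2 889-906	GEPGPAGVVGPAGAVGPR	1	1560	-
COL1a2 889-906	GEPGPVGAVGPTGAVGPR	1	1590	-
COL1a2 889-906	GEPGPVGAVGPVGAVGPR	1	1588	-
COL1a2 889-906	GEPGPVGAIGPAGAVGPR	1	1574	-
COL1a2 502-519	GPPGESGAAGPAGPIGSR	1	1550	-
COL1a2 502-519	GPPGESGAAGPTGPIGSR	1	1580	-
COL1a1 586-618	GLTGPIGPPGPAGAPGDKGEAGPSGPAGPTGAR	2	2853	2869
COL1a1 586-618	GLTGPIGPPGPAGAPGDKGETGPSGPAGPTGAR	2	2883	2899
COL1a1 586-618	GLTGPIGPPGPAGAAGDKGETGPSGPAGPTGAR	2	2857	2873
COL1a2 757-789	GPSGEPGTAGPPGTPGPQGLLGAPGFLGLPGSR	4	3017	3033
COL1a2 757-789	GPSGEPGTAGPPGTPGPQGFLGPPGFLGLPGSR	4	3077	3093
COL1a2 757-789	GPSGEPGTAGPPGTPGPQGLLGPPGFLGLPGSR	4	3043	3059
COL1a2 757-789	GPSGEPGTAGPPGTPGPQGLLGLPGFLGLPGSR	4	3059	3075
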