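locus_id	letter	tryptic_name	chain	start	end	oh	mass_column	prime_column
COL1a1 508-519	P1	-	COL1A1	508	519	-	P1	-
COL1a2 978-990	A	A2T85	COL1A2	978	990	0	A	A'
COL1a2 375-386	-	A2T34	COL1A2	375	386	1	375-386	-
COL1a2 375-396	-	A2T34+35	COL1A2	375	396	1	375-396	375-396'
COL1a2 484-498	B	A2T43	COL1A2	484	498	2	B	-
COL1a2 889-906	-	A2T75	COL1A2	889	906	1	889-906	-
COL1a2 502-519	C	A2T45	COL1A2	502	519	1	C	-
COL1a2 292-309	P2	-	COL1A2	292	309	-	P2	-
COL1a2 793-816	D	-	COL1A2	793	816	-	D	-
COL1a2 454-483	E	-	COL1A2	454	483	-	E	-
COL1a1 586-618	F	A1T55/56	COL1A1	586	618	2	F	F'
COL1a2 757-789	G	A2T67	COL1A2	757	789	4	G	G'
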