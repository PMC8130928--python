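# Non-diagnostic peptides observed across all bovid spectra.  The
# conserved COL1a2 89-130 peptide is sequence-confirmed; the others are
# nominal-only stubs for peaks reported as composite/shared.
label	sequence	oh	nominal
COL1a2 89-130	GPPGASGAPGPQGFQGPPGEPGEPGQTGPAGAR	5	3017
shared-1560	-	-	1560
shared-1586	-	-	1586
shared-2056	-	-	2056
shared-2072	-	-	2072
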