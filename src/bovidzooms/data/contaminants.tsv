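# Common MALDI contaminant masses ([M+H]+, monoisotopic) used by the
# marker uniqueness checks: porcine trypsin autolysis products and human
# keratin tryptic peptides.  Editable; extend as needed.
label	mz
trypsin-autolysis	842.509
trypsin-autolysis	1045.564
trypsin-autolysis	2211.104
trypsin-autolysis	2283.180
keratin	1179.601
keratin	1300.530
keratin	1475.785
keratin	1638.864
keratin	2383.952
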