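# Reference ligand-binding profile fixture for the eight alpha-synuclein
# fibril polymorphs.  Provenance tags: "stated" = binding call or class
# reported directly for this cell; "implied" = entailed by a reported
# statement about the complementary fibrils; "stated-significant" =
# backed by a reported significant paired-t comparison.
fibril	assay	feature	value	provenance
F	AAR-direct	bind	yes	stated
R	AAR-direct	bind	no	stated
f65	AAR-direct	bind	yes	stated
f91	AAR-direct	bind	no	stated
f110	AAR-direct	bind	yes	stated
PD	AAR-direct	bind	yes	stated
MSA	AAR-direct	bind	yes	stated
DLB	AAR-direct	bind	yes	stated
F	ThT/S5H	bind	no	stated
R	ThT/S5H	bind	no	stated
f65	ThT/S5H	bind	no	stated
f91	ThT/S5H	bind	yes	stated
f110	ThT/S5H	bind	no	stated
PD	ThT/S5H	bind	yes	stated
MSA	ThT/S5H	bind	yes	stated
DLB	ThT/S5H	bind	yes	stated
F	ThT/BTA	bind	no	stated
R	ThT/BTA	bind	no	stated
f65	ThT/BTA	bind	yes	stated
f91	ThT/BTA	bind	yes	implied
f110	ThT/BTA	bind	yes	stated
PD	ThT/BTA	bind	yes	implied
MSA	ThT/BTA	bind	yes	implied
DLB	ThT/BTA	bind	yes	implied
F	ThT/OXI	bind	yes	implied
R	ThT/OXI	bind	yes	stated
f65	ThT/OXI	bind	yes	stated
f91	ThT/OXI	bind	yes	stated
f110	ThT/OXI	bind	yes	stated
PD	ThT/OXI	bind	yes	implied
MSA	ThT/OXI	bind	yes	implied
DLB	ThT/OXI	bind	yes	implied
F	ThT/OXI	bs1_class	high	stated
R	ThT/OXI	bs1_class	low	stated
f65	ThT/OXI	bs1_class	high	stated
f91	ThT/OXI	bs1_class	high	stated
f110	ThT/OXI	bs1_class	low	stated
PD	ThT/OXI	bs1_class	high	stated
MSA	ThT/OXI	bs1_class	high	stated
DLB	ThT/OXI	bs1_class	high	stated
PD	ThT/S5H	kd_rank	lowest	stated-significant
MSA	ThT/S5H	kd_rank	other	stated
DLB	ThT/S5H	kd_rank	other	stated
MSA	AAR-direct	kd_rank	lower	stated-significant
DLB	AAR-direct	kd_rank	higher	stated
PD	ThT/S5H	kd_sig_vs	MSA	stated-significant
PD	ThT/S5H	kd_sig_vs	DLB	stated-significant
MSA	AAR-direct	kd_sig_vs	PD	stated-significant
MSA	AAR-direct	kd_sig_vs	DLB	stated-significant
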