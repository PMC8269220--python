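# Standard molal Gibbs energies of formation at 25 C, 1 bar (kJ/mol),
# SUPCRT92-consistent compilation (Helgeson-school values, cal -> kJ x 4.184).
# ion_size_A: Debye-Hueckel a-parameter (Kielland 1937); blank -> default 4.0
# for ions, unused for neutral/liquid species. dGf0 blank -> unavailable
# (species usable for NOSC/balance bookkeeping only).
name	formula	charge	dGf0_kJ_mol	ion_size_A	phase
H2O	H2O	0	-237.183		liquid
H+	H	1	0.0	9.0	aqueous
OH-	HO	-1	-157.297	3.5	aqueous
O2	O2	0	16.544		aqueous
CO2	CO2	0	-385.974		aqueous
HCO3-	CHO3	-1	-586.940	4.0	aqueous
CO3-2	CO3	-2	-527.983	4.5	aqueous
SO4-2	O4S	-2	-744.459	4.0	aqueous
S2O3-2	O3S2	-2	-522.582	4.0	aqueous
HS-	HS	-1	11.966	3.5	aqueous
H2S	H2S	0	-27.920		aqueous
NH4+	H4N	1	-79.454	2.5	aqueous
Na+	Na	1	-261.881	4.0	aqueous
Cl-	Cl	-1	-131.290	3.0	aqueous
methane	CH4	0	-34.354		aqueous
methanol	CH4O	0	-175.310		aqueous
formate	CHO2	-1	-350.879	3.5	aqueous
acetate	C2H3O2	-1	-369.322	4.5	aqueous
glucose	C6H12O6	0	-915.900		aqueous
glycine	C2H5NO2	0			aqueous
pyruvate	C3H3O3	-1		4.0	aqueous
succinate	C4H4O4	-2		4.5	aqueous
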