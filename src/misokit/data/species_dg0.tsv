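# Standard Gibbs free energies of formation at 25 C, 1 bar, for the chemical
# species of the iron/sulfur redox reactions handled by misokit.energetics.
# Values (kJ/mol) are from the NBS thermochemical tables (Wagman et al. 1982)
# and standard aquatic-chemistry compilations (Stumm & Morgan 1996).
# Ferrihydrite is treated compositionally as Fe(OH)3 with the free energy of
# amorphous ferric hydroxide; users may override any row with a custom table.
# phase: aqueous | solid | water | gas
name	formula	charge	phase	dGf0_kJ_mol
H2O	H2O	0	water	-237.18
H+	H	1	aqueous	0.0
OH-	OH	-1	aqueous	-157.29
H2S	H2S	0	aqueous	-27.87
HS-	HS	-1	aqueous	12.05
S2-	S	-2	aqueous	85.8
S0	S	0	solid	0.0
SO4-2	SO4	-2	aqueous	-744.0
S2O3-2	S2O3	-2	aqueous	-522.5
Fe2+	Fe	2	aqueous	-78.87
Fe3+	Fe	3	aqueous	-4.6
Fe(OH)3	Fe(OH)3	0	solid	-699.0
FeS	FeS	0	solid	-93.3
CO2	CO2	0	aqueous	-385.98
HCOO-	CHO2	-1	aqueous	-351.0
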