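# Joback-Reid group contributions to the normal boiling point (Kelvin).
# Columns: group name, SMARTS, tb contribution. Assignment walks rows top to
# bottom (most specific first); a match counts only if none of its atoms has
# been claimed by an earlier group, and then claims all its atoms.
# Recursive SMARTS are used where a group should claim a single atom.
group	smarts	tb
carboxylic_acid	[CX3](=[OX1])[OX2H1]	169.09
ester	[CX3](=[OX1])[OX2H0]	81.10
aldehyde	[CX3H1](=[OX1])	72.24
nitro	[NX3](~[OX1])~[OX1]	152.54
nitrile	[CX2]#[NX1]	125.66
ketone_ring	[CX3;R](=[OX1])	94.97
ketone	[CX3;!R](=[OX1])	76.75
oxo_other	[OX1]	-10.50
phenol_oh	[OX2H1;$([OX2H1][c])]	76.34
alcohol_oh	[OX2H1]	92.88
ether_ring	[OX2H0;R]	31.22
ether	[OX2H0;!R]	22.42
amine_primary	[NX3H2]	73.23
amine_secondary_ring	[#7X3H1;R]	52.82
amine_secondary	[NX3H1;!R]	50.17
imine_nh	[NX2H1]	83.08
n_double_ring	[#7X2H0;R]	57.55
n_double	[#7X2H0;!R]	74.60
amine_tertiary	[#7X3H0;!R]	11.74
thiol	[SX2H1]	63.56
sulfide_ring	[SX2H0;R]	52.10
sulfide	[SX2H0;!R]	68.78
fluorine	[F]	-0.03
chlorine	[Cl]	38.13
bromine	[Br]	66.86
iodine	[I]	93.84
allene_c	[CX2H0;$([CX2H0](=*)=*)]	26.15
alkyne_ch	[CX2H1;$([CX2H1]#*)]	9.20
alkyne_c	[CX2H0;$([CX2H0]#*)]	27.38
ch2_double	[CX3H2]	18.18
ch_double_ring	[#6X3H1;R]	26.73
c_double_ring	[#6X3H0;R]	31.01
ch_double	[#6X3H1;!R]	24.96
c_double	[#6X3H0;!R]	24.14
ch3	[CX4H3]	23.58
ch2_ring	[CX4H2;R]	27.15
ch2	[CX4H2;!R]	22.88
ch_ring	[CX4H1;R]	21.78
ch	[CX4H1;!R]	21.74
c_ring	[CX4H0;R]	21.32
c	[CX4H0;!R]	18.25
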