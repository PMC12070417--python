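# Element constants used throughout the package.
# monoisotopic_mass_da: mass of the most abundant isotope (IUPAC 2021), Da.
# atomic_weight: conventional standard atomic weight, used only for bulk
#   elemental-analysis (weight-percent) arithmetic.
# The row "e-" is the electron rest mass (CODATA), needed for ion m/z.
element	monoisotopic_mass_da	atomic_weight
C	12.0	12.011
H	1.007825031898	1.008
N	14.003074004251	14.007
O	15.994914619257	15.999
S	31.972071174414	32.06
e-	0.000548579909	0.000548579909
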