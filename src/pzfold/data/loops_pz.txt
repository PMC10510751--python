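# Measured loop increments involving P/Z printed in the primary report, plus
# the rule constants used to extrapolate every remaining loop entry of the
# DNA-PZ alphabet.  Units: kcal/mol at 37 C.
# columns: closing_top closing_bottom mm_top mm_bottom dG37
[measured_terminal_mismatch]
T A Z Z -0.91
G C Z Z -0.76
T A P P -0.51
# columns: side(5p|3p) closing_top closing_bottom dangle dG37
[measured_dangle]
5p A T Z -0.8
5p C G P -0.37
# Extrapolation rule constants.
[rules]
# canonical A/C/G/T dangle on a P-Z (or Z-P) terminal pair, by side
dangle_canonical_on_pz_5p -0.1
dangle_canonical_on_pz_3p -0.1
# unmeasured P and Z dangling ends, by side (means of the measured values)
dangle_P_5p -0.5
dangle_P_3p 0.1
dangle_Z_5p -0.7
dangle_Z_3p -0.1
# unmeasured P-P and Z-Z terminal mismatches (means of the measured values)
tm_PP -0.5
tm_ZZ -0.8
# terminal mismatches on P-Z, Z-G or G-Z closing pairs (other than PP/ZZ)
tm_on_pz_closing -0.2
# stabilization added per P/Z-containing mismatch in 1x1/2x1/2x2 loops
int_pz_stabilizer -0.6
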