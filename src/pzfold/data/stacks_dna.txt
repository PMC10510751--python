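# Canonical DNA helix nearest-neighbor parameters, unified compilation
# (SantaLucia & Hicks 2004; the same values ship with the RNAstructure DNA tables).
# Stacks written top strand 5'->3' over bottom strand 3'->5'.
# columns: top bottom dG37[kcal/mol] dH[kcal/mol] dS[cal/(mol.K)]
[stacks]
AA TT -1.00 -7.6 -21.3
AT TA -0.88 -7.2 -20.4
TA AT -0.58 -7.2 -21.3
CA GT -1.45 -8.5 -22.7
GT CA -1.44 -8.4 -22.4
CT GA -1.28 -7.8 -21.0
GA CT -1.30 -8.2 -22.2
CG GC -2.17 -10.6 -27.2
GC CG -2.24 -9.8 -24.4
GG CC -1.84 -8.0 -19.9
# columns: name dG37 dH dS
[penalties]
intermolecular_initiation 1.96 0.2 -5.7
symmetry_correction 0.43 0.0 -1.4
terminal_AT 0.05 2.2 6.9
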