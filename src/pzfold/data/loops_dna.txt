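# Canonical DNA loop parameters at 37 C.  Units: kcal/mol.
# Loop-length initiation increments follow the unified DNA compilation
# (SantaLucia & Hicks 2004); lengths between tabulated sizes are interpolated
# with the Jacobson-Stockmayer form.  Dangling-end and mismatch content terms
# are coarse representative values chosen inside the published DNA ranges;
# they are configuration data and can be replaced entry-by-entry through an
# overlay file.
# '.'  = not defined at that size.
[lengths]
# size hairpin bulge internal
1 . 4.0 .
2 . 2.9 .
3 3.5 3.1 3.2
4 3.5 3.2 3.6
5 3.3 3.3 4.0
6 4.0 3.5 4.4
7 4.2 3.7 4.6
8 4.3 3.9 4.8
9 4.5 4.1 4.9
10 4.6 4.3 4.9
12 5.0 4.5 5.2
14 5.1 4.8 5.4
16 5.3 5.0 5.6
18 5.5 5.2 5.8
20 5.7 5.3 5.9
25 6.1 5.6 6.3
30 6.3 5.9 6.6
[multibranch]
offset 3.4
per_branch 0.4
per_unpaired 0.0
[internal_asymmetry]
per_nt 0.3
max 3.0
# Single nucleotides stacked 5' of a helix-terminal pair.
# columns: closing_top closing_bottom dangle dG37
[dangle5]
A T A -0.5
A T C -0.2
A T G -0.4
A T T -0.3
T A A -0.4
T A C -0.2
T A G -0.3
T A T -0.2
C G A -0.9
C G C -0.6
C G G -0.7
C G T -0.5
G C A -0.6
G C C -0.4
G C G -0.5
G C T -0.4
[dangle3]
A T A -0.4
A T C -0.1
A T G -0.3
A T T -0.2
T A A -0.3
T A C -0.1
T A G -0.2
T A T -0.1
C G A -1.0
C G C -0.6
C G G -0.8
C G T -0.4
G C A -0.5
G C C -0.3
G C G -0.4
G C T -0.3
# Terminal-mismatch increment when no specific entry exists.
# columns: closing_top closing_bottom dG37
[terminal_mismatch_default]
G C -0.7
C G -0.7
A T -0.3
T A -0.3
# columns: closing_top closing_bottom mm_top mm_bottom dG37
[terminal_mismatch]
G C C C -0.75
C G C C -0.75
G C T T -0.75
C G T T -0.75
G C A A -1.06
C G A A -1.06
G C G G -1.06
C G G G -1.06
T A G G -0.50
A T G G -0.50
T A A A -0.50
A T A A -0.50
T A C C -0.25
A T C C -0.25
T A T T -0.25
A T T T -0.25
# 1x1 internal-loop content term by unordered mismatch identity.
[int11_mismatch]
A A 0.61
A C 1.33
A G 0.14
C C 1.33
C T 1.05
G G -0.13
G T 0.44
T T 0.64
A T 0.30
C G 0.30
# Added once per closing pair of a 1x1/2x1/2x2 internal loop.
[int11_closing_adjust]
G C 0.0
C G 0.0
A T 0.35
T A 0.35
[int21]
base 2.4
# 2x2 internal-loop per-mismatch content term.
[int22_mismatch]
A A 0.2
A C 0.6
A G -0.1
C C 0.7
C T 0.5
G G -0.4
G T 0.1
T T 0.3
A T 0.2
C G 0.2
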