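# P-Z stack nearest-neighbor free-energy parameters at 37 C.
# Each stack contains at least one P-Z pair; the other pair is Watson-Crick-
# Franklin or a second P-Z.  Stacks written top strand 5'->3' over bottom
# strand 3'->5'; one row per rotationally unique stack (11 total).
# The free-energy increment for terminal P-Z pairs is 0 kcal/mol.
# columns: top bottom dG37[kcal/mol] stderr_dG37[kcal/mol]
[stacks]
AZ TP -1.44 0.17
TP AZ -1.45 0.15
TZ AP -1.49 0.15
PZ ZP -1.57 0.33
GZ CP -1.74 0.16
AP TZ -1.85 0.16
CZ GP -2.07 0.13
GP CZ -2.28 0.16
PP ZZ -2.35 0.13
CP GZ -2.77 0.16
ZP PZ -3.35 0.32
[penalties]
terminal_PZ 0.0
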