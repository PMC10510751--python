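# G-Z wobble stack nearest-neighbor free-energy parameters at 37 C.
# Each stack contains at least one G-Z pair stacked on an A-T, G-C, P-Z or
# second G-Z pair.  One row per rotationally unique stack (15 total).
# No enthalpy/entropy parameters are fitted for G-Z stacks.
# columns: top bottom dG37[kcal/mol] stderr_dG37[kcal/mol]
[stacks]
GZ ZG 1.70 0.48
GA ZT 0.33 0.27
GG ZZ 0.26 0.14
CZ GG -0.17 0.26
GP ZZ -0.50 0.28
AG TZ -0.58 0.14
GG CZ -0.75 0.20
AZ TG -1.16 0.10
TG AZ -1.40 0.24
ZG GZ -1.67 0.41
CG GZ -1.79 0.26
GZ ZP -1.81 0.28
ZP GZ -1.85 0.20
GZ CG -2.07 0.17
PG ZZ -2.47 0.24
[penalties]
terminal_GZ 0.0
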