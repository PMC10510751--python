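# Methods

This note documents the models implemented in `pzfold`, the choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not emulate. Energies are kcal/mol at the reference temperature
310.15 K (37 °C); entropies are cal/(mol·K); R = 1.987 cal/(mol·K).

## Alphabet and pairing

Six bases: A, C, G, T plus the AEGIS pair P (a purine analog) and Z (a
pyrimidine analog). Two folding alphabets are defined. `canonical-DNA`
allows C–G and A–T; `DNA-PZ` allows C–G, A–T, P–Z and the G–Z wobble, and
never G–T (G–T is less stable than both A–T and G–Z and is treated as a
mismatch in the expanded alphabet). A `canonical-DNA+GT` mode exists for
legacy comparisons, but no G–T stack parameters are packaged; supplying
them requires an overlay file.

Self-complementarity uses strict complements only (C↔G, A↔T, P↔Z), so
duplexes such as (GTPPZZAC)₂ receive the symmetry correction while G–Z is
never treated as a complement.

Helix stacks are written top strand 5′→3′ over bottom strand 3′→5′. A
stack and its 180° rotation are the same physical object; parameters are
stored once under the lexicographically smaller rendering.

## Parameter provenance

- Canonical helix stacks, initiation (+1.96), symmetry correction (+0.43)
  and the terminal A–T penalty (+0.05), with their ΔH°/ΔS° decompositions,
  are transcribed from the unified DNA nearest-neighbor compilation
  (SantaLucia & Hicks 2004), the same values distributed with RNAstructure.
- The 11 P–Z and 15 G–Z stack ΔG°₃₇ values are the package's primary
  payload. Terminal P–Z pairs carry no end correction: fitting with an
  end-penalty column, after removing a single outlier duplex, leaves the
  penalty smaller than its standard error, and the packaged value is 0.
  The terminal G–Z penalty likewise defaults to 0 (the G–U and m⁶A–U
  precedents needed none). G–Z stacks carry no enthalpy parameters, and
  the P–Z stack enthalpies are not packaged; consequently ΔH°/ΔS°/Tm
  prediction is available out of the box only for fully canonical duplexes,
  and folding free energies are defined at 310.15 K only (any other
  temperature raises an error rather than silently extrapolating).
- Canonical *loop content* terms (dangling ends, terminal mismatches, and
  the 1×1/2×1/2×2 mismatch content values) are coarse representative values
  chosen inside published DNA ranges — a handful of them pinned by measured
  means (e.g. C·C/T·T on a G–C closure at −0.75, A·A/G·G on T–A at −0.50).
  They are configuration data, kept in a diffable plain-text dialect
  (`src/pzfold/data/*.txt`, whitespace tables, `.` = unavailable), and any
  entry can be replaced via an overlay without touching code. Loop-length
  increments follow the unified compilation, with Jacobson–Stockmayer
  extrapolation (`+2.44·R·T·ln(n/n₀)`) between and beyond tabulated sizes.

## Loop-table extrapolation for P and Z

The complete six-letter loop tables are assembled at load time, in this
precedence order:

1. measured values verbatim (packaged: Z–Z on T–A −0.91, Z–Z on G–C −0.76,
   P–P on T–A −0.51; 5′ dangling Z on A–T −0.8; 5′ dangling P on C–G
   −0.37); the packaged set contains only main-text-printed values, and a
   supplementary overlay can add more;
2. dangling ends: canonical A/C/G/T dangles on P–Z or Z–P terminal pairs
   default to −0.1 (both sides); unmeasured P dangles are +0.1 (3′) and
   −0.5 (5′); unmeasured Z dangles are −0.1 (3′) and −0.7 (5′). The −0.1
   default is also applied to canonical dangles on G–Z closures, for which
   no rule was stated;
3. terminal mismatches: unmeasured P·P → −0.5, Z·Z → −0.8; any other
   mismatch on a P–Z, Z–P, G–Z or Z–G closing pair → −0.2; P/Z-containing
   mismatches on canonical closures are remapped (below) and looked up in
   the canonical table;
4. 1×1, 2×1 and 2×2 internal loops: map P–Z closures to G–C, G–Z closures
   to A–T, loop P→G and loop Z→C; if a mapped mismatch becomes a
   Watson–Crick–Franklin pair it is remapped to A–C preserving
   purine/pyrimidine orientation; the canonical entry is then stabilized by
   −0.6 kcal/mol per P/Z-containing mismatch (for 2×1 loops, once if any
   loop nucleotide is P or Z);
5. hairpin first-mismatch, large-internal-loop end-mismatch and coaxial
   mismatch tables reuse the terminal-mismatch values.

After assembly every legal query resolves to a finite value; a gap raises
at load time, naming the entry. Internal-loop position dependence is not
modeled: the 1×1 values represent centrally placed (most destabilizing)
mismatches, a known limitation shared with the canonical DNA tables.

The table statistics reported by `table_statistics` substitute P→G, Z→C to
find each P–Z stack's canonical analog; the mean ΔΔG°₃₇ per P–Z
substitution is −0.19 (−0.2 at the printed precision), and the 5′/3′-Z
family means over the XP/YZ and XZ/YP renderings are −2.34 and −1.78. For
G–Z stacks a documented rendering-based partition (a stack joins the 5′-Z
group when the Z of a G–Z column has a 3′ neighbor within the stack) gives
−1.28/−0.43; the partition used for the published 5′/3′ averages is
ambiguous, so these two numbers are reported only under this explicit
convention.

## Duplex model

Predicted duplex stability is the sum of interior stacks, intermolecular
initiation, the symmetry correction (self-complementary duplexes only),
terminal-pair penalties at the outermost paired columns, and motif
increments for single-nucleotide overhangs (dangles), terminal mismatches
and isolated interior 1×1 mismatches. Larger interior loops are outside
the duplex model and belong to the folding engine. Motif increments follow
the reference-subtraction convention: ΔG°(motif) = ΔG°(duplex with motif) −
ΔG°(reference helix), with the reference predicted by the model (for
internal loops, the flanking-stack sum may be supplied directly). Terminal
pair penalties are applied at the outermost paired columns even when a
terminal mismatch sits beyond them; since motif and reference share those
columns, increments are insensitive to this convention.

## Folding engine

The single-strand energy model is loop-decomposable: helix stacks; hairpin
loops (length increment, plus a first-mismatch term for loops of ≥4
nucleotides); bulges (the flanking stack is retained across 1-nt bulges);
1×1/2×1/2×2 internal loops from their sequence tables; larger internal
loops (length + asymmetry at 0.3 kcal/mol per unpaired-count difference,
capped at 3.0, + end mismatches at both closures), capped at 30 unpaired
nucleotides; multibranch loops with the linear model a + b·(helices) +
c·(unpaired) using a = 3.4, b = 0.4, c = 0.0 (unchanged for P/Z — no
multibranch measurements exist); and exterior loops. Minimum hairpin size
is 3; isolated base pairs are allowed (the designer can reject targets
containing them, but the thermodynamic model always permits them).

Dangling ends use the always-counted convention: every branch pair in an
exterior or multibranch loop receives its 5′/3′ dangle increments from the
neighboring positions whenever they exist, paired or not, and multibranch
closing pairs receive inner-side dangles. Terminal-pair penalties are
charged whenever a pair closes any loop other than a stack. This makes
every term local, so the McCaskill-style inside recursions (pair,
multibranch-segment and exterior matrices) decompose the model exactly;
pair probabilities come from the matching outside recursion. Coaxial
stacking is not modeled. The heavy kernels are numba-compiled; a 122-nt
partition function with probabilities runs in ~50 ms. Partition-function
weights are held in unscaled float64, which overflows for very long, very
stable sequences; the intended regime (≤ a few hundred nucleotides) is
safe.

Correctness is established against a brute-force oracle: for sequences of
length ≤ 14 every pseudoknot-free structure is enumerated and scored with
the loop-decomposition energy function, and Q, p(i,j), q(i), NED and the
MFE must agree with the dynamic programs to 1e−9. The MFE traceback is
deterministic (hairpin preferred over interior loops, enumerated by
increasing k then l, over multibranch closures).

NED follows the ensemble-defect definition: for a target-paired position,
Pᵢ = p(i, partner(i)); for a target-unpaired position, Pᵢ = q(i);
NED = mean(1 − Pᵢ).

## Stack-parameter regression

Per-duplex stabilities are reduced by all fixed contributions (canonical
stacks, initiation, symmetry, terminal A–T penalties) and regressed on
occurrence counts of the free stacks, with rotational symmetry collapsed
so PP/ZZ and ZZ/PP increment one column. Stages: `pz` (free: P–Z stacks),
`gz` (free: G–Z stacks; canonical and P–Z fixed), and `dh-pz`/`ds-pz`
(the same design against ΔH°/ΔS° responses). The regression is ordinary
least squares (statsmodels), unweighted by default with an optional
weights path left to the caller; parameter uncertainties are the standard
errors of the regression. Rank deficiency is detected and reported with
the names of the unidentifiable terms. Outlier exclusion is explicit and
by duplex id — the report ranks residuals but applies no automatic
threshold, because the historical removal was a judgment call, not a rule.
The end-penalty report fits with and without a terminal-P–Z column and
reports both estimates, their standard errors and each fit's
largest-residual duplex.

## Global melt-curve fitting

Two-state duplex formation A + B ⇌ AB is solved exactly for unequal strand
concentrations (stable quadratic root), with
K(T) = exp(−(ΔH·1000 − T·ΔS)/(R·T)). Predicted absorbance is

    A(T) = [A]free·bA(T) + [B]free·bB(T)
           + [AB]·((1−h)·(bA(25°C) + bB(25°C)) + m_ds·(T − 25°C)),

where bX(T) are per-molar single-strand baselines (measured curves or the
quadratic-plus-sigmoid parametric family provided), h is the common
hypochromicity and m_ds the common duplex absorbance slope. This split of
duplex absorbance between h and m_ds is the implementation's definition.

The global fit shares six parameters across both melts (ΔH, ΔS, h, m_ds,
and one free concentration per melt — the designated excess strand's); the
other concentration is determined from the total absorbance near the top
of the curve, where the sample is essentially fully melted. The fit is
repeated for all four excess-strand assignments (bounded trust-region
least squares, three jittered seeded starts plus a tight-tolerance polish),
with a soft penalty keeping the designated excess strand non-limiting so
the four assignments are genuinely distinct hypotheses — without it they
span the same model space. Selection: among assignments whose fitted
concentrations deviate ≤15% from nominal (pipetting errors are typically
~5%), the lowest sum of squared residuals wins; if none pass the gate the
lowest-residual fit is returned flagged. More than two concentrations are
supported.

Identifiability note: with *linear* single-strand baselines the assignment
choice is exactly degenerate — a shared shift in h absorbs the strand swap
at every concentration — which is the quantitative reason measured
single-strand curves are preferred over linearly extrapolated trendlines.
Curvature differences between the strands' baselines, expressed mostly in
the melted region, are what identify the composition.

## Synthetic fixtures (study conditions)

- **Duplex datasets** (regression tests): random 6–12-mer all-helix
  duplexes over the expanded alphabet; two deterministic embeddings per
  free stack guarantee coverage before random extras are added; responses
  are model predictions from planted parameter values plus Gaussian noise
  (σ = 0.3 kcal/mol for the headline recovery test, matching
  cross-laboratory reproducibility of optical melting).
- **Melt fixtures**: nominal 1 and 5 µM total strand, 12–95 °C sampled
  every 0.5 °C, Gaussian absorbance noise 3×10⁻⁴ (≈0.3% of signal),
  planted truth ΔH = −70 kcal/mol, ΔS = −190 cal/(mol·K), h = 0.18.
  Baselines: strand A 1.25×10⁵ + 100·T + 5·T² and strand B
  1.0×10⁵ + 600·T − 2.5·T² per mol/L (each rising ~30–40% over the range,
  with opposite curvature). Per-cuvette pipetting errors are Gaussian with
  σ = 5%, truncated at 2σ (gross errors are the kind an experimenter
  catches and repeats), and resampled until the strand imbalance reaches
  the 5% error scale, because the "excess strand" label is undefined as
  the imbalance vanishes. The fixtures do not emulate instrument drift,
  correlated noise or real ss-curve fine structure — passing tests
  demonstrate the estimator's correctness and precision under clean
  two-state conditions, not robustness to non-two-state melting.
- **Design targets**: symmetric "iron-cross"-family structures — `arms`
  branches from a central exterior loop, each arm a 3-bp stem ending in a
  hairpin or in a three-way junction of two further 3-bp hairpin helices.
  These reproduce, at desk scale, the regime where helices are short,
  numerous and symmetric, which is where the canonical alphabet exhausts
  its orthogonal sequence options.

## Designer

Initialization draws each target pair's type from the pair weights (DNA-PZ
default 20/50/30 for P–Z/G–C/A–T; canonical 50/50) with uniform
orientation, and each unpaired position from the loop weights (A/C/G/T =
60/10/10/20; P and Z never appear in loops). Refinement repeatedly selects
one element — a pair (its two positions' defects summed) or an unpaired
position — with probability proportional to its defect contribution,
redraws it from the same biases, and keeps the change only if the NED
strictly decreases, stopping at the threshold (default 0.01), the
iteration cap (default 2000) or an optional wall-time limit. This is a
single-level, defect-weighted stochastic refinement in the spirit of
ensemble-defect optimizers; no hierarchical decomposition or sequence
constraints are implemented. Each attempt uses one named RNG; clock
seeding is used only when no seed is given, and the seed actually used is
always recorded. Batches report lowest and mean NED and mean time — the
two standard evaluation views.

The benchmark test compares best-of-5 NED for DNA-PZ versus canonical DNA
over ten fixture targets at a fixed refinement budget (150 iterations,
threshold 0.01) with a one-sided paired t test at α = 0.05; the companion
Welch test is available for unpaired groups. A fixed budget, rather than
stopping at an accuracy threshold, is used for the comparison because
threshold stopping censors both alphabets at the same value and erases the
contrast the benchmark measures. Problem sizes (83–153 nt, 5 attempts per
mode) keep the full comparison within a few minutes on one core.

## Known limitations

- Canonical loop *content* values are representative, not measured;
  applications needing literature-exact DNA loop increments should supply
  an overlay.
- No coaxial stacking, pseudoknots, salt or pH corrections (all values
  refer to pH 7, 1 M NaCl-equivalent conditions of the source
  compilations); single-mismatch position dependence is not modeled.
- Folding is fixed at 37 °C; Tm prediction requires enthalpy-complete
  duplexes.
- The designer is single-level stochastic refinement; very large or highly
  repetitive targets may need more iterations than the defaults.
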