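"""Two-state duplex formation thermodynamics from the nearest-neighbor model.

A duplex prediction is the sum of the interior helix stacks, the
intermolecular initiation, the symmetry correction for self-complementary
duplexes, terminal-pair penalties (A-T; P-Z and G-Z are zero by default) and
the increments of any terminal motifs (single-nucleotide dangling ends,
terminal mismatches) or isolated interior 1x1 mismatches.  Larger interior
loops belong to the folding engine, not to this module.

Melting temperatures use the two-state relation
Tm = dH * 1000 / (dS + R ln(C_T / x)) with x = 1 for self-complementary
duplexes and x = 4 otherwise (R = 1.987 cal/(mol K)).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

from .alphabet import Sequence, is_self_complementary, parse_sequence
from .parameters import ParameterSet, R_GAS, T_REF, base_index

__all__ = [
    "DuplexSpec",
    "DuplexThermo",
    "duplex_dG37",
    "duplex_thermo",
    "melting_temperature",
    "motif_increment",
]

R_CAL = 1.987  # cal/(mol K)


@dataclass(frozen=True)
class DuplexSpec:
    """Two strands, each 5'->3', hybridizing antiparallel at full length.

    Single-nucleotide overhangs are permitted at each end; interior columns
    must be allowed pairs or isolated single mismatches; end columns may be
    terminal mismatches.
    """

    top: Sequence
    bottom: Sequence

    @classmethod
    def from_strings(cls, top: str, bottom: str) -> "DuplexSpec":
        return cls(parse_sequence(top, "top"), parse_sequence(bottom, "bottom"))

    @classmethod
    def self_duplex(cls, strand: str | Sequence) -> "DuplexSpec":
        seq = parse_sequence(strand) if isinstance(strand, str) else strand
        return cls(seq, seq)

    @property
    def is_self_complementary(self) -> bool:
        return (self.top.bases == self.bottom.bases
                and is_self_complementary(self.top))


@dataclass(frozen=True)
class DuplexThermo:
    dG37: float
    dH: float | None = None
    dS: float | None = None

    def Tm_at(self, C_T: float, self_complementary: bool = False) -> float:
        if self.dH is None or self.dS is None:
            raise ValueError("Tm requires dH and dS")
        return melting_temperature(self, C_T, self_complementary)


def _alignment(spec: DuplexSpec, params: ParameterSet):
    """Column alignment of top against reversed bottom with <=1-nt overhangs.

    Returns (columns, left_overhang, right_overhang) where each overhang is
    None or ('top'|'bottom', base), and columns is a list of (top_base,
    bottom_base) left-to-right with the bottom strand read 3'->5'.
    """
    top = list(spec.top.bases)
    bot = list(reversed(spec.bottom.bases))  # 3'->5' left to right
    nt, nb = len(top), len(bot)

    candidates = []
    for lo_t in (0, 1):
        for lo_b in (0, 1):
            if lo_t and lo_b:
                continue
            L_t = nt - lo_t
            L_b = nb - lo_b
            d = L_t - L_b
            if d in (-1, 0, 1):
                ro_t = d if d > 0 else 0
                ro_b = -d if d < 0 else 0
                L = L_t - ro_t
                if L < 2:
                    continue
                cols = [(top[lo_t + k], bot[lo_b + k]) for k in range(L)]
                score = sum(params.mode.can_pair(a, b) for a, b in cols)
                n_over = lo_t + lo_b + ro_t + ro_b
                candidates.append((score, -n_over, lo_t, lo_b, ro_t, ro_b, cols))
    if not candidates:
        raise ValueError("strand lengths differ by more than one-base overhangs")
    candidates.sort(reverse=True)
    score, _, lo_t, lo_b, ro_t, ro_b, cols = candidates[0]
    left = ("top", top[0]) if lo_t else (("bottom", bot[0]) if lo_b else None)
    right = ("top", top[-1]) if ro_t else (("bottom", bot[-1]) if ro_b else None)
    return cols, left, right


def _walk(spec: DuplexSpec, params: ParameterSet, value):
    """Sum NN terms over the duplex; ``value`` maps term kinds to increments.

    ``value`` is called as value(kind, *args) with kinds 'stack', 'init',
    'symmetry', 'terminal', 'dangle', 'tm', 'int11'.
    """
    cols, left, right = _alignment(spec, params)
    mode = params.mode
    paired = [mode.can_pair(a, b) for a, b in cols]
    n = len(cols)

    # classify mismatch columns
    for idx in range(n):
        if paired[idx]:
            continue
        interior = 0 < idx < n - 1
        if interior:
            if not (paired[idx - 1] and paired[idx + 1]):
                raise ValueError(
                    f"unsupported motif: adjacent mismatches around column {idx + 1}; "
                    "use the folding engine for larger loops")
        else:
            neighbor = 1 if idx == 0 else n - 2
            if not paired[neighbor]:
                raise ValueError("unsupported motif: tandem terminal mismatch")

    total = value("init")
    if spec.is_self_complementary:
        total += value("symmetry")

    # stacks between adjacent paired columns; loop terms at mismatches
    for idx in range(n - 1):
        if paired[idx] and paired[idx + 1]:
            a, b = cols[idx]
            c, d = cols[idx + 1]
            total += value("stack", (a, c), (b, d))
    for idx in range(n):
        if paired[idx]:
            continue
        a, b = cols[idx]
        if idx == 0:
            x, y = cols[1]
            total += value("tm", (y, x), (b, a))  # closing pair seen from the end
        elif idx == n - 1:
            x, y = cols[n - 2]
            total += value("tm", (x, y), (a, b))
        else:
            total += value("int11", cols[idx - 1], (a, b), cols[idx + 1])

    # terminal pair penalties at the outermost paired columns
    first = min(i for i in range(n) if paired[i])
    last = max(i for i in range(n) if paired[i])
    total += value("terminal", cols[first])
    total += value("terminal", cols[last])

    # dangling ends
    if left is not None:
        strand, base = left
        x, y = cols[0]
        if not paired[0]:
            raise ValueError("overhang adjacent to a mismatch is unsupported")
        if strand == "top":
            total += value("dangle", "5p", (x, y), base)
        else:
            total += value("dangle", "3p", (y, x), base)
    if right is not None:
        strand, base = right
        x, y = cols[-1]
        if not paired[-1]:
            raise ValueError("overhang adjacent to a mismatch is unsupported")
        if strand == "top":
            total += value("dangle", "3p", (x, y), base)
        else:
            total += value("dangle", "5p", (y, x), base)
    return total


def duplex_dG37(spec: DuplexSpec, params: ParameterSet) -> float:
    """Predicted duplex formation free energy at 37 C (kcal/mol)."""
    lt = params.loops

    def value(kind, *args):
        if kind == "init":
            return params.penalties.intermolecular_initiation
        if kind == "symmetry":
            return params.penalties.symmetry_correction
        if kind == "stack":
            return params.stack_dG37(*args)
        if kind == "terminal":
            return params.terminal_penalty(*args[0])
        if kind == "dangle":
            return lt.dangling(args[0], args[1], args[2], params.mode)
        if kind == "tm":
            return lt.tm(args[0], args[1], params.mode)
        if kind == "int11":
            c1, mm, c2 = args
            return lt.int11_value(c1, mm, c2, params.mode)
        raise AssertionError(kind)

    return float(_walk(spec, params, value))


def duplex_thermo(spec: DuplexSpec, params: ParameterSet) -> DuplexThermo:
    """dG37 plus dH/dS when every constituent term has enthalpy data.

    G-Z stacks never carry enthalpies; motif increments (dangles, mismatches)
    have no packaged enthalpies either, so dH/dS prediction is available for
    perfectly paired duplexes whose stacks all provide dH/dS.
    """
    dG = duplex_dG37(spec, params)

    def value_h(kind, *args):
        if kind == "init":
            return params.penalties.initiation_dH
        if kind == "symmetry":
            return 0.0
        if kind == "stack":
            return params.stack_dH(*args)
        if kind == "terminal":
            x, y = args[0]
            if frozenset((x, y)) == frozenset("AT"):
                return params.penalties.terminal_AT_dH
            return 0.0
        raise ValueError(
            f"no enthalpy parameters for {kind} motifs; dH/dS prediction "
            "covers perfectly paired duplexes only")

    def value_s(kind, *args):
        if kind == "init":
            return params.penalties.initiation_dS
        if kind == "symmetry":
            return params.penalties.symmetry_dS
        if kind == "stack":
            return params.stack_dS(*args)
        if kind == "terminal":
            x, y = args[0]
            if frozenset((x, y)) == frozenset("AT"):
                return params.penalties.terminal_AT_dS
            return 0.0
        raise ValueError(
            f"no entropy parameters for {kind} motifs; dH/dS prediction "
            "covers perfectly paired duplexes only")

    try:
        dH = float(_walk(spec, params, value_h))
        dS = float(_walk(spec, params, value_s))
    except ValueError as exc:
        raise ValueError(str(exc)) from None
    return DuplexThermo(dG37=dG, dH=dH, dS=dS)


def melting_temperature(thermo: DuplexThermo, C_T: float,
                        self_complementary: bool = False) -> float:
    """Two-state melting temperature in Kelvin at total strand conc C_T (M)."""
    if thermo.dH is None or thermo.dS is None:
        raise ValueError("Tm requires dH and dS")
    if thermo.dH >= 0:
        raise ValueError("not a two-state forming duplex (dH must be negative)")
    x = 1.0 if self_complementary else 4.0
    return thermo.dH * 1000.0 / (thermo.dS + R_CAL * log(C_T / x))


def motif_increment(dG37_measured: float,
                    reference: "DuplexSpec | float",
                    params: ParameterSet | None = None) -> float:
    """Stability increment of a motif by reference subtraction.

    dG(motif) = dG(duplex with motif, measured) - dG(reference), where the
    reference is either the motif-free reference duplex (NN-predicted here)
    or, for internal loops, the precomputed sum of the flanking helical
    stacks passed as a number.
    """
    if isinstance(reference, DuplexSpec):
        if params is None:
            raise ValueError("params required to predict the reference duplex")
        ref = duplex_dG37(reference, params)
    else:
        ref = float(reference)
    return float(dG37_measured - ref)
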