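"""Single-strand secondary-structure free-energy model.

The energy of a structure is the sum over the loops of its loop decomposition:
helix stacks, hairpin loops (length increment plus a first-mismatch term for
loops of four or more nucleotides), bulges (the flanking helix stack is kept
across single-nucleotide bulges), 1x1/2x1/2x2 internal loops from their
sequence tables, larger internal loops (length + asymmetry + an end-mismatch
term at both closing pairs), multibranch loops with the linear
offset/per-branch/per-unpaired model, and exterior-loop terms.

Dangling ends follow the always-counted convention: every branch pair in an
exterior or multibranch loop receives 5' and 3' dangle increments from its
neighboring positions whenever those positions exist, whether or not they are
paired, and the closing pair of a multibranch loop receives its inner-side
dangles.  Helix-terminal pair penalties (A-T; P-Z and G-Z, both zero by
default) are charged whenever a pair closes any loop other than a helix stack.

This convention is purely local, so the dynamic-programming recursions in
:mod:`pzfold.folding` decompose it exactly; :func:`fold_energy` is the
authoritative definition used by the brute-force enumeration oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import Sequence, encode, parse_sequence
from .parameters import BIG, R_GAS, T_REF, ParameterSet

__all__ = ["EnergyModel", "SecondaryStructure", "fold_energy"]

MIN_HAIRPIN = 3
MAX_LOOP = 30


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free secondary structure: 0-based pair set, nested."""

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        seen: set[int] = set()
        plist = sorted(self.pairs)
        for i, j in plist:
            if not (0 <= i < j < self.length):
                raise ValueError(f"pair ({i},{j}) out of range for length {self.length}")
            if i in seen or j in seen:
                raise ValueError(f"index in more than one pair near ({i},{j})")
            seen.update((i, j))
            if j - i - 1 < MIN_HAIRPIN:
                raise ValueError(f"hairpin loop of pair ({i},{j}) shorter than "
                                 f"{MIN_HAIRPIN} nucleotides")
        for a, (i, j) in enumerate(plist):
            for k, l in plist[a + 1:]:
                if k > j:
                    break
                if i < k <= j < l:
                    raise ValueError(f"pseudoknot: pairs ({i},{j}) and ({k},{l}) cross")

    @property
    def partner(self) -> np.ndarray:
        arr = np.full(self.length, -1, dtype=np.int64)
        for i, j in self.pairs:
            arr[i] = j
            arr[j] = i
        return arr

    @classmethod
    def from_pairs_1based(cls, length: int, pairs) -> "SecondaryStructure":
        return cls(length, frozenset((i - 1, j - 1) for i, j in pairs))

    def to_dotbracket(self) -> str:
        out = ["."] * self.length
        for i, j in self.pairs:
            out[i], out[j] = "(", ")"
        return "".join(out)


class EnergyModel:
    """Dense-array view of a :class:`ParameterSet` used for loop scoring."""

    def __init__(self, params: ParameterSet, T: float = T_REF):
        if abs(T - T_REF) > 1e-9:
            raise ValueError(
                "folding free energies are parameterized at 310.15 K only: "
                "G-Z stacks carry no enthalpy parameters and loop enthalpies "
                "are not tabulated, so extrapolation to other temperatures "
                "is not supported"
            )
        self.params = params
        self.T = T
        self.RT = R_GAS * T
        lt = params.loops
        self.allowed = np.ascontiguousarray(params.allowed)
        self.stack = np.ascontiguousarray(params.stack_dG)
        self.endpen = np.ascontiguousarray(params.end_penalty)
        self.d5 = np.ascontiguousarray(lt.dangle5)
        self.d3 = np.ascontiguousarray(lt.dangle3)
        self.tmm = np.ascontiguousarray(lt.terminal_mismatch)
        self.int11 = np.ascontiguousarray(lt.int11)
        self.int21 = np.ascontiguousarray(lt.int21)
        self.int22 = np.ascontiguousarray(lt.int22)
        self.hairpin_len = np.ascontiguousarray(lt.hairpin_len)
        self.bulge_len = np.ascontiguousarray(lt.bulge_len)
        self.internal_len = np.ascontiguousarray(lt.internal_len)
        self.ml_a = lt.ml_offset
        self.ml_b = lt.ml_per_branch
        self.ml_c = lt.ml_per_unpaired
        self.asym_pn = lt.asym_per_nt
        self.asym_max = lt.asym_max

    # -- loop terms (0-based indices into an encoded sequence) --------------

    def can_pair(self, s, i, j) -> bool:
        return bool(self.allowed[s[i], s[j]]) and j - i - 1 >= MIN_HAIRPIN

    def e_hairpin(self, s, i, j) -> float:
        u = j - i - 1
        e = self.hairpin_len[u] + self.endpen[s[i], s[j]]
        if u >= 4:
            e += self.tmm[s[i], s[j], s[i + 1], s[j - 1]]
        return float(e)

    def e_interior(self, s, i, j, k, l) -> float:
        """Stack, bulge or internal loop between closing pairs (i,j), (k,l)."""
        u1 = k - i - 1
        u2 = j - l - 1
        if u1 == 0 and u2 == 0:
            return float(self.stack[s[i], s[j], s[k], s[l]])
        if u1 == 0 or u2 == 0:
            b = u1 + u2
            if b == 1:
                return float(self.bulge_len[1] + self.stack[s[i], s[j], s[k], s[l]])
            return float(self.bulge_len[b] + self.endpen[s[i], s[j]]
                         + self.endpen[s[k], s[l]])
        if u1 == 1 and u2 == 1:
            return float(self.int11[s[i], s[j], s[i + 1], s[j - 1], s[k], s[l]])
        if u1 == 1 and u2 == 2:
            return float(self.int21[s[i], s[j], s[i + 1], s[j - 1], s[j - 2],
                                    s[k], s[l]])
        if u1 == 2 and u2 == 1:
            # rotated rendering: single unpaired nucleotide on the top strand
            return float(self.int21[s[l], s[k], s[j - 1], s[i + 2], s[i + 1],
                                    s[j], s[i]])
        if u1 == 2 and u2 == 2:
            return float(self.int22[s[i], s[j], s[i + 1], s[i + 2],
                                    s[j - 1], s[j - 2], s[k], s[l]])
        asym = min(self.asym_max, self.asym_pn * abs(u1 - u2))
        return float(self.internal_len[u1 + u2] + asym
                     + self.endpen[s[i], s[j]] + self.endpen[s[k], s[l]]
                     + self.tmm[s[i], s[j], s[i + 1], s[j - 1]]
                     + self.tmm[s[l], s[k], s[l + 1], s[k - 1]])

    def e_ml_closing(self, s, i, j) -> float:
        return float(self.ml_a + self.ml_b + self.endpen[s[i], s[j]]
                     + self.d3[s[i], s[j], s[i + 1]]
                     + self.d5[s[j], s[i], s[j - 1]])

    def e_ml_branch(self, s, k, l) -> float:
        return float(self.ml_b + self.endpen[s[k], s[l]]
                     + self.d5[s[k], s[l], s[k - 1]]
                     + self.d3[s[l], s[k], s[l + 1]])

    def e_ext_branch(self, s, i, j, n) -> float:
        e = self.endpen[s[i], s[j]]
        if i > 0:
            e += self.d5[s[i], s[j], s[i - 1]]
        if j < n - 1:
            e += self.d3[s[j], s[i], s[j + 1]]
        return float(e)


def _children(partner: np.ndarray, i: int, j: int) -> tuple[list, int]:
    """Directly nested pairs and unpaired count strictly inside (i, j)."""
    kids = []
    unpaired = 0
    k = i + 1
    while k < j:
        if partner[k] == -1:
            unpaired += 1
            k += 1
        else:
            kids.append((k, int(partner[k])))
            k = int(partner[k]) + 1
    return kids, unpaired


def fold_energy(seq: Sequence | str | np.ndarray,
                structure: SecondaryStructure,
                model: EnergyModel | ParameterSet) -> float:
    """Free energy (kcal/mol, 37 C) of ``structure`` for ``seq``.

    The empty structure is the zero-energy reference state.  Raises
    :class:`ValueError` when the structure contains a disallowed pair.
    """
    if isinstance(model, ParameterSet):
        model = EnergyModel(model)
    s = seq if isinstance(seq, np.ndarray) else encode(seq)
    n = len(s)
    if structure.length != n:
        raise ValueError("structure length does not match sequence length")
    from .alphabet import BASES

    for i, j in structure.pairs:
        if not model.allowed[s[i], s[j]]:
            raise ValueError(
                f"pair ({i + 1},{j + 1}) {BASES[s[i]]}-{BASES[s[j]]} is not an "
                f"allowed pair in {model.params.mode.name}")

    partner = structure.partner
    e = 0.0
    # exterior loop
    k = 0
    while k < n:
        if partner[k] == -1:
            k += 1
            continue
        i, j = k, int(partner[k])
        e += model.e_ext_branch(s, i, j, n)
        k = j + 1
    # per-pair loops
    for i, j in sorted(structure.pairs):
        kids, unpaired = _children(partner, i, j)
        if not kids:
            e += model.e_hairpin(s, i, j)
        elif len(kids) == 1:
            (k2, l2) = kids[0]
            u1, u2 = k2 - i - 1, j - l2 - 1
            if u1 + u2 > MAX_LOOP:
                raise ValueError(
                    f"internal loop at ({i + 1},{j + 1}) has {u1 + u2} unpaired "
                    f"nucleotides; the model caps internal loops at {MAX_LOOP}")
            e += model.e_interior(s, i, j, k2, l2)
        else:
            # a + b per helix (closing + branches) + c per unpaired nucleotide
            e += model.e_ml_closing(s, i, j)
            e += model.ml_c * unpaired
            for (k2, l2) in kids:
                e += model.e_ml_branch(s, k2, l2)
    return float(e)
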