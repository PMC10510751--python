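"""Extended six-letter DNA alphabet: bases, pairing rules, and stack notation.

The alphabet covers the four canonical deoxynucleotides plus the two
second-generation AEGIS bases P (2-amino-imidazo-[1,2-a]-1,3,5-triazin-4(8H)-one,
a purine analog) and Z (6-amino-5-nitro-pyridin-2(1H)-one, a pyrimidine analog).
P and Z form a three-hydrogen-bond pair orthogonal to Watson-Crick-Franklin
pairing; G and Z additionally form a wobble pair comparable in stability to A-T.

Two alphabet modes are supported:

``canonical-DNA``
    allows C-G and A-T pairs (G-T wobble optionally re-enabled for legacy
    comparisons, off by default).
``DNA-PZ``
    allows C-G, A-T, P-Z and G-Z pairs and never G-T.

Helix stacks are written top strand 5'->3' over bottom strand 3'->5', e.g.
``CP/GZ`` is a C-G pair followed by a P-Z pair.  A stack and its 180-degree
rotation are physically identical; :func:`canonical_stack_key` collapses both
renderings onto a single key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "BASES",
    "PURINES",
    "PYRIMIDINES",
    "COMPLEMENT",
    "AlphabetMode",
    "CANONICAL_DNA",
    "DNA_PZ",
    "Sequence",
    "StackKey",
    "parse_sequence",
    "pairing_partner",
    "is_self_complementary",
    "reverse_complement",
    "canonical_stack_key",
    "base_index",
    "encode",
    "decode",
]

#: The six one-letter base codes, in the fixed internal encoding order.
BASES: tuple[str, ...] = ("A", "C", "G", "T", "P", "Z")

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

PURINES = frozenset({"A", "G", "P"})
PYRIMIDINES = frozenset({"C", "T", "Z"})

#: Strict complements used for self-complementarity (G-Z is never a complement).
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "P": "Z", "Z": "P"}


def base_index(code: str) -> int:
    """Return the fixed integer encoding (0-5) of a base code."""
    try:
        return _BASE_INDEX[code]
    except KeyError:
        raise ValueError(f"unknown base code {code!r}") from None


@dataclass(frozen=True)
class AlphabetMode:
    """A folding alphabet: a name and the set of allowed base pairs.

    ``allowed_pairs`` stores ordered tuples; both orientations of every
    allowed pair are present, so membership tests need no normalization.
    """

    name: str
    allowed_pairs: frozenset[tuple[str, str]]

    @staticmethod
    def _expand(pairs: Iterable[tuple[str, str]]) -> frozenset[tuple[str, str]]:
        out = set()
        for a, b in pairs:
            out.add((a, b))
            out.add((b, a))
        return frozenset(out)

    def can_pair(self, a: str, b: str) -> bool:
        return (a, b) in self.allowed_pairs

    def partners(self, a: str) -> frozenset[str]:
        return frozenset(y for (x, y) in self.allowed_pairs if x == a)


def _make_mode(name: str, pairs: list[tuple[str, str]]) -> AlphabetMode:
    return AlphabetMode(name, AlphabetMode._expand(pairs))


#: Canonical DNA: Watson-Crick-Franklin pairs only (G-T off by default).
CANONICAL_DNA = _make_mode("canonical-DNA", [("C", "G"), ("A", "T")])

#: Canonical DNA with the legacy G-T wobble re-enabled.
CANONICAL_DNA_GT = _make_mode("canonical-DNA+GT", [("C", "G"), ("A", "T"), ("G", "T")])

#: The expanded alphabet: C-G, A-T, P-Z and the G-Z wobble; never G-T.
DNA_PZ = _make_mode("DNA-PZ", [("C", "G"), ("A", "T"), ("P", "Z"), ("G", "Z")])

MODES = {m.name: m for m in (CANONICAL_DNA, CANONICAL_DNA_GT, DNA_PZ)}


@dataclass(frozen=True)
class Sequence:
    """An ordered, validated sequence over the six-letter alphabet."""

    bases: tuple[str, ...]
    id: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError("sequence must be nonempty")
        for pos, b in enumerate(self.bases, start=1):
            if b not in _BASE_INDEX:
                raise ValueError(f"unknown base {b!r} at position {pos}")

    def __len__(self) -> int:
        return len(self.bases)

    def __iter__(self) -> Iterator[str]:
        return iter(self.bases)

    def __getitem__(self, i):
        return self.bases[i]

    def __str__(self) -> str:
        return "".join(self.bases)


def parse_sequence(text: str, seq_id: str = "") -> Sequence:
    """Parse ``text`` into a :class:`Sequence`.

    Case-insensitive; interior whitespace is rejected, surrounding whitespace
    stripped.  Unknown symbols raise :class:`ValueError` naming the 1-based
    position and the offending symbol.
    """
    s = text.strip()
    if not s:
        raise ValueError("empty sequence")
    bases = []
    for pos, ch in enumerate(s, start=1):
        up = ch.upper()
        if up not in _BASE_INDEX:
            raise ValueError(f"invalid symbol {ch!r} at position {pos}")
        bases.append(up)
    return Sequence(tuple(bases), id=seq_id)


def pairing_partner(base: str, mode: AlphabetMode) -> frozenset[str]:
    """All bases that ``base`` may pair with under ``mode``."""
    if base not in _BASE_INDEX:
        raise ValueError(f"unknown base code {base!r}")
    return mode.partners(base)


def reverse_complement(seq: Sequence | str) -> Sequence:
    """Strict reverse complement (C<->G, A<->T, P<->Z)."""
    if isinstance(seq, str):
        seq = parse_sequence(seq)
    return Sequence(tuple(COMPLEMENT[b] for b in reversed(seq.bases)), id=seq.id)


def is_self_complementary(seq: Sequence | str, mode: AlphabetMode = DNA_PZ) -> bool:
    """True iff the strand pairs with itself in antiparallel orientation.

    Uses strict complements only (never the G-Z wobble), so e.g. GTPPZZAC is
    self-complementary via P<->Z.  Implies even length.
    """
    if isinstance(seq, str):
        seq = parse_sequence(seq)
    if len(seq) % 2:
        return False
    return seq.bases == reverse_complement(seq).bases


StackKey = tuple[tuple[str, str], tuple[str, str]]


def rotate_stack(top: tuple[str, str], bottom: tuple[str, str]) -> StackKey:
    """The 180-degree rotation of a stack rendering (swap strands, reverse)."""
    return ((bottom[1], bottom[0]), (top[1], top[0]))


def canonical_stack_key(
    top: Iterable[str],
    bottom: Iterable[str],
    mode: AlphabetMode | None = None,
) -> StackKey:
    """Canonical key for a helix stack given top (5'->3') and bottom (3'->5').

    The stack and its rotation map to the same key; the tie-break is the
    lexicographically smaller rendering.  When ``mode`` is given, both columns
    (top1-bottom1 and top2-bottom2) must be allowed pairs.
    """
    top = tuple(top)
    bottom = tuple(bottom)
    if len(top) != 2 or len(bottom) != 2:
        raise ValueError("a stack is two bases on each strand")
    for b in top + bottom:
        if b not in _BASE_INDEX:
            raise ValueError(f"unknown base code {b!r}")
    if mode is not None:
        for col, (x, y) in enumerate(zip(top, bottom), start=1):
            if not mode.can_pair(x, y):
                raise ValueError(
                    f"column {col}: {x}-{y} is not an allowed pair in {mode.name}"
                )
    rot = rotate_stack(top, bottom)
    return min((top, bottom), rot)


def encode(seq: Sequence | str):
    """Encode a sequence as a numpy int8 array in the fixed base order."""
    import numpy as np

    if isinstance(seq, str):
        seq = parse_sequence(seq)
    return np.array([_BASE_INDEX[b] for b in seq.bases], dtype=np.int8)


def decode(codes) -> str:
    """Inverse of :func:`encode`."""
    return "".join(BASES[int(c)] for c in codes)
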