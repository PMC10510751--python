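"""Nearest-neighbor parameter store for the DNA and DNA-PZ alphabets.

Stack free energies (and, for canonical stacks, enthalpies/entropies) are
loaded from packaged plain-text tables.  Complete loop tables over the
six-letter alphabet are assembled at load time from (a) canonical DNA loop
parameters, (b) the measured P/Z loop increments, and (c) a small set of
extrapolation rules:

1. measured values are used verbatim where present;
2. canonical A/C/G/T dangling ends on P-Z terminal pairs default to
   -0.1 kcal/mol; unmeasured P and Z dangles use the means of the measured
   values (3' P +0.1, 5' P -0.5, 3' Z -0.1, 5' Z -0.7);
3. unmeasured P-P terminal mismatches are -0.5, Z-Z are -0.8; any other
   terminal mismatch on a P-Z, Z-P, G-Z or Z-G closing pair is -0.2;
4. 1x1 / 2x1 / 2x2 internal loops map P-Z closures to G-C, G-Z closures to
   A-T, loop P to G, loop Z to C (remapping to A-C, purine-pyrimidine
   orientation preserved, whenever the mapping yields a Watson-Crick-Franklin
   pair), look up the canonical entry, and are stabilized by -0.6 kcal/mol
   per P/Z-containing mismatch;
5. hairpin first-mismatch, large-internal-loop end-mismatch and coaxial
   mismatch terms reuse the terminal-mismatch table.

All energies are kcal/mol at the 310.15 K reference temperature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .alphabet import (
    BASES,
    CANONICAL_DNA,
    DNA_PZ,
    PURINES,
    AlphabetMode,
    StackKey,
    base_index,
    canonical_stack_key,
    rotate_stack,
)

__all__ = [
    "StackParameter",
    "GlobalPenalties",
    "LoopTables",
    "ParameterSet",
    "load_parameter_set",
    "extrapolate_loop_tables",
    "table_statistics",
    "write_stack_table",
    "read_stack_table",
]

T_REF = 310.15  # K
R_GAS = 1.987e-3  # kcal/(mol K)
BIG = 1.0e6  # sentinel for energetically impossible entries

_PZ_SET = frozenset({"P", "Z"})

# P->G, Z->C; canonical bases map to themselves (loop-content remapping).
_BASE_REMAP = {"A": "A", "C": "C", "G": "G", "T": "T", "P": "G", "Z": "C"}
# Closing-pair remapping for internal-loop lookups.
_CLOSING_REMAP = {
    ("P", "Z"): ("G", "C"),
    ("Z", "P"): ("C", "G"),
    ("G", "Z"): ("A", "T"),
    ("Z", "G"): ("T", "A"),
}
_WCF = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


def _remap_mismatch(a: str, b: str) -> tuple[str, str]:
    """Map loop bases to canonical and resolve WCF collisions to A-C."""
    a2, b2 = _BASE_REMAP[a], _BASE_REMAP[b]
    if (a2, b2) in _WCF:
        a2 = "A" if a2 in PURINES else "C"
        b2 = "A" if b2 in PURINES else "C"
    return a2, b2


def _remap_closing(x: str, y: str) -> tuple[str, str]:
    return _CLOSING_REMAP.get((x, y), (x, y))


# ---------------------------------------------------------------------------
# plain-text table dialect


def _parse_sections(text: str) -> dict[str, list[list[str]]]:
    """Parse the whitespace-delimited sectioned dialect used by the data files."""
    sections: dict[str, list[list[str]]] = {}
    current: list[list[str]] | None = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip()
            current = sections.setdefault(name, [])
            continue
        if current is None:
            raise ValueError(f"data line outside any section: {raw!r}")
        current.append(line.split())
    return sections


def _num(tok: str) -> float | None:
    return None if tok == "." else float(tok)


def _read_packaged(name: str) -> str:
    return resources.files("pzfold.data").joinpath(name).read_text()


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class StackParameter:
    """One helix stack: free energy at 37 C plus optional dH/dS and stderr."""

    key: StackKey
    dG37: float
    dH: float | None = None
    dS: float | None = None
    stderr_dG37: float | None = None

    def __post_init__(self) -> None:
        if self.dH is not None and self.dS is not None:
            implied = self.dH - T_REF * self.dS / 1000.0
            if abs(implied - self.dG37) > 0.15:
                raise ValueError(
                    f"stack {self.key}: dH - T*dS = {implied:.3f} disagrees with "
                    f"dG37 = {self.dG37:.3f} beyond rounding slack"
                )


@dataclass(frozen=True)
class GlobalPenalties:
    intermolecular_initiation: float
    symmetry_correction: float
    terminal_AT_penalty: float
    terminal_PZ_penalty: float = 0.0
    terminal_GZ_penalty: float = 0.0
    initiation_dH: float = 0.0
    initiation_dS: float = 0.0
    symmetry_dS: float = 0.0
    terminal_AT_dH: float = 0.0
    terminal_AT_dS: float = 0.0


@dataclass
class LoopTables:
    """Complete loop parameter tables over the six-letter alphabet.

    Dense arrays are indexed by the fixed base encoding (A,C,G,T,P,Z = 0..5).
    Every array is finite on all legal queries after extrapolation; illegal
    closings carry the ``BIG`` sentinel.
    """

    dangle5: np.ndarray  # [x, y, d] : d stacked 5' of x on pair x-y
    dangle3: np.ndarray  # [x, y, d] : d stacked 3' of x on pair x-y
    terminal_mismatch: np.ndarray  # [x, y, a, b]
    int11: np.ndarray  # [x1, y1, a, b, x2, y2]
    int21: np.ndarray  # [x1, y1, a, c1, c2, x2, y2]
    int22: np.ndarray  # [x1, y1, a1, a2, c1, c2, x2, y2]
    hairpin_len: np.ndarray
    bulge_len: np.ndarray
    internal_len: np.ndarray
    ml_offset: float
    ml_per_branch: float
    ml_per_unpaired: float
    asym_per_nt: float
    asym_max: float
    rules: dict[str, float] = field(default_factory=dict)

    # -- checked accessors ---------------------------------------------------

    def _check_pair(self, mode: AlphabetMode, x: str, y: str) -> None:
        if not mode.can_pair(x, y):
            raise KeyError(f"{x}-{y} is not an allowed closing pair in {mode.name}")

    def dangling(self, side: str, closing: tuple[str, str], base: str,
                 mode: AlphabetMode = DNA_PZ) -> float:
        self._check_pair(mode, *closing)
        arr = self.dangle5 if side in ("5p", "5'") else self.dangle3
        v = arr[base_index(closing[0]), base_index(closing[1]), base_index(base)]
        if not np.isfinite(v) or v >= BIG / 2:
            raise KeyError(f"missing dangle entry {side} {closing} {base}")
        return float(v)

    def tm(self, closing: tuple[str, str], mm: tuple[str, str],
           mode: AlphabetMode = DNA_PZ) -> float:
        self._check_pair(mode, *closing)
        v = self.terminal_mismatch[
            base_index(closing[0]), base_index(closing[1]),
            base_index(mm[0]), base_index(mm[1])]
        if not np.isfinite(v) or v >= BIG / 2:
            raise KeyError(f"missing terminal mismatch entry {closing} {mm}")
        return float(v)

    def int11_value(self, c1: tuple[str, str], mm: tuple[str, str],
                    c2: tuple[str, str], mode: AlphabetMode = DNA_PZ) -> float:
        self._check_pair(mode, *c1)
        self._check_pair(mode, *c2)
        v = self.int11[base_index(c1[0]), base_index(c1[1]),
                       base_index(mm[0]), base_index(mm[1]),
                       base_index(c2[0]), base_index(c2[1])]
        if v >= BIG / 2:
            raise KeyError(f"missing 1x1 loop entry {c1} {mm} {c2}")
        return float(v)


@dataclass
class ParameterSet:
    """All thermodynamic parameters for one alphabet mode."""

    mode: AlphabetMode
    stacks: dict[StackKey, StackParameter]
    penalties: GlobalPenalties
    loops: LoopTables
    temperature_reference: float = T_REF
    # dense mirrors used by the folding engine
    stack_dG: np.ndarray | None = None  # [x1, y1, x2, y2]
    end_penalty: np.ndarray | None = None  # [x, y]
    allowed: np.ndarray | None = None  # [x, y] bool

    def stack_key(self, top, bottom) -> StackKey:
        return canonical_stack_key(top, bottom, self.mode)

    def stack_dG37(self, top, bottom=None) -> float:
        """Free energy of a stack; rotation-equivalent renderings agree."""
        if bottom is None:
            top, bottom = top  # a StackKey was passed
        key = self.stack_key(top, bottom)
        try:
            return self.stacks[key].dG37
        except KeyError:
            raise KeyError(f"no stack parameter for {key}") from None

    def stack_dH(self, top, bottom=None) -> float:
        if bottom is None:
            top, bottom = top
        key = self.stack_key(top, bottom)
        p = self.stacks[key]
        if p.dH is None:
            raise ValueError(
                f"no enthalpy parameter for stack {key}; enthalpy prediction "
                "requires Watson-Crick-Franklin (and overlay-supplied P-Z) stacks only"
            )
        return p.dH

    def stack_dS(self, top, bottom=None) -> float:
        if bottom is None:
            top, bottom = top
        key = self.stack_key(top, bottom)
        p = self.stacks[key]
        if p.dS is None:
            raise ValueError(f"no entropy parameter for stack {key}")
        return p.dS

    def terminal_penalty(self, x: str, y: str) -> float:
        pair = frozenset((x, y))
        if pair == frozenset("AT"):
            return self.penalties.terminal_AT_penalty
        if pair == frozenset("PZ"):
            return self.penalties.terminal_PZ_penalty
        if pair == frozenset("GZ"):
            return self.penalties.terminal_GZ_penalty
        return 0.0


# ---------------------------------------------------------------------------
# loaders


def _load_stack_file(text: str, mode: AlphabetMode, with_hs: bool) -> tuple[
        dict[StackKey, StackParameter], dict[str, tuple[float, ...]]]:
    sections = _parse_sections(text)
    stacks: dict[StackKey, StackParameter] = {}
    for row in sections.get("stacks", []):
        top, bottom = tuple(row[0]), tuple(row[1])
        key = canonical_stack_key(top, bottom, mode)
        if with_hs:
            dG, dH, dS = _num(row[2]), _num(row[3]), _num(row[4])
            stacks[key] = StackParameter(key, dG, dH, dS)
        else:
            dG, se = _num(row[2]), _num(row[3]) if len(row) > 3 else None
            stacks[key] = StackParameter(key, dG, stderr_dG37=se)
    penalties = {row[0]: tuple(float(t) for t in row[1:])
                 for row in sections.get("penalties", [])}
    return stacks, penalties


def _jacobson_stockmayer(tab: dict[int, float], n: int) -> float:
    """Loop-length increment at size n, extrapolating between/past tabulated sizes."""
    if n in tab:
        return tab[n]
    below = [m for m in tab if m < n]
    if not below:
        raise KeyError(f"loop of size {n} smaller than any tabulated size")
    m = max(below)
    return tab[m] + 2.44 * R_GAS * T_REF * math.log(n / m)


def _length_array(tab: dict[int, float], max_n: int) -> np.ndarray:
    arr = np.full(max_n + 1, BIG)
    for n in range(1, max_n + 1):
        try:
            arr[n] = _jacobson_stockmayer(tab, n)
        except KeyError:
            pass
    return arr


def extrapolate_loop_tables(
    mode: AlphabetMode,
    canonical_cfg: dict[str, list[list[str]]],
    pz_cfg: dict[str, list[list[str]]],
    max_loop: int = 30,
    max_hairpin: int = 500,
) -> LoopTables:
    """Assemble complete six-letter loop tables from canonical data, measured
    P/Z increments, and the extrapolation rules (see module docstring)."""
    nb = len(BASES)
    rules = {row[0]: float(row[1]) for row in pz_cfg.get("rules", [])}

    canonical = set("ACGT")
    allowed = [(x, y) for x in BASES for y in BASES if mode.can_pair(x, y)]

    # --- dangling ends ------------------------------------------------------
    d5 = np.full((nb, nb, nb), BIG)
    d3 = np.full((nb, nb, nb), BIG)
    can_d = {"dangle5": {}, "dangle3": {}}
    for sec, store in can_d.items():
        for row in canonical_cfg.get(sec, []):
            store[(row[0], row[1], row[2])] = float(row[3])
    measured_d = {}
    for row in pz_cfg.get("measured_dangle", []):
        side, x, y, d, v = row
        measured_d[(side, x, y, d)] = float(v)

    for (x, y) in allowed:
        for d in BASES:
            for side, arr, store in (("5p", d5, can_d["dangle5"]),
                                     ("3p", d3, can_d["dangle3"])):
                if (side, x, y, d) in measured_d:
                    v = measured_d[(side, x, y, d)]
                elif x in canonical and y in canonical and d in canonical:
                    v = store[(x, y, d)]
                elif d == "P":
                    v = rules[f"dangle_P_{side}"]
                elif d == "Z":
                    v = rules[f"dangle_Z_{side}"]
                else:
                    # canonical dangle on a P/Z-containing terminal pair
                    v = rules[f"dangle_canonical_on_pz_{side}"]
                arr[base_index(x), base_index(y), base_index(d)] = v

    # --- terminal mismatches ------------------------------------------------
    tm = np.full((nb, nb, nb, nb), BIG)
    can_tm_default = {(r[0], r[1]): float(r[2])
                      for r in canonical_cfg.get("terminal_mismatch_default", [])}
    can_tm = {(r[0], r[1], r[2], r[3]): float(r[4])
              for r in canonical_cfg.get("terminal_mismatch", [])}
    meas_tm = {(r[0], r[1], r[2], r[3]): float(r[4])
               for r in pz_cfg.get("measured_terminal_mismatch", [])}

    def canonical_tm(x: str, y: str, a: str, b: str) -> float:
        return can_tm.get((x, y, a, b), can_tm_default[(x, y)])

    for (x, y) in allowed:
        for a in BASES:
            for b in BASES:
                if (x, y, a, b) in meas_tm:
                    v = meas_tm[(x, y, a, b)]
                elif (a, b) == ("P", "P"):
                    v = rules["tm_PP"]
                elif (a, b) == ("Z", "Z"):
                    v = rules["tm_ZZ"]
                elif x in _PZ_SET or y in _PZ_SET:
                    v = rules["tm_on_pz_closing"]
                elif a in _PZ_SET or b in _PZ_SET:
                    v = canonical_tm(x, y, *_remap_mismatch(a, b))
                else:
                    v = canonical_tm(x, y, a, b)
                tm[base_index(x), base_index(y), base_index(a), base_index(b)] = v

    # --- internal-loop tables (vectorized over dense arrays) ----------------
    stab = rules["int_pz_stabilizer"]  # -0.6 per P/Z-containing mismatch

    mm11 = {frozenset(r[:2]): float(r[2]) for r in canonical_cfg["int11_mismatch"]}
    mm22 = {frozenset(r[:2]): float(r[2]) for r in canonical_cfg["int22_mismatch"]}
    adj = {(r[0], r[1]): float(r[2]) for r in canonical_cfg["int11_closing_adjust"]}
    int21_base = float(canonical_cfg["int21"][0][1])

    # 6x6 mismatch-content grids after the P->G / Z->C / WCF->A-C remapping
    mapped11 = np.zeros((nb, nb))
    mapped22 = np.zeros((nb, nb))
    pz_mm = np.zeros((nb, nb))
    for a in BASES:
        for b in BASES:
            ra, rb = _remap_mismatch(a, b)
            mapped11[base_index(a), base_index(b)] = mm11[frozenset((ra, rb))]
            mapped22[base_index(a), base_index(b)] = mm22[frozenset((ra, rb))]
            pz_mm[base_index(a), base_index(b)] = float(a in _PZ_SET or b in _PZ_SET)

    # per-closing adjustment after closure remapping; BIG for non-pairs
    adjc = np.full((nb, nb), BIG)
    for (x, y) in allowed:
        adjc[base_index(x), base_index(y)] = adj[_remap_closing(x, y)]

    a1 = adjc[:, :, None, None, None, None]
    a2 = adjc[None, None, None, None, :, :]
    int11 = (a1 + a2 + mapped11[None, None, :, :, None, None]
             + stab * pz_mm[None, None, :, :, None, None])

    pz1 = np.array([float(b in _PZ_SET) for b in BASES])
    any_pz_3 = 1.0 - ((1 - pz1)[:, None, None]
                      * (1 - pz1)[None, :, None]
                      * (1 - pz1)[None, None, :])
    int21 = (adjc[:, :, None, None, None, None, None]
             + adjc[None, None, None, None, None, :, :]
             + int21_base
             + stab * any_pz_3[None, None, :, :, :, None, None])

    int22 = (adjc[:, :, None, None, None, None, None, None]
             + adjc[None, None, None, None, None, None, :, :]
             + mapped22[None, None, :, None, :, None, None, None]   # (a1, c1)
             + mapped22[None, None, None, :, None, :, None, None]   # (a2, c2)
             + stab * (pz_mm[None, None, :, None, :, None, None, None]
                       + pz_mm[None, None, None, :, None, :, None, None]))

    np.clip(int11, None, BIG, out=int11)
    np.clip(int21, None, BIG, out=int21)
    np.clip(int22, None, BIG, out=int22)

    # --- loop-length penalties ----------------------------------------------
    lengths = {"hairpin": {}, "bulge": {}, "internal": {}}
    for row in canonical_cfg["lengths"]:
        n = int(row[0])
        for name, tok in zip(("hairpin", "bulge", "internal"), row[1:]):
            v = _num(tok)
            if v is not None:
                lengths[name][n] = v

    mb = {r[0]: float(r[1]) for r in canonical_cfg["multibranch"]}
    asym = {r[0]: float(r[1]) for r in canonical_cfg["internal_asymmetry"]}

    return LoopTables(
        dangle5=d5,
        dangle3=d3,
        terminal_mismatch=tm,
        int11=int11,
        int21=int21,
        int22=int22,
        hairpin_len=_length_array(lengths["hairpin"], max_hairpin),
        bulge_len=_length_array(lengths["bulge"], max_loop),
        internal_len=_length_array(lengths["internal"], max_loop),
        ml_offset=mb["offset"],
        ml_per_branch=mb["per_branch"],
        ml_per_unpaired=mb["per_unpaired"],
        asym_per_nt=asym["per_nt"],
        asym_max=asym["max"],
        rules=rules,
    )


def _dense_stacks(stacks: dict[StackKey, StackParameter]) -> np.ndarray:
    arr = np.full((6, 6, 6, 6), BIG)
    for key, p in stacks.items():
        for (top, bottom) in (key, rotate_stack(*key)):
            arr[base_index(top[0]), base_index(bottom[0]),
                base_index(top[1]), base_index(bottom[1])] = p.dG37
    return arr


def load_parameter_set(
    mode: AlphabetMode | str = DNA_PZ,
    overlay: str | Path | None = None,
) -> ParameterSet:
    """Load the complete, validated parameter set for an alphabet mode.

    ``overlay`` optionally names a sectioned text file whose ``[stacks]``
    rows (top bottom dG37 [dH dS]) replace or extend packaged stack values
    (e.g. supplementary P-Z enthalpies or legacy G-T stacks).
    Loading is deterministic.
    """
    if isinstance(mode, str):
        from .alphabet import MODES

        mode = MODES[mode]

    dna_stacks, dna_pen = _load_stack_file(_read_packaged("stacks_dna.txt"), DNA_PZ, True)
    stacks = dict(dna_stacks)
    pz_pen = gz_pen = {}
    if "P" in {b for pair in mode.allowed_pairs for b in pair}:
        pz_stacks, pz_pen = _load_stack_file(_read_packaged("stacks_pz.txt"), mode, False)
        gz_stacks, gz_pen = _load_stack_file(_read_packaged("stacks_gz.txt"), mode, False)
        if len(pz_stacks) != 11:
            raise ValueError(f"expected 11 unique P-Z stacks, got {len(pz_stacks)}")
        if len(gz_stacks) != 15:
            raise ValueError(f"expected 15 unique G-Z stacks, got {len(gz_stacks)}")
        stacks.update(pz_stacks)
        stacks.update(gz_stacks)

    if overlay is not None:
        extra, _ = _load_stack_file(Path(overlay).read_text(), mode, True)
        stacks.update(extra)

    pen = GlobalPenalties(
        intermolecular_initiation=dna_pen["intermolecular_initiation"][0],
        symmetry_correction=dna_pen["symmetry_correction"][0],
        terminal_AT_penalty=dna_pen["terminal_AT"][0],
        terminal_PZ_penalty=pz_pen.get("terminal_PZ", (0.0,))[0],
        terminal_GZ_penalty=gz_pen.get("terminal_GZ", (0.0,))[0],
        initiation_dH=dna_pen["intermolecular_initiation"][1],
        initiation_dS=dna_pen["intermolecular_initiation"][2],
        symmetry_dS=dna_pen["symmetry_correction"][2],
        terminal_AT_dH=dna_pen["terminal_AT"][1],
        terminal_AT_dS=dna_pen["terminal_AT"][2],
    )

    loops = extrapolate_loop_tables(
        mode,
        _parse_sections(_read_packaged("loops_dna.txt")),
        _parse_sections(_read_packaged("loops_pz.txt")),
    )

    ps = ParameterSet(mode=mode, stacks=stacks, penalties=pen, loops=loops)
    ps.stack_dG = _dense_stacks(stacks)
    allowed = np.zeros((6, 6), dtype=bool)
    endpen = np.zeros((6, 6))
    for x in BASES:
        for y in BASES:
            if mode.can_pair(x, y):
                allowed[base_index(x), base_index(y)] = True
                endpen[base_index(x), base_index(y)] = ps.terminal_penalty(x, y)
    ps.allowed = allowed
    ps.end_penalty = endpen
    _validate(ps)
    return ps


def _validate(ps: ParameterSet) -> None:
    """Hard-fail if any legal query would miss after extrapolation."""
    missing = []
    mode = ps.mode
    for x in BASES:
        for y in BASES:
            if not mode.can_pair(x, y):
                continue
            ix, iy = base_index(x), base_index(y)
            for d in range(6):
                if ps.loops.dangle5[ix, iy, d] >= BIG / 2:
                    missing.append(f"dangle5 {x}{y} {BASES[d]}")
                if ps.loops.dangle3[ix, iy, d] >= BIG / 2:
                    missing.append(f"dangle3 {x}{y} {BASES[d]}")
            if np.any(ps.loops.terminal_mismatch[ix, iy] >= BIG / 2):
                missing.append(f"terminal mismatch block {x}{y}")
            for u in BASES:
                for v in BASES:
                    if not mode.can_pair(u, v):
                        continue
                    iu, iv = base_index(u), base_index(v)
                    if np.any(ps.loops.int11[ix, iy, :, :, iu, iv] >= BIG / 2):
                        missing.append(f"int11 block {x}{y}..{u}{v}")
    if missing:
        raise ValueError("missing loop entries after extrapolation: "
                         + "; ".join(missing[:20]))


# ---------------------------------------------------------------------------
# statistics over the stack tables


def _substitute_analog(key: StackKey, sub: dict[str, str]) -> StackKey:
    top = tuple(sub.get(b, b) for b in key[0])
    bottom = tuple(sub.get(b, b) for b in key[1])
    return canonical_stack_key(top, bottom)


def _n_pairs(key: StackKey, pair: frozenset[str]) -> int:
    return sum(frozenset((t, b)) == pair for t, b in zip(key[0], key[1]))


def table_statistics(ps: ParameterSet) -> dict:
    """Aggregate statistics over the P-Z and G-Z stack tables.

    Returns the mean ddG37 per P-Z substitution against the analogous G-C
    stacks, the family means over the XP/YZ (5' Z on the bottom strand) and
    XZ/YP stack forms, min/max per family, and -- under the documented
    partition by rendering (membership by the Z-containing column position,
    each unique stack counted once per matching rendering) -- the G-Z 5'/3'
    Z-side averages.
    """
    pz_pair = frozenset("PZ")
    gz_pair = frozenset("GZ")
    pz = {k: p for k, p in ps.stacks.items() if _n_pairs(k, pz_pair) > 0
          and _n_pairs(k, gz_pair) == 0}
    gz = {k: p for k, p in ps.stacks.items() if _n_pairs(k, gz_pair) > 0}

    ddg = []
    for key, p in pz.items():
        analog = _substitute_analog(key, {"P": "G", "Z": "C"})
        n = _n_pairs(key, pz_pair)
        ddg.append((p.dG37 - ps.stacks[analog].dG37) / n)

    def family(stacks, col_top: str, col_bottom: str) -> list[float]:
        out = []
        for key, p in stacks.items():
            renderings = {key, rotate_stack(*key)}
            for top, bottom in renderings:
                if top[1] == col_top and bottom[1] == col_bottom:
                    out.append(p.dG37)
        return out

    xp_yz = family(pz, "P", "Z")
    xz_yp = family(pz, "Z", "P")
    gz_vals = [p.dG37 for p in gz.values()]
    pz_vals = [p.dG37 for p in pz.values()]

    # Documented partition for the G-Z 5'/3' Z-side averages: over distinct
    # renderings, a G-Z column contributes to the 5'-Z group when its Z has a
    # 3' neighbor within the stack (top column 0 or bottom column 1) and to
    # the 3'-Z group otherwise; a stack may appear in both groups.
    gz_5pz, gz_3pz = [], []
    for key, p in gz.items():
        for top, bottom in {key, rotate_stack(*key)}:
            for col in (0, 1):
                if frozenset((top[col], bottom[col])) != gz_pair:
                    continue
                z_on_top = top[col] == "Z"
                five_prime = (col == 0) if z_on_top else (col == 1)
                (gz_5pz if five_prime else gz_3pz).append(p.dG37)

    return {
        "mean_ddG_per_PZ_substitution": float(np.mean(ddg)),
        "mean_XP_YZ": float(np.mean(xp_yz)),
        "mean_XZ_YP": float(np.mean(xz_yp)),
        "pz_min": float(min(pz_vals)),
        "pz_max": float(max(pz_vals)),
        "gz_min": float(min(gz_vals)),
        "gz_max": float(max(gz_vals)),
        "gz_mean_5pZ": float(np.mean(gz_5pz)),
        "gz_mean_3pZ": float(np.mean(gz_3pz)),
        "n_pz_stacks": len(pz),
        "n_gz_stacks": len(gz),
    }


# ---------------------------------------------------------------------------
# round-trip stack table I/O


def write_stack_table(stacks: dict[StackKey, StackParameter], path: str | Path) -> None:
    """Write a stack table in the packaged dialect (bit-faithful round trip)."""
    lines = ["# stack table, kcal/mol (dS in cal/(mol.K))", "[stacks]"]
    for key in sorted(stacks):
        p = stacks[key]

        def tok(v):
            return "." if v is None else repr(float(v))

        lines.append(f"{''.join(key[0])} {''.join(key[1])} "
                     f"{tok(p.dG37)} {tok(p.dH)} {tok(p.dS)} {tok(p.stderr_dG37)}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_stack_table(path: str | Path,
                     mode: AlphabetMode = DNA_PZ) -> dict[StackKey, StackParameter]:
    sections = _parse_sections(Path(path).read_text())
    out: dict[StackKey, StackParameter] = {}
    for row in sections["stacks"]:
        key = canonical_stack_key(tuple(row[0]), tuple(row[1]), mode)
        out[key] = StackParameter(key, float(row[2]), _num(row[3]), _num(row[4]),
                                  stderr_dG37=_num(row[5]))
    return out
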