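"""Readers and writers: dot-bracket, CT (RNAstructure dialect), FASTA with
the extended P/Z letters, sparse pair-probability text files, and run
manifests.  All readers reject invalid input with located error messages;
all writers round-trip.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .alphabet import Sequence, parse_sequence
from .energy import SecondaryStructure
from .folding import PairProbabilityMatrix

__all__ = [
    "parse_dotbracket",
    "to_dotbracket",
    "read_structure",
    "write_ct",
    "read_ct",
    "read_fasta",
    "write_fasta",
    "write_probability_matrix",
    "read_probability_matrix",
    "RunManifest",
]


def parse_dotbracket(db: str) -> SecondaryStructure:
    """Parse a '().'-only dot-bracket string (no pseudoknot brackets)."""
    db = db.strip()
    stack: list[int] = []
    pairs = set()
    for pos, ch in enumerate(db):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {pos + 1}")
            pairs.add((stack.pop(), pos))
        elif ch != ".":
            raise ValueError(
                f"unsupported symbol {ch!r} at position {pos + 1}; only '().' "
                "are accepted (pseudoknot not supported)")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return SecondaryStructure(len(db), frozenset(pairs))


def to_dotbracket(structure: SecondaryStructure) -> str:
    return structure.to_dotbracket()


def write_ct(path: str | Path, seq: Sequence, structure: SecondaryStructure,
             title: str = "") -> None:
    """Write RNAstructure-dialect CT: count header then per-line
    index, base, prev, next, pair, natural index (1-based)."""
    if len(seq) != structure.length:
        raise ValueError("sequence and structure lengths differ")
    partner = structure.partner
    n = len(seq)
    lines = [f"{n}\t{title or seq.id}"]
    for i in range(n):
        lines.append(f"{i + 1}\t{seq[i]}\t{i}\t{(i + 2) if i + 1 < n else 0}"
                     f"\t{int(partner[i]) + 1}\t{i + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_ct(path: str | Path) -> tuple[Sequence, SecondaryStructure]:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty CT file")
    head = lines[0].split()
    try:
        n = int(head[0])
    except (IndexError, ValueError):
        raise ValueError(f"{path}: CT header must start with the base count")
    title = " ".join(head[1:])
    if len(lines) - 1 < n:
        raise ValueError(f"{path}: CT declares {n} bases, {len(lines) - 1} given")
    bases = []
    pairs = set()
    for k in range(n):
        toks = lines[1 + k].split()
        if len(toks) < 6:
            raise ValueError(f"{path}: line {k + 2}: expected 6 CT columns")
        idx, base, pair = int(toks[0]), toks[1], int(toks[4])
        if idx != k + 1:
            raise ValueError(f"{path}: line {k + 2}: index {idx} out of order")
        bases.append(base)
        if pair > 0 and pair > idx:
            pairs.add((idx - 1, pair - 1))
        elif pair > 0 and (pair - 1, idx - 1) not in pairs:
            raise ValueError(f"{path}: line {k + 2}: pairing is not symmetric")
    seq = parse_sequence("".join(bases), seq_id=title)
    return seq, SecondaryStructure(n, frozenset(pairs))


def read_structure(path: str | Path, fmt: str = "auto"
                   ) -> tuple[Sequence | None, SecondaryStructure]:
    """Read a target structure from CT or dot-bracket (optionally with a
    FASTA-style header and/or a sequence line)."""
    path = Path(path)
    if fmt == "auto":
        fmt = "ct" if path.suffix.lower() == ".ct" else "dotbracket"
        text = path.read_text()
        first = text.lstrip().splitlines()[0].split()
        if fmt == "dotbracket" and first and first[0].isdigit():
            fmt = "ct"
    if fmt == "ct":
        return read_ct(path)
    lines = [ln.strip() for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith((">", "#", ";"))]
    if not lines:
        raise ValueError(f"{path}: no structure line found")
    seq = None
    db = lines[-1]
    if len(lines) >= 2 and set(lines[-2]) & set("ACGTPZacgtpz"):
        seq = parse_sequence(lines[-2])
    structure = parse_dotbracket(db)
    if seq is not None and len(seq) != structure.length:
        raise ValueError(f"{path}: sequence and structure lengths differ")
    return seq, structure


def read_fasta(path: str | Path) -> list[Sequence]:
    """FASTA over the letters A,C,G,T,P,Z (P/Z read literally)."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.append(parse_sequence(str(rec.seq), seq_id=rec.id))
    if not out:
        raise ValueError(f"{path}: no FASTA records")
    return out


def write_fasta(path: str | Path, seqs) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(str(s)), id=s.id or f"seq{k + 1}", description="")
               for k, s in enumerate(seqs)]
    seqio_write(records, str(path), "fasta")


def write_probability_matrix(probs: PairProbabilityMatrix,
                             path: str | Path) -> None:
    """Sparse triplet text (1-based i, j, p) plus an unpaired-q column."""
    n = probs.p.shape[0]
    lines = [f"# pair probabilities, N={n}", "# i j p(i,j)  [i<j, p>0]"]
    for i in range(n):
        for j in range(i + 1, n):
            if probs.p[i, j] > 0.0:
                lines.append(f"{i + 1} {j + 1} {probs.p[i, j]:.17g}")
    lines.append("# i q(i)")
    for i in range(n):
        lines.append(f"q {i + 1} {probs.q[i]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_probability_matrix(path: str | Path) -> PairProbabilityMatrix:
    n = None
    trip, qs = [], {}
    for ln in Path(path).read_text().splitlines():
        if ln.startswith("#"):
            if "N=" in ln:
                n = int(ln.split("N=")[1].split()[0])
            continue
        toks = ln.split()
        if not toks:
            continue
        if toks[0] == "q":
            qs[int(toks[1]) - 1] = float(toks[2])
        else:
            trip.append((int(toks[0]) - 1, int(toks[1]) - 1, float(toks[2])))
    if n is None:
        raise ValueError(f"{path}: missing N= header")
    p = np.zeros((n, n))
    for i, j, v in trip:
        p[i, j] = p[j, i] = v
    q = np.array([qs.get(i, 1.0) for i in range(n)])
    return PairProbabilityMatrix(p=p, q=q)


class RunManifest:
    """Record of one command invocation: config, seeds, digests, wall time."""

    def __init__(self, command: str, **config):
        self.data = {
            "command": command,
            "config": config,
            "inputs": {},
            "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._t0 = time.monotonic()

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
        self.data["inputs"][str(path)] = digest

    def write(self, path: str | Path) -> None:
        import pzfold

        self.data["version"] = pzfold.__version__
        self.data["wall_time_s"] = round(time.monotonic() - self._t0, 3)
        Path(path).write_text(json.dumps(self.data, indent=2) + "\n")
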