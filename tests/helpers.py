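"""Independent brute-force oracles used by the test suite.

The enumeration oracle lists every pseudoknot-free structure (hairpin loops
>= 3 nt) for short sequences and evaluates each with the loop-based energy
function, giving reference values for the partition function, pair
probabilities, NED and MFE that are independent of the dynamic-programming
recursions under test.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from pzfold.alphabet import encode
from pzfold.energy import MIN_HAIRPIN, EnergyModel, SecondaryStructure, fold_energy


def enumerate_structures(seq, model: EnergyModel) -> list[SecondaryStructure]:
    """All valid structures for ``seq`` (use only for n <= ~16)."""
    s = encode(seq) if not isinstance(seq, np.ndarray) else seq
    n = len(s)
    allowed = model.allowed

    @lru_cache(maxsize=None)
    def interval(i: int, j: int) -> tuple[frozenset, ...]:
        if j - i + 1 <= MIN_HAIRPIN:
            return (frozenset(),)
        out = list(interval(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if allowed[s[i], s[k]]:
                for inner in interval(i + 1, k - 1):
                    for outer in interval(k + 1, j):
                        out.append(inner | outer | {(i, k)})
        return tuple(out)

    if n <= MIN_HAIRPIN:
        return [SecondaryStructure(n, frozenset())]
    return [SecondaryStructure(n, p) for p in interval(0, n - 1)]


def brute_force_ensemble(seq, model: EnergyModel):
    """Reference Q, pair-probability matrix, unpaired probabilities and MFE."""
    s = encode(seq) if not isinstance(seq, np.ndarray) else seq
    n = len(s)
    structures = enumerate_structures(s, model)
    weights = np.array([math.exp(-fold_energy(s, st, model) / model.RT)
                        for st in structures])
    Q = weights.sum()
    p = np.zeros((n, n))
    for st, w in zip(structures, weights):
        for i, j in st.pairs:
            p[i, j] += w
            p[j, i] += w
    p /= Q
    q = 1.0 - p.sum(axis=1)
    energies = np.array([fold_energy(s, st, model) for st in structures])
    k = int(np.argmin(energies))
    return {
        "Q": float(Q),
        "p": p,
        "q": q,
        "mfe": float(energies[k]),
        "mfe_structure": structures[k],
        "structures": structures,
        "weights": weights,
    }


def brute_force_ned(seq, target: SecondaryStructure, model: EnergyModel) -> float:
    """NED as the ensemble average of the per-structure defect."""
    s = encode(seq) if not isinstance(seq, np.ndarray) else seq
    ref = brute_force_ensemble(s, model)
    partner = target.partner
    per = np.zeros(len(s))
    for i in range(len(s)):
        if partner[i] >= 0:
            per[i] = 1.0 - ref["p"][i, partner[i]]
        else:
            per[i] = 1.0 - ref["q"][i]
    return float(per.mean())
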