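"""Partition function, base-pair probabilities, MFE and the normalized
ensemble defect (NED) for single strands over the expanded alphabet.

The equilibrium partition function Q = sum over all pseudoknot-free
structures of exp(-dG/RT) is computed by the standard interior/multibranch
dynamic-programming decomposition of the loop-based energy model defined in
:mod:`pzfold.energy` (internal loops capped at 30 unpaired nucleotides,
minimum hairpin 3, isolated pairs permitted).  Pair probabilities follow from
the inside-outside recursions; the numerically heavy kernels are JIT-compiled
with numba.  The MFE structure uses the same decomposition with minimization
and a deterministic traceback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .alphabet import Sequence, encode
from .energy import MAX_LOOP, MIN_HAIRPIN, EnergyModel, SecondaryStructure, fold_energy
from .parameters import ParameterSet, T_REF

__all__ = [
    "PartitionFunction",
    "PairProbabilityMatrix",
    "NEDReport",
    "partition_function",
    "pair_probabilities",
    "ned",
    "mfe_structure",
]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _e_interior_nb(s, i, j, k, l, stack, bulge_len, internal_len,
                   int11, int21, int22, tmm, endpen, asym_pn, asym_max):
    u1 = k - i - 1
    u2 = j - l - 1
    if u1 == 0 and u2 == 0:
        return stack[s[i], s[j], s[k], s[l]]
    if u1 == 0 or u2 == 0:
        b = u1 + u2
        if b == 1:
            return bulge_len[1] + stack[s[i], s[j], s[k], s[l]]
        return bulge_len[b] + endpen[s[i], s[j]] + endpen[s[k], s[l]]
    if u1 == 1 and u2 == 1:
        return int11[s[i], s[j], s[i + 1], s[j - 1], s[k], s[l]]
    if u1 == 1 and u2 == 2:
        return int21[s[i], s[j], s[i + 1], s[j - 1], s[j - 2], s[k], s[l]]
    if u1 == 2 and u2 == 1:
        return int21[s[l], s[k], s[j - 1], s[i + 2], s[i + 1], s[j], s[i]]
    if u1 == 2 and u2 == 2:
        return int22[s[i], s[j], s[i + 1], s[i + 2], s[j - 1], s[j - 2], s[k], s[l]]
    asym = asym_pn * abs(u1 - u2)
    if asym > asym_max:
        asym = asym_max
    return (internal_len[u1 + u2] + asym
            + endpen[s[i], s[j]] + endpen[s[k], s[l]]
            + tmm[s[i], s[j], s[i + 1], s[j - 1]]
            + tmm[s[l], s[k], s[l + 1], s[k - 1]])


@njit(cache=True)
def _e_hairpin_nb(s, i, j, hairpin_len, tmm, endpen):
    u = j - i - 1
    e = hairpin_len[u] + endpen[s[i], s[j]]
    if u >= 4:
        e += tmm[s[i], s[j], s[i + 1], s[j - 1]]
    return e


@njit(cache=True)
def _e_ml_closing_nb(s, i, j, ml_a, ml_b, d5, d3, endpen):
    return (ml_a + ml_b + endpen[s[i], s[j]]
            + d3[s[i], s[j], s[i + 1]] + d5[s[j], s[i], s[j - 1]])


@njit(cache=True)
def _e_ml_branch_nb(s, k, l, ml_b, d5, d3, endpen):
    return (ml_b + endpen[s[k], s[l]]
            + d5[s[k], s[l], s[k - 1]] + d3[s[l], s[k], s[l + 1]])


@njit(cache=True)
def _e_ext_nb(s, i, j, n, d5, d3, endpen):
    e = endpen[s[i], s[j]]
    if i > 0:
        e += d5[s[i], s[j], s[i - 1]]
    if j < n - 1:
        e += d3[s[j], s[i], s[j + 1]]
    return e


@njit(cache=True)
def _inside_nb(s, allowed, stack, bulge_len, internal_len, int11, int21, int22,
               tmm, endpen, d5, d3, hairpin_len,
               ml_a, ml_b, ml_c, asym_pn, asym_max, RT):
    n = len(s)
    QB = np.zeros((n, n))
    QM = np.zeros((n, n))
    QM1 = np.zeros((n, n))
    ec = math.exp(-ml_c / RT)
    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - d):
            j = i + d
            if allowed[s[i], s[j]]:
                q = math.exp(-_e_hairpin_nb(s, i, j, hairpin_len, tmm, endpen) / RT)
                kmax = j - MIN_HAIRPIN - 2
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    if u1 > MAX_LOOP:
                        break
                    lmin = k + MIN_HAIRPIN + 1
                    lo = j - 1 - (MAX_LOOP - u1)
                    if lo > lmin:
                        lmin = lo
                    for l in range(lmin, j):
                        if QB[k, l] > 0.0:
                            e = _e_interior_nb(s, i, j, k, l, stack, bulge_len,
                                               internal_len, int11, int21, int22,
                                               tmm, endpen, asym_pn, asym_max)
                            q += math.exp(-e / RT) * QB[k, l]
                if d >= 2 * (MIN_HAIRPIN + 2) + 1:
                    acc = 0.0
                    for k in range(i + 2, j - MIN_HAIRPIN - 1):
                        if QM[i + 1, k - 1] > 0.0 and QM1[k, j - 1] > 0.0:
                            acc += QM[i + 1, k - 1] * QM1[k, j - 1]
                    if acc > 0.0:
                        ecl = _e_ml_closing_nb(s, i, j, ml_a, ml_b, d5, d3, endpen)
                        q += math.exp(-ecl / RT) * acc
                QB[i, j] = q
            # QM1: last-branch segment starting exactly at i.  A multibranch
            # branch always has an enclosing pair, so i-1 and j+1 exist.
            v = QM1[i, j - 1] * ec
            if QB[i, j] > 0.0 and i >= 1 and j <= n - 2:
                wb = math.exp(-_e_ml_branch_nb(s, i, j, ml_b, d5, d3, endpen) / RT)
                v += QB[i, j] * wb
            QM1[i, j] = v
            # QM: >=1 branch in [i, j]
            m = 0.0
            eu = 1.0
            for k in range(i, j - MIN_HAIRPIN):
                if QM1[k, j] > 0.0:
                    left = eu
                    if k > i:
                        left += QM[i, k - 1]
                    m += left * QM1[k, j]
                elif k > i:
                    pass
                eu *= ec
            QM[i, j] = m
    # exterior
    QEp = np.ones(n + 1)
    for j in range(0, n):
        tot = QEp[j]
        for i in range(0, j - MIN_HAIRPIN):
            if QB[i, j] > 0.0:
                w = math.exp(-_e_ext_nb(s, i, j, n, d5, d3, endpen) / RT)
                tot += QEp[i] * QB[i, j] * w
        QEp[j + 1] = tot
    QEs = np.ones(n + 1)
    for i in range(n - 1, -1, -1):
        tot = QEs[i + 1]
        for j in range(i + MIN_HAIRPIN + 1, n):
            if QB[i, j] > 0.0:
                w = math.exp(-_e_ext_nb(s, i, j, n, d5, d3, endpen) / RT)
                tot += QB[i, j] * w * QEs[j + 1]
        QEs[i] = tot
    return QB, QM, QM1, QEp, QEs


@njit(cache=True)
def _outside_nb(s, allowed, QB, QM, QEp, QEs,
                stack, bulge_len, internal_len, int11, int21, int22,
                tmm, endpen, d5, d3,
                ml_a, ml_b, ml_c, asym_pn, asym_max, RT):
    n = len(s)
    QBhat = np.zeros((n, n))
    C = np.zeros((n, n))  # QBhat * multibranch closing weight
    ec = math.exp(-ml_c / RT)
    for d in range(n - 1, MIN_HAIRPIN, -1):
        for i in range(0, n - d):
            j = i + d
            if QB[i, j] <= 0.0:
                continue
            wext = math.exp(-_e_ext_nb(s, i, j, n, d5, d3, endpen) / RT)
            tot = QEp[i] * QEs[j + 1] * wext
            # enclosed in an interior loop closed by (h, q)
            hmin = i - MAX_LOOP - 1
            if hmin < 0:
                hmin = 0
            for h in range(hmin, i):
                u1 = i - h - 1
                qmax = j + 1 + (MAX_LOOP - u1)
                if qmax > n - 1:
                    qmax = n - 1
                for q in range(j + 1, qmax + 1):
                    if QBhat[h, q] > 0.0 and allowed[s[h], s[q]]:
                        e = _e_interior_nb(s, h, q, i, j, stack, bulge_len,
                                           internal_len, int11, int21, int22,
                                           tmm, endpen, asym_pn, asym_max)
                        tot += QBhat[h, q] * math.exp(-e / RT)
            # a branch of a multibranch loop closed by (h, q)
            acc = 0.0
            for h in range(0, i):
                lg = i - h - 1  # unpaired-capacity of the left gap
                left_eu = ec ** lg
                left_qm = QM[h + 1, i - 1] if i - 1 >= h + 1 else 0.0
                if left_qm <= 0.0 and left_eu <= 0.0:
                    continue
                for q in range(j + 1, n):
                    c = C[h, q]
                    if c > 0.0:
                        right_qm = QM[j + 1, q - 1] if q - 1 >= j + 1 else 0.0
                        right_eu = ec ** (q - j - 1)
                        other = left_qm * (right_qm + right_eu) + left_eu * right_qm
                        if other > 0.0:
                            acc += c * other
            if acc > 0.0:
                wb = math.exp(-_e_ml_branch_nb(s, i, j, ml_b, d5, d3, endpen) / RT)
                tot += wb * acc
            QBhat[i, j] = tot
            ecl = _e_ml_closing_nb(s, i, j, ml_a, ml_b, d5, d3, endpen)
            C[i, j] = tot * math.exp(-ecl / RT)
    return QBhat


# ---------------------------------------------------------------------------
# public API


@dataclass
class PairProbabilityMatrix:
    """Boltzmann pairing probabilities p(i,j) and unpaired probabilities q(i)."""

    p: np.ndarray  # symmetric (n, n)
    q: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = self.p.shape[0]
        if not np.allclose(self.p, self.p.T, atol=1e-12):
            raise ValueError("pair probability matrix must be symmetric")
        total = self.q + self.p.sum(axis=1)
        if np.any(self.p < -1e-12) or np.any(self.p > 1 + 1e-9):
            raise ValueError("pair probabilities outside [0, 1]")
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("q(i) + sum_j p(i,j) must equal 1")


@dataclass
class PartitionFunction:
    """Inside (and lazily outside) partition-function state for one sequence."""

    seq: np.ndarray
    model: EnergyModel
    Q: float
    _QB: np.ndarray
    _QM: np.ndarray
    _QEp: np.ndarray
    _QEs: np.ndarray
    _probs: PairProbabilityMatrix | None = None

    def pair_probabilities(self) -> PairProbabilityMatrix:
        if self._probs is None:
            m = self.model
            s = self.seq.astype(np.int64)
            QBhat = _outside_nb(
                s, m.allowed, self._QB, self._QM, self._QEp, self._QEs,
                m.stack, m.bulge_len, m.internal_len, m.int11, m.int21, m.int22,
                m.tmm, m.endpen, m.d5, m.d3,
                m.ml_a, m.ml_b, m.ml_c, m.asym_pn, m.asym_max, m.RT)
            p = self._QB * QBhat / self.Q
            p = np.triu(p)
            p = p + p.T
            np.clip(p, 0.0, 1.0, out=p)
            q = np.clip(1.0 - p.sum(axis=1), 0.0, 1.0)
            self._probs = PairProbabilityMatrix(p=p, q=q)
        return self._probs


def partition_function(seq: Sequence | str | np.ndarray,
                       params: ParameterSet | EnergyModel,
                       T: float = T_REF) -> PartitionFunction:
    """Compute the equilibrium partition function of a single strand."""
    model = params if isinstance(params, EnergyModel) else EnergyModel(params, T=T)
    if isinstance(params, EnergyModel) and abs(T - model.T) > 1e-9:
        raise ValueError("temperature does not match the energy model")
    s = (seq if isinstance(seq, np.ndarray) else encode(seq)).astype(np.int64)
    m = model
    QB, QM, QM1, QEp, QEs = _inside_nb(
        s, m.allowed, m.stack, m.bulge_len, m.internal_len,
        m.int11, m.int21, m.int22, m.tmm, m.endpen, m.d5, m.d3, m.hairpin_len,
        m.ml_a, m.ml_b, m.ml_c, m.asym_pn, m.asym_max, m.RT)
    return PartitionFunction(seq=s, model=model, Q=float(QEp[len(s)]),
                             _QB=QB, _QM=QM, _QEp=QEp, _QEs=QEs)


def pair_probabilities(pf: PartitionFunction) -> PairProbabilityMatrix:
    return pf.pair_probabilities()


@dataclass
class NEDReport:
    """Normalized ensemble defect: mean over positions of 1 - P_i."""

    ned: float
    per_position: np.ndarray
    N: int


def ned(seq: Sequence | str | np.ndarray,
        target: SecondaryStructure,
        probs: PairProbabilityMatrix | PartitionFunction | None = None,
        params: ParameterSet | EnergyModel | None = None) -> NEDReport:
    """NED of ``seq`` against ``target``.

    P_i is p(i, partner(i)) for nucleotides paired in the target and the
    unpaired probability q(i) otherwise; NED = mean(1 - P_i).
    """
    s = (seq if isinstance(seq, np.ndarray) else encode(seq)).astype(np.int64)
    if target.length != len(s):
        raise ValueError("target length does not match sequence length")
    if probs is None:
        if params is None:
            raise ValueError("either probabilities or parameters are required")
        probs = partition_function(s, params).pair_probabilities()
    elif isinstance(probs, PartitionFunction):
        probs = probs.pair_probabilities()
    partner = target.partner
    per = np.empty(len(s))
    for i in range(len(s)):
        if partner[i] >= 0:
            per[i] = 1.0 - probs.p[i, partner[i]]
        else:
            per[i] = 1.0 - probs.q[i]
    return NEDReport(ned=float(per.mean()), per_position=per, N=len(s))


# ---------------------------------------------------------------------------
# minimum free energy structure (pure-python mirror of the decomposition)


def mfe_structure(seq: Sequence | str | np.ndarray,
                  params: ParameterSet | EnergyModel) -> tuple[SecondaryStructure, float]:
    """MFE structure and its free energy under the same decomposition.

    Traceback is deterministic: hairpin is preferred over interior loops
    (enumerated by increasing k then increasing l) over multibranch closures,
    with ties resolved toward the first matching option.
    """
    model = params if isinstance(params, EnergyModel) else EnergyModel(params)
    s = (seq if isinstance(seq, np.ndarray) else encode(seq)).astype(np.int64)
    n = len(s)
    INF = math.inf
    V = np.full((n, n), INF)
    WM = np.full((n, n), INF)
    WM1 = np.full((n, n), INF)

    def wext_e(i, j):
        return model.e_ext_branch(s, i, j, n)

    for d in range(MIN_HAIRPIN + 1, n):
        for i in range(0, n - d):
            j = i + d
            if model.can_pair(s, i, j):
                best = model.e_hairpin(s, i, j)
                kmax = j - MIN_HAIRPIN - 2
                for k in range(i + 1, kmax + 1):
                    u1 = k - i - 1
                    if u1 > MAX_LOOP:
                        break
                    lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_LOOP - u1))
                    for l in range(lmin, j):
                        if V[k, l] < INF:
                            e = model.e_interior(s, i, j, k, l) + V[k, l]
                            if e < best:
                                best = e
                if d >= 2 * (MIN_HAIRPIN + 2) + 1:
                    for k in range(i + 2, j - MIN_HAIRPIN - 1):
                        if WM[i + 1, k - 1] < INF and WM1[k, j - 1] < INF:
                            e = (model.e_ml_closing(s, i, j)
                                 + WM[i + 1, k - 1] + WM1[k, j - 1])
                            if e < best:
                                best = e
                V[i, j] = best
            v = WM1[i, j - 1] + model.ml_c if j > i else INF
            if V[i, j] < INF and i >= 1 and j <= n - 2:
                v = min(v, V[i, j] + model.e_ml_branch(s, i, j))
            WM1[i, j] = v
            m = INF
            for k in range(i, j - MIN_HAIRPIN):
                if WM1[k, j] < INF:
                    left = model.ml_c * (k - i)
                    if k > i and WM[i, k - 1] < INF:
                        left = min(left, WM[i, k - 1])
                    m = min(m, left + WM1[k, j])
            WM[i, j] = m

    W = np.zeros(n + 1)
    for j in range(n):
        best = W[j]
        for i in range(0, j - MIN_HAIRPIN):
            if V[i, j] < INF:
                e = W[i] + V[i, j] + wext_e(i, j)
                if e < best:
                    best = e
        W[j + 1] = best

    pairs: set[tuple[int, int]] = set()
    TOL = 1e-9

    def trace_v(i, j):
        pairs.add((i, j))
        e = V[i, j]
        if abs(e - model.e_hairpin(s, i, j)) <= TOL:
            return
        kmax = j - MIN_HAIRPIN - 2
        for k in range(i + 1, kmax + 1):
            u1 = k - i - 1
            if u1 > MAX_LOOP:
                break
            lmin = max(k + MIN_HAIRPIN + 1, j - 1 - (MAX_LOOP - u1))
            for l in range(lmin, j):
                if V[k, l] < INF and abs(e - (model.e_interior(s, i, j, k, l)
                                              + V[k, l])) <= TOL:
                    trace_v(k, l)
                    return
        for k in range(i + 2, j - MIN_HAIRPIN - 1):
            if WM[i + 1, k - 1] < INF and WM1[k, j - 1] < INF:
                cand = (model.e_ml_closing(s, i, j)
                        + WM[i + 1, k - 1] + WM1[k, j - 1])
                if abs(e - cand) <= TOL:
                    trace_wm(i + 1, k - 1)
                    trace_wm1(k, j - 1)
                    return
        raise AssertionError("MFE traceback failed")

    def trace_wm1(i, j):
        e = WM1[i, j]
        if (V[i, j] < INF
                and abs(e - (V[i, j] + model.e_ml_branch(s, i, j))) <= TOL):
            trace_v(i, j)
            return
        trace_wm1_tail(i, j)

    def trace_wm1_tail(i, j):
        # peel trailing unpaired nucleotides
        jj = j
        while jj > i and abs(WM1[i, jj] - (WM1[i, jj - 1] + model.ml_c)) <= TOL:
            jj -= 1
            if (V[i, jj] < INF
                    and abs(WM1[i, jj] - (V[i, jj]
                                          + model.e_ml_branch(s, i, jj))) <= TOL):
                trace_v(i, jj)
                return
        raise AssertionError("WM1 traceback failed")

    def trace_wm(i, j):
        e = WM[i, j]
        for k in range(i, j - MIN_HAIRPIN):
            if WM1[k, j] >= INF:
                continue
            if abs(e - (model.ml_c * (k - i) + WM1[k, j])) <= TOL:
                trace_wm1(k, j)
                return
            if k > i and WM[i, k - 1] < INF and abs(
                    e - (WM[i, k - 1] + WM1[k, j])) <= TOL:
                trace_wm(i, k - 1)
                trace_wm1(k, j)
                return
        raise AssertionError("WM traceback failed")

    def trace_w(j):
        while j >= 0:
            if abs(W[j + 1] - W[j]) <= TOL:
                j -= 1
                continue
            done = False
            for i in range(0, j - MIN_HAIRPIN):
                if V[i, j] < INF and abs(
                        W[j + 1] - (W[i] + V[i, j] + wext_e(i, j))) <= TOL:
                    trace_v(i, j)
                    j = i - 1
                    done = True
                    break
            if not done:
                raise AssertionError("exterior traceback failed")

    if n > MIN_HAIRPIN:
        trace_w(n - 1)
    energy = float(W[n])
    return SecondaryStructure(n, frozenset(pairs)), energy
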