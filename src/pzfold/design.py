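"""Stochastic inverse folding: find sequences that minimize the normalized
ensemble defect (NED) against a target secondary structure.

The designer initializes each target pair from biased pair-type weights
(DNA-PZ default: P-Z 20%, G-C 50%, A-T 30%; canonical: G-C/A-T 50/50) and
each unpaired position from loop weights (A 60%, C 10%, G 10%, T 20%; P and
Z are never placed in loops), then refines by redrawing one pair or loop
position at a time -- selected with probability proportional to its defect
contribution -- keeping only changes that strictly lower the NED.  This is a
single-level defect-weighted stochastic refinement in the spirit of the
ensemble-defect optimizers used by NUPACK-style designers; no hierarchical
structure decomposition is performed.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alphabet import CANONICAL_DNA, DNA_PZ, AlphabetMode, Sequence
from .energy import EnergyModel, SecondaryStructure
from .folding import ned, partition_function
from .parameters import ParameterSet

__all__ = [
    "SelectionBias",
    "DesignConfig",
    "DesignResult",
    "initialize_sequence",
    "refine",
    "design_batch",
    "paired_comparison",
]


@dataclass(frozen=True)
class SelectionBias:
    """Pair-type and loop-base selection probabilities."""

    pair_weights: dict[str, float]
    loop_weights: dict[str, float]

    def __post_init__(self) -> None:
        for name, w in (("pair", self.pair_weights), ("loop", self.loop_weights)):
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} weights sum to {total}, not 1")
            if any(v < 0 for v in w.values()):
                raise ValueError(f"{name} weights must be nonnegative")
        if set(self.loop_weights) - set("ACGT"):
            raise ValueError("P and Z are never selected for loops")

    @classmethod
    def default(cls, mode: AlphabetMode = DNA_PZ) -> "SelectionBias":
        loops = {"A": 0.60, "C": 0.10, "G": 0.10, "T": 0.20}
        if "P" in {b for pair in mode.allowed_pairs for b in pair}:
            pairs = {"PZ": 0.20, "GC": 0.50, "AT": 0.30}
        else:
            pairs = {"GC": 0.50, "AT": 0.50}
        return cls(pair_weights=pairs, loop_weights=loops)


@dataclass(frozen=True)
class DesignConfig:
    bias: SelectionBias | None = None
    seed: int | None = None
    ned_threshold: float = 0.01
    max_iterations: int = 2000
    wall_time_limit: float | None = None
    allow_isolated_pairs: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.ned_threshold <= 1.0):
            raise ValueError("NED threshold must be in (0, 1]")


@dataclass
class DesignResult:
    sequence: Sequence
    ned: float
    iterations_used: int
    elapsed: float
    seed: int
    trajectory: list[float] = field(default_factory=list)


def _isolated_pairs(target: SecondaryStructure) -> list[tuple[int, int]]:
    pairs = set(target.pairs)
    out = []
    for i, j in pairs:
        if (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs:
            out.append((i, j))
    return out


def _validate_target(target: SecondaryStructure, config: DesignConfig) -> None:
    # SecondaryStructure already enforces nesting and hairpin >= 3
    if not config.allow_isolated_pairs and _isolated_pairs(target):
        raise ValueError("target contains isolated base pairs and "
                         "allow_isolated_pairs is off")


def _draw_pair(bias: SelectionBias, rng: np.random.Generator) -> tuple[str, str]:
    kinds = sorted(bias.pair_weights)
    probs = np.array([bias.pair_weights[k] for k in kinds])
    kind = kinds[rng.choice(len(kinds), p=probs)]
    a, b = kind[0], kind[1]
    return (a, b) if rng.random() < 0.5 else (b, a)


def _draw_loop(bias: SelectionBias, rng: np.random.Generator) -> str:
    bases = sorted(bias.loop_weights)
    probs = np.array([bias.loop_weights[b] for b in bases])
    return bases[rng.choice(len(bases), p=probs)]


def initialize_sequence(target: SecondaryStructure, bias: SelectionBias,
                        rng: np.random.Generator) -> Sequence:
    """Biased random sequence consistent with the target's pairing."""
    out = [""] * target.length
    for i, j in sorted(target.pairs):
        a, b = _draw_pair(bias, rng)
        out[i], out[j] = a, b
    for k in range(target.length):
        if not out[k]:
            out[k] = _draw_loop(bias, rng)
    return Sequence(tuple(out))


def refine(seq: Sequence, target: SecondaryStructure, config: DesignConfig,
           params: ParameterSet | EnergyModel,
           rng: np.random.Generator | None = None,
           seed_used: int | None = None) -> DesignResult:
    """Defect-weighted stochastic refinement; returns the best-seen sequence.

    Each iteration redraws one element (a target pair, jointly, or one loop
    position), chosen with probability proportional to its current defect
    contribution; the change is kept only if it strictly lowers the NED.
    """
    model = params if isinstance(params, EnergyModel) else EnergyModel(params)
    _validate_target(target, config)
    bias = config.bias or SelectionBias.default(model.params.mode)
    mode = model.params.mode
    for kind in bias.pair_weights:
        if not mode.can_pair(kind[0], kind[1]):
            raise ValueError(f"pair type {kind} is not allowed in {mode.name}")
    for i, j in target.pairs:
        if not mode.can_pair(seq[i], seq[j]):
            raise ValueError(
                f"sequence is inconsistent with the target: {seq[i]}-{seq[j]} "
                f"at pair ({i + 1},{j + 1}) is not allowed in {mode.name}")
    if rng is None:
        seed_used = config.seed if config.seed is not None else (
            time.time_ns() % (2 ** 31))
        rng = np.random.default_rng(seed_used)
    if seed_used is None:
        seed_used = -1

    pairs = sorted(target.pairs)
    loops = [k for k in range(target.length)
             if all(k not in pr for pr in pairs)]
    partner = target.partner
    t0 = time.monotonic()

    current = list(seq.bases)

    def evaluate(bases: list[str]):
        pf = partition_function(np.array(
            [("ACGTPZ").index(b) for b in bases], dtype=np.int8), model)
        return ned(pf.seq, target, pf.pair_probabilities())

    report = evaluate(current)
    best = (report.ned, tuple(current))
    trajectory = [report.ned]
    iters = 0

    while (report.ned > config.ned_threshold
           and iters < config.max_iterations
           and (config.wall_time_limit is None
                or time.monotonic() - t0 < config.wall_time_limit)):
        iters += 1
        defect = report.per_position
        weights = ([defect[i] + defect[j] for i, j in pairs]
                   + [defect[k] for k in loops])
        weights = np.maximum(np.array(weights), 1e-12)
        pick = int(rng.choice(len(weights), p=weights / weights.sum()))
        cand = list(current)
        if pick < len(pairs):
            i, j = pairs[pick]
            a, b = _draw_pair(bias, rng)
            cand[i], cand[j] = a, b
        else:
            k = loops[pick - len(pairs)]
            cand[k] = _draw_loop(bias, rng)
        if cand == current:
            trajectory.append(report.ned)
            continue
        cand_report = evaluate(cand)
        if cand_report.ned < report.ned:
            current = cand
            report = cand_report
            if report.ned < best[0]:
                best = (report.ned, tuple(current))
        trajectory.append(report.ned)

    return DesignResult(
        sequence=Sequence(best[1]), ned=best[0], iterations_used=iters,
        elapsed=time.monotonic() - t0, seed=seed_used, trajectory=trajectory)


def design_batch(target: SecondaryStructure, config: DesignConfig,
                 n_attempts: int, params: ParameterSet | EnergyModel,
                 seeds: list[int] | None = None) -> dict:
    """Independent seeded attempts plus a summary (best/mean NED, mean time).

    ``seeds`` overrides the per-attempt seeds; otherwise they derive
    deterministically from ``config.seed`` (or the clock when unset, with the
    seed used always recorded in each result).
    """
    if n_attempts < 1:
        raise ValueError("n_attempts must be at least 1")
    if seeds is None:
        root = config.seed if config.seed is not None else (
            time.time_ns() % (2 ** 31))
        seeds = [int(s) for s in
                 np.random.SeedSequence(root).generate_state(n_attempts) % (2 ** 31)]
    if len(seeds) != n_attempts:
        raise ValueError("need one seed per attempt")
    model = params if isinstance(params, EnergyModel) else EnergyModel(params)
    bias = config.bias or SelectionBias.default(model.params.mode)
    results = []
    for s in seeds:
        rng = np.random.default_rng(s)
        seq0 = initialize_sequence(target, bias, rng)
        results.append(refine(seq0, target, config, model, rng=rng, seed_used=s))
    neds = [r.ned for r in results]
    times = [r.elapsed for r in results]
    return {
        "results": results,
        "best_ned": float(min(neds)),
        "mean_ned": float(np.mean(neds)),
        "mean_time": float(np.mean(times)),
        "seeds": list(seeds),
    }


def paired_comparison(results_a, results_b, metric: str = "ned",
                      kind: str = "paired", alternative: str = "less") -> dict:
    """One-sided t test comparing two design-result groups.

    ``kind='paired'`` performs a paired t test over matched targets;
    ``kind='welch'`` an unequal-variance two-sample test.  ``alternative``
    follows scipy semantics for group A versus group B.  The type I error
    rate is 0.05.
    """

    def values(results):
        out = []
        for r in results:
            if isinstance(r, (int, float)):
                out.append(float(r))
            elif metric == "ned":
                out.append(r.ned)
            elif metric == "time":
                out.append(r.elapsed)
            else:
                raise ValueError(f"unknown metric {metric!r}")
        return np.array(out)

    a, b = values(results_a), values(results_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if kind == "paired":
        if len(a) != len(b):
            raise ValueError("paired test needs matched groups")
        res = stats.ttest_rel(a, b, alternative=alternative)
    elif kind == "welch":
        res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "n": (len(a), len(b)),
        "alpha": 0.05,
        "significant": bool(res.pvalue < 0.05),
    }
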