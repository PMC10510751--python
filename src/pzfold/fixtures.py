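"""Synthetic fixtures: duplex-stability datasets with known ("planted")
parameters, symmetric multibranch design targets, and noisy melt curves.

Everything is reproducible bit-for-bit from its arguments and seed.  The
generators emulate the structure of real inputs -- per-duplex optical melting
summaries, Eterna-style symmetric targets with four arms of three-way
junctions ("iron-cross" topology), and two-concentration melt experiments
with pipetting errors -- without emulating instrument noise spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import (
    BASES,
    COMPLEMENT,
    DNA_PZ,
    Sequence,
    StackKey,
    canonical_stack_key,
    parse_sequence,
)
from .duplex import DuplexSpec
from .energy import SecondaryStructure
from .meltfit import GlobalMeltModel, MeltCurve, SingleStrandBaseline, simulate_melt
from .nnfit import MeltSummary, _fixed_prediction, _stack_keys, _terminal_pz_count, FitStage
from .parameters import ParameterSet

__all__ = [
    "PAPER_DUPLEXES",
    "gen_duplex_dataset",
    "gen_cross_target",
    "gen_melt_fixture",
    "default_baselines",
]

#: Self-complementary duplex strands named in the primary report's main text
#: (experimental values live in its supplement and are not packaged).
PAPER_DUPLEXES = ("GTPPZZAC", "GAZZPPTC", "ZGCATGCP")


# ---------------------------------------------------------------------------
# duplex-stability datasets for the regression stages


def _complement_strand(top: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(top))


def _random_pz_strand(rng: np.random.Generator, length: int) -> str:
    """Random strand with at least one P or Z pair position."""
    letters = list("ACGT")
    top = [letters[rng.integers(4)] for _ in range(length)]
    # embed one or two P/Z positions
    n_pz = int(rng.integers(1, 3))
    pos = rng.choice(length, size=min(n_pz, length), replace=False)
    for p in pos:
        top[p] = "P" if rng.random() < 0.5 else "Z"
    return "".join(top)


def gen_duplex_dataset(
    n: int,
    truth: dict[StackKey, float],
    noise_sd: float,
    seed: int,
    params: ParameterSet,
    end_penalty: float = 0.0,
    min_len: int = 6,
    max_len: int = 12,
) -> list[MeltSummary]:
    """Random all-helix duplexes whose dG37 values are generated from
    ``truth`` (free P/Z-containing stacks) on top of the canonical fixed
    terms, plus Gaussian noise.

    Every free stack in ``truth`` appears in at least two duplexes; an
    optional terminal P-Z ``end_penalty`` is planted per terminal P-Z pair.
    Raises if coverage cannot be met at the requested ``n``.
    """
    rng = np.random.default_rng(seed)
    need = list(truth)
    if n < 2 * len(need) / max(min_len - 1, 1):
        raise ValueError(f"n = {n} cannot cover {len(need)} stacks twice")

    duplexes: list[DuplexSpec] = []
    counts: dict[StackKey, int] = {k: 0 for k in need}

    def embed(key: StackKey, rng) -> DuplexSpec:
        top2 = "".join(key[0])
        length = int(rng.integers(min_len, max_len + 1))
        at = int(rng.integers(0, length - 1))
        letters = list("ACGT")
        top = [letters[rng.integers(4)] for _ in range(length)]
        top[at], top[at + 1] = top2[0], top2[1]
        tops = "".join(top)
        return DuplexSpec.from_strings(tops, _complement_strand(tops))

    # deterministic coverage first: two embeddings per free stack
    for key in need:
        for _ in range(2):
            duplexes.append(embed(key, rng))
    # random extras up to n
    while len(duplexes) < n:
        tops = _random_pz_strand(rng, int(rng.integers(min_len, max_len + 1)))
        duplexes.append(DuplexSpec.from_strings(tops, _complement_strand(tops)))

    out: list[MeltSummary] = []
    stage = FitStage("pz")
    for k, d in enumerate(duplexes):
        fixed = _fixed_prediction(d, params, stage)
        free_sum = 0.0
        for key in _stack_keys(d, params):
            if key in truth:
                free_sum += truth[key]
                counts[key] = counts.get(key, 0) + 1
            elif key not in params.stacks:
                raise ValueError(f"truth does not cover stack {key}")
        value = fixed + free_sum
        value += end_penalty * _terminal_pz_count(d, params)
        value += noise_sd * rng.standard_normal() if noise_sd > 0 else 0.0
        out.append(MeltSummary(duplex=d, dG37_exp=float(value),
                               id=f"syn{k:03d}", source="synthetic"))

    short = [k for k, c in counts.items() if c < 2]
    if short:
        raise ValueError(f"coverage unattainable at n = {n}: {short}")
    return out


# ---------------------------------------------------------------------------
# symmetric multibranch design targets


def gen_cross_target(arms: int = 4, stem_len: int = 3,
                     branches: bool = True, loop_len: int = 4,
                     spacer: int = 2) -> SecondaryStructure:
    """Symmetric target with ``arms`` branches from a central exterior loop.

    Each arm is a helix of ``stem_len`` pairs ending either in a hairpin loop
    (``branches=False``) or in a three-way junction carrying two sub-helices
    of ``stem_len`` pairs with ``loop_len``-nt hairpins (``branches=True``) --
    the iron-cross topology at configurable scale.
    """
    if arms < 3:
        raise ValueError("a symmetric cross target needs at least 3 arms")
    if stem_len < 1:
        raise ValueError("stem_len must be at least 1")
    if loop_len < 3:
        raise ValueError("hairpin loops must have at least 3 nucleotides")

    db: list[str] = []

    def hairpin_arm():
        db.extend("(" * stem_len)
        db.extend("." * loop_len)
        db.extend(")" * stem_len)

    def branch_arm():
        db.extend("(" * stem_len)
        db.append(".")
        db.extend("(" * stem_len)
        db.extend("." * loop_len)
        db.extend(")" * stem_len)
        db.append(".")
        db.extend("(" * stem_len)
        db.extend("." * loop_len)
        db.extend(")" * stem_len)
        db.append(".")
        db.extend(")" * stem_len)

    for a in range(arms):
        if a:
            db.extend("." * spacer)
        branch_arm() if branches else hairpin_arm()

    from .structio import parse_dotbracket

    return parse_dotbracket("".join(db))


# ---------------------------------------------------------------------------
# melt-curve fixtures


def default_baselines() -> tuple[SingleStrandBaseline, SingleStrandBaseline]:
    """Linear per-molar single-strand baselines for the two strands.

    Chosen so that 1 uM of strand absorbs ~0.1-0.15 at 260 nm and gains
    25-30% on heating.  The strands differ in level and in the midpoint and
    amplitude of their broad unstacking transitions, as measured
    single-strand curves do; those shape differences are what make the
    excess-strand assignments distinguishable.
    """
    return (SingleStrandBaseline(intercept=1.25e5, slope=100.0, quad=5.0),
            SingleStrandBaseline(intercept=1.0e5, slope=600.0, quad=-2.5))


def gen_melt_fixture(
    seed: int,
    truth: GlobalMeltModel | None = None,
    noise_sd: float = 3e-4,
    pipetting: float = 0.05,
    grid: np.ndarray | None = None,
    nominal_CT: tuple[float, float] = (1e-6, 5e-6),
) -> tuple[tuple[MeltCurve, ...], GlobalMeltModel,
           tuple[SingleStrandBaseline, SingleStrandBaseline]]:
    """Simulated two-concentration melt with planted pipetting errors.

    One strand per melt is pipetted high by ``pipetting`` (fractionally) and
    the other low, with the excess strand drawn at random, so the true
    excess-strand assignment is well defined.  Gaussian absorbance noise of
    ``noise_sd`` is added.  Returns (curves, truth model, baselines).
    """
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.arange(12.0, 95.0 + 0.25, 0.5)
    baselines = default_baselines()
    if truth is None:
        conc = []
        excess = []
        for ct in nominal_CT:
            # independent per-cuvette pipetting errors.  The excess-strand
            # label is undefined as the imbalance vanishes, so near-equal
            # draws are resampled until the imbalance reaches the typical
            # error scale; gross (>2 sigma) errors are resampled too, as an
            # experimenter identifies and repeats such samples
            while True:
                eA, eB = pipetting * rng.standard_normal(2)
                if abs(eA - eB) >= pipetting and max(abs(eA), abs(eB)) <= 2 * pipetting:
                    break
            conc.append((ct / 2.0 * (1 + eA), ct / 2.0 * (1 + eB)))
            excess.append("A" if eA > eB else "B")
        truth = GlobalMeltModel(
            dH=-70.0, dS=-190.0, hypochromicity=0.18, ds_slope=100.0,
            concentrations=tuple(conc), excess_assignment=tuple(excess))
    curves = simulate_melt(truth, baselines, grid)
    noisy = tuple(
        MeltCurve(c.temperatures,
                  c.absorbance + noise_sd * rng.standard_normal(len(c.absorbance)),
                  nominal_CT=ct, label=c.label)
        for c, ct in zip(curves, nominal_CT))
    return noisy, truth, baselines
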