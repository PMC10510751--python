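"""Global two-state fitting of optical melting curves at multiple strand
concentrations.

Two absorbance-vs-temperature curves (nominally 1 and 5 uM total strand) are
fitted simultaneously with six shared parameters: dH, dS, a common duplex
hypochromicity, a common duplex absorbance slope, and one free single-strand
concentration per melt -- the concentration of the strand designated in
excess; the other strand's concentration is determined from the total
absorbance at the top of the curve, where the sample is essentially fully
melted.  The fit is repeated for all four excess-strand assignments, and the
assignment with the lowest residual among those whose fitted concentrations
deviate from nominal by at most 15% is selected (pipetting errors are
typically about 5%).

The duplex equilibrium A + B <=> AB is solved exactly for unequal strand
concentrations, and predicted absorbance includes the remaining excess
single strand:

    A(T) = [A]free * bA(T) + [B]free * bB(T)
           + [AB] * ((1 - h) * (bA(Tref) + bB(Tref)) + m_ds * (T - Tref))

with per-molar single-strand baselines bX(T) (measured or linear) and
Tref = 25 C.  This forward model is the implementation's definition of how
duplex absorbance splits between hypochromicity and the linear dsDNA slope.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .parameters import T_REF

__all__ = [
    "MeltCurve",
    "SingleStrandBaseline",
    "GlobalMeltModel",
    "MeltFitResult",
    "MeltCurveModel",
    "duplex_fraction",
    "simulate_melt",
    "global_fit",
]

R_CAL = 1.987  # cal/(mol K)
T_REF_BASELINE_C = 25.0


@dataclass(frozen=True)
class MeltCurve:
    """One absorbance-vs-temperature melt at one nominal total concentration."""

    temperatures: np.ndarray  # deg C, strictly increasing
    absorbance: np.ndarray
    nominal_CT: float  # mol/L total strand
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "absorbance", a)
        if len(t) < 20:
            raise ValueError("a melt curve needs at least 20 points")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if len(t) != len(a):
            raise ValueError("temperature and absorbance lengths differ")


@dataclass(frozen=True)
class SingleStrandBaseline:
    """Per-molar single-strand absorbance versus temperature.

    Emulates a measured ssDNA curve: a linear part plus an optional quadratic
    term and a broad sigmoidal unstacking transition centered at a
    strand-specific midpoint,

        b(T) = a + s*T + c*T^2 + A_u / (1 + exp(-(T - T_mid)/w)).

    Measured single-strand curves are not straight lines; their
    strand-specific shapes are what make the excess-strand assignments of
    the global fit distinguishable, which is why measured curves are
    preferred over linearly extrapolated trendlines.
    """

    intercept: float  # absorbance per (mol/L) at 0 C
    slope: float  # absorbance per (mol/L) per deg C
    quad: float = 0.0  # absorbance per (mol/L) per deg C^2
    sig_amp: float = 0.0  # unstacking amplitude, absorbance per (mol/L)
    sig_mid: float = 45.0  # unstacking midpoint, deg C
    sig_width: float = 12.0  # unstacking width, deg C

    def at(self, T_C) -> np.ndarray:
        t = np.asarray(T_C, dtype=float)
        out = self.intercept + self.slope * t + self.quad * t * t
        if self.sig_amp:
            out = out + self.sig_amp / (1.0 + np.exp(-(t - self.sig_mid)
                                                     / self.sig_width))
        return out


@dataclass(frozen=True)
class GlobalMeltModel:
    """The six shared fit parameters plus per-melt concentrations."""

    dH: float  # kcal/mol
    dS: float  # cal/(mol K)
    hypochromicity: float
    ds_slope: float  # absorbance per (mol/L duplex) per deg C
    concentrations: tuple[tuple[float, float], ...]  # (cA, cB) per melt, mol/L
    excess_assignment: tuple[str, ...] = ()  # 'A' or 'B' per melt

    def __post_init__(self) -> None:
        if not (0.0 < self.hypochromicity < 1.0):
            raise ValueError("hypochromicity must be in (0, 1)")
        for cA, cB in self.concentrations:
            if cA <= 0 or cB <= 0:
                raise ValueError("strand concentrations must be positive")

    @property
    def dG37(self) -> float:
        return self.dH - T_REF * self.dS / 1000.0


def duplex_fraction(T_K, dH: float, dS: float, cA: float, cB: float):
    """Fraction of the limiting strand in duplex at temperature T (K).

    Solves the A + B <=> AB mass-action equilibrium with
    K(T) = exp(-(dH*1000 - T*dS) / (R*T)); numerically stable root.
    """
    T_K = np.asarray(T_K, dtype=float)
    lnK = -(dH * 1000.0 - T_K * dS) / (R_CAL * T_K)
    invK = np.exp(np.clip(-lnK, -700, 700))
    S = cA + cB + invK
    disc = np.sqrt(np.maximum(S * S - 4.0 * cA * cB, 0.0))
    ab = 2.0 * cA * cB / (S + disc)
    return np.clip(ab / min(cA, cB), 0.0, 1.0)


def _predict_absorbance(T_C, dH, dS, h, m_ds, cA, cB,
                        bA: SingleStrandBaseline, bB: SingleStrandBaseline):
    T_K = np.asarray(T_C, dtype=float) + 273.15
    frac = duplex_fraction(T_K, dH, dS, cA, cB)
    ab = frac * min(cA, cB)
    duplex_eps = ((1.0 - h) * (bA.at(T_REF_BASELINE_C) + bB.at(T_REF_BASELINE_C))
                  + m_ds * (np.asarray(T_C, dtype=float) - T_REF_BASELINE_C))
    return (cA - ab) * bA.at(T_C) + (cB - ab) * bB.at(T_C) + ab * duplex_eps


def simulate_melt(model: GlobalMeltModel,
                  baselines: tuple[SingleStrandBaseline, SingleStrandBaseline],
                  grid) -> tuple[MeltCurve, ...]:
    """Deterministic forward simulation at every melt's concentrations."""
    bA, bB = baselines
    grid = np.asarray(grid, dtype=float)
    curves = []
    for k, (cA, cB) in enumerate(model.concentrations):
        absorb = _predict_absorbance(grid, model.dH, model.dS,
                                     model.hypochromicity, model.ds_slope,
                                     cA, cB, bA, bB)
        curves.append(MeltCurve(grid, absorb, nominal_CT=cA + cB,
                                label=f"melt{k + 1}"))
    return tuple(curves)


@dataclass
class MeltFitResult:
    """Selected global fit plus the per-assignment comparison table."""

    model: GlobalMeltModel
    ssr: float
    concentration_deviation: float
    chosen_assignment: tuple[str, ...]
    assignments: pd.DataFrame
    gate_passed: bool

    @property
    def dG37(self) -> float:
        return self.model.dG37

    def summary(self) -> str:
        m = self.model
        lines = [
            "Global two-state melt fit",
            f"  dH = {m.dH:9.2f} kcal/mol",
            f"  dS = {m.dS:9.2f} cal/(mol K)",
            f"  dG37 = {m.dG37:7.3f} kcal/mol",
            f"  hypochromicity = {m.hypochromicity:.4f}",
            f"  ds slope = {m.ds_slope:.3g} abs/(M K)",
            f"  excess strands: {'/'.join(self.chosen_assignment)}"
            + ("" if self.gate_passed else "  [concentration gate FAILED]"),
            f"  ssr = {self.ssr:.3e}, max conc. deviation = "
            f"{self.concentration_deviation * 100:.1f}%",
        ]
        for k, (cA, cB) in enumerate(m.concentrations):
            lines.append(f"  melt {k + 1}: [A] = {cA * 1e6:.3f} uM, "
                         f"[B] = {cB * 1e6:.3f} uM")
        return "\n".join(lines)


class MeltCurveModel:
    """Model object for the six-parameter global melt fit.

    Parameters
    ----------
    curves : sequence of MeltCurve (two or more, distinct concentrations)
    baselines : (SingleStrandBaseline, SingleStrandBaseline) for strands A, B
    """

    MAX_CONC_DEV = 0.15

    def __init__(self, curves, baselines):
        self.curves = tuple(curves)
        if len(self.curves) < 2:
            raise ValueError("global fitting needs at least two melts")
        self.bA, self.bB = baselines

    # -- internals -----------------------------------------------------------

    def _high_T_anchor(self, curve: MeltCurve) -> tuple[float, float]:
        k = max(3, len(curve.temperatures) // 20)
        return (float(curve.temperatures[-k:].mean()),
                float(curve.absorbance[-k:].mean()))

    def _concentrations(self, assignment, c_free) -> list[tuple[float, float]]:
        out = []
        for curve, who, c_ex in zip(self.curves, assignment, c_free):
            Th, Ah = self._high_T_anchor(curve)
            bA_h = float(self.bA.at(Th))
            bB_h = float(self.bB.at(Th))
            if who == "A":
                cA = c_ex
                cB = max((Ah - cA * bA_h) / bB_h, 1e-12)
            else:
                cB = c_ex
                cA = max((Ah - cB * bB_h) / bA_h, 1e-12)
            out.append((cA, cB))
        return out

    def _residuals(self, p, assignment):
        dH, dS, h, m_ds = p[:4]
        conc = self._concentrations(assignment, p[4:])
        res = []
        for curve, who, (cA, cB) in zip(self.curves, assignment, conc):
            pred = _predict_absorbance(curve.temperatures, dH, dS, h, m_ds,
                                       cA, cB, self.bA, self.bB)
            res.append(pred - curve.absorbance)
            # the designated excess strand must not be the limiting one;
            # a soft penalty keeps each assignment a distinct hypothesis
            viol = (cB - cA) if who == "A" else (cA - cB)
            res.append(np.array([max(0.0, viol / curve.nominal_CT) * 10.0]))
        return np.concatenate(res)

    def _initial_guesses(self, rng, n_starts):
        c0 = self.curves[0]
        dA = np.gradient(c0.absorbance, c0.temperatures)
        Tm0 = float(c0.temperatures[int(np.argmax(dA))]) + 273.15
        amp = (c0.absorbance[-1] - c0.absorbance[0]) / max(c0.absorbance[-1], 1e-12)
        h0 = float(np.clip(amp, 0.05, 0.4))
        guesses = []
        for _ in range(n_starts):
            dH0 = -70.0 * (1.0 + 0.15 * rng.standard_normal())
            dS0 = (dH0 * 1000.0 / Tm0
                   - R_CAL * math.log(self.curves[0].nominal_CT / 4.0))
            guesses.append([dH0, dS0, h0 * (1 + 0.2 * rng.standard_normal()),
                            0.0]
                           + [c.nominal_CT / 2.0 * (1 + 0.05 * rng.standard_normal())
                              for c in self.curves])
        return guesses

    # -- fitting -------------------------------------------------------------

    def fit(self, seed: int = 0, n_starts: int = 3,
            max_conc_dev: float | None = None) -> MeltFitResult:
        """Nonlinear least squares over all excess-strand assignments."""
        rng = np.random.default_rng(seed)
        max_dev = self.MAX_CONC_DEV if max_conc_dev is None else max_conc_dev
        n_melts = len(self.curves)
        lo = [-300.0, -900.0, 0.01, -5e3] + [c.nominal_CT * 0.05 for c in self.curves]
        hi = [-5.0, -5.0, 0.6, 5e3] + [c.nominal_CT * 2.0 for c in self.curves]
        x_scale = [10.0, 30.0, 0.05, 100.0] + [c.nominal_CT / 2
                                               for c in self.curves]
        rows = []
        best_per_assignment = {}
        for assignment in itertools.product("AB", repeat=n_melts):
            best = None
            for x0 in self._initial_guesses(rng, n_starts):
                x0 = np.clip(x0, lo, hi)
                try:
                    sol = least_squares(
                        self._residuals, x0, args=(assignment,),
                        bounds=(lo, hi), method="trf", x_scale=x_scale)
                except Exception:
                    continue
                ssr = float(np.sum(sol.fun ** 2))
                if best is None or ssr < best[0]:
                    best = (ssr, sol.x)
            if best is None:
                continue
            # polish with tight tolerances so assignment selection compares
            # converged optima rather than optimizer noise
            try:
                sol = least_squares(
                    self._residuals, best[1], args=(assignment,),
                    bounds=(lo, hi), method="trf", x_scale=x_scale,
                    ftol=1e-14, xtol=1e-14, gtol=1e-14)
                ssr = float(np.sum(sol.fun ** 2))
                if ssr < best[0]:
                    best = (ssr, sol.x)
            except Exception:
                pass
            ssr, x = best
            conc = self._concentrations(assignment, x[4:])
            dev = max(abs(c - curve.nominal_CT / 2.0) / (curve.nominal_CT / 2.0)
                      for curve, pair in zip(self.curves, conc) for c in pair)
            best_per_assignment[assignment] = (ssr, x, conc, dev)
            rows.append({"assignment": "/".join(assignment), "ssr": ssr,
                         "conc_deviation": dev, "dH": x[0], "dS": x[1]})
        if not best_per_assignment:
            raise RuntimeError("no excess-strand assignment converged; "
                               "check baselines and curve quality")
        table = pd.DataFrame(rows).sort_values("ssr").reset_index(drop=True)
        passing = {a: v for a, v in best_per_assignment.items() if v[3] <= max_dev}
        gate_passed = bool(passing)
        pool = passing if passing else best_per_assignment
        chosen = min(pool, key=lambda a: pool[a][0])
        ssr, x, conc, dev = pool[chosen]
        model = GlobalMeltModel(
            dH=float(x[0]), dS=float(x[1]), hypochromicity=float(x[2]),
            ds_slope=float(x[3]), concentrations=tuple(conc),
            excess_assignment=tuple(chosen))
        return MeltFitResult(model=model, ssr=ssr, concentration_deviation=dev,
                             chosen_assignment=tuple(chosen), assignments=table,
                             gate_passed=gate_passed)


def global_fit(curves, baselines, seed: int = 0, **kwargs) -> MeltFitResult:
    """Functional wrapper around :class:`MeltCurveModel`."""
    return MeltCurveModel(curves, baselines).fit(seed=seed, **kwargs)
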