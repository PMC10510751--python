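"""Staged ordinary-least-squares fitting of nearest-neighbor stack parameters.

Per-duplex melting summaries (dG37, optionally dH/dS) are reduced by the
fixed contributions -- canonical Watson-Crick-Franklin stacks, intermolecular
initiation, the symmetry correction for self-complementary duplexes and
terminal A-T penalties -- and the remaining stability is regressed on the
occurrence counts of the free stacks (rotational symmetry collapsed onto
canonical stack keys).  Stages:

``pz``
    free terms are stacks containing a P-Z pair (canonical stacks fixed);
``gz``
    free terms are stacks containing a G-Z pair (canonical and P-Z fixed);
``dh-pz`` / ``ds-pz``
    the same design matrix fitted to enthalpy / entropy data.

An optional terminal P-Z end-penalty column supports the end-correction
hypothesis test; outlier exclusion is explicit and by duplex id, never
automatic.  Parameter uncertainties are the standard errors of the
regression.  The model/results split follows statsmodels conventions and the
regression itself is delegated to :class:`statsmodels.api.OLS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .alphabet import StackKey, canonical_stack_key
from .duplex import DuplexSpec, _alignment
from .parameters import ParameterSet

__all__ = [
    "MeltSummary",
    "FitStage",
    "StackRegression",
    "StackFitResults",
    "residual_stability",
    "end_penalty_report",
]

END_PENALTY_TERM = "terminal_PZ"

_PZ = frozenset("PZ")
_GZ = frozenset("GZ")


@dataclass(frozen=True)
class MeltSummary:
    """Experimental two-state stability of one duplex."""

    duplex: DuplexSpec
    dG37_exp: float
    dH_exp: float | None = None
    dS_exp: float | None = None
    id: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        if not np.isfinite(self.dG37_exp):
            raise ValueError(f"duplex {self.id}: dG37_exp must be finite")


@dataclass(frozen=True)
class FitStage:
    """Which terms are free, which response is fitted."""

    stage: str = "pz"  # pz | gz | dh-pz | ds-pz
    include_end_penalty: bool = False

    def __post_init__(self) -> None:
        if self.stage not in ("pz", "gz", "dh-pz", "ds-pz"):
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def response(self) -> str:
        return {"pz": "dG37_exp", "gz": "dG37_exp",
                "dh-pz": "dH_exp", "ds-pz": "dS_exp"}[self.stage]


def _stack_keys(duplex: DuplexSpec, params: ParameterSet) -> list[StackKey]:
    """Canonical keys of all interior stacks of a (fully paired) duplex."""
    cols, left, right = _alignment(duplex, params)
    for a, b in cols:
        if not params.mode.can_pair(a, b):
            raise ValueError(
                f"duplex {duplex.top.id or str(duplex.top)}: column {a}-{b} "
                "is not a pair; fitting supports all-helix duplexes")
    keys = []
    for k in range(len(cols) - 1):
        (a, b), (c, d) = cols[k], cols[k + 1]
        keys.append(canonical_stack_key((a, c), (b, d), params.mode))
    return keys


def _is_free(key: StackKey, stage: str) -> bool:
    pairs = [frozenset((key[0][c], key[1][c])) for c in (0, 1)]
    has_pz = _PZ in pairs
    has_gz = _GZ in pairs
    if stage in ("pz", "dh-pz", "ds-pz"):
        return has_pz and not has_gz
    return has_gz  # gz stage


def _terminal_pz_count(duplex: DuplexSpec, params: ParameterSet) -> int:
    cols, _, _ = _alignment(duplex, params)
    return sum(frozenset(cols[k]) == _PZ for k in (0, -1))


def _fixed_prediction(duplex: DuplexSpec, params: ParameterSet,
                      stage: FitStage) -> float:
    """Sum of all fixed contributions for the stage's response variable."""
    pen = params.penalties
    keys = _stack_keys(duplex, params)
    if stage.stage == "pz" or stage.stage == "gz":
        total = pen.intermolecular_initiation
        if duplex.is_self_complementary:
            total += pen.symmetry_correction
        cols, _, _ = _alignment(duplex, params)
        for k in (0, -1):
            total += params.terminal_penalty(*cols[k])
        for key in keys:
            # in the gz stage the P-Z stacks are among the fixed terms
            if not _is_free(key, stage.stage):
                total += params.stacks[key].dG37
        return total
    # enthalpy / entropy stages
    if stage.stage == "dh-pz":
        total = pen.initiation_dH
        get = params.stack_dH
        term = pen.terminal_AT_dH
        sym = 0.0
    else:
        total = pen.initiation_dS
        get = params.stack_dS
        term = pen.terminal_AT_dS
        sym = pen.symmetry_dS
    if duplex.is_self_complementary:
        total += sym
    cols, _, _ = _alignment(duplex, params)
    for k in (0, -1):
        if frozenset(cols[k]) == frozenset("AT"):
            total += term
    for key in keys:
        if not _is_free(key, "pz"):
            total += get(key)
    return total


def residual_stability(summary: MeltSummary, params: ParameterSet,
                       stage: FitStage | None = None) -> float:
    """Experimental value minus every fixed contribution.

    What remains is attributable to the stage's free terms (plus noise).
    """
    stage = stage or FitStage("pz")
    y = getattr(summary, stage.response)
    if y is None:
        raise ValueError(f"duplex {summary.id}: no {stage.response} value")
    return float(y - _fixed_prediction(summary.duplex, params, stage))


class StackRegression:
    """OLS model for stack nearest-neighbor parameters.

    Parameters
    ----------
    data : list of MeltSummary
    stage : FitStage
    params : ParameterSet
        Source of the fixed-term values (canonical stacks, penalties, and,
        for the gz stage, the P-Z stacks).
    """

    def __init__(self, data: list[MeltSummary], stage: FitStage,
                 params: ParameterSet):
        if not data:
            raise ValueError("no data")
        self.data = list(data)
        self.stage = stage
        self.params = params
        self.ids = [s.id or f"duplex{k}" for k, s in enumerate(self.data)]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplex ids must be unique")

        free: dict[StackKey, None] = {}
        for s in self.data:
            for key in _stack_keys(s.duplex, params):
                if _is_free(key, "pz" if stage.stage in ("dh-pz", "ds-pz")
                            else stage.stage):
                    free.setdefault(key)
        self.free_terms: list[StackKey] = sorted(free)
        self.columns = [self._term_name(k) for k in self.free_terms]
        if stage.include_end_penalty:
            self.columns.append(END_PENALTY_TERM)

    @staticmethod
    def _term_name(key: StackKey) -> str:
        return f"{''.join(key[0])}/{''.join(key[1])}"

    def design_matrix(self, exclude_ids: tuple[str, ...] = ()) -> pd.DataFrame:
        rows, y, kept = [], [], []
        for sid, s in zip(self.ids, self.data):
            if sid in exclude_ids:
                continue
            counts = dict.fromkeys(self.columns, 0.0)
            for key in _stack_keys(s.duplex, self.params):
                name = self._term_name(key)
                if name in counts:
                    counts[name] += 1.0
            if self.stage.include_end_penalty:
                counts[END_PENALTY_TERM] = float(
                    _terminal_pz_count(s.duplex, self.params))
            rows.append(counts)
            y.append(residual_stability(s, self.params, self.stage))
            kept.append(sid)
        X = pd.DataFrame(rows, index=kept, columns=self.columns)
        X["__y__"] = y
        return X

    def fit(self, exclude_ids: tuple[str, ...] = ()) -> "StackFitResults":
        for sid in exclude_ids:
            if sid not in self.ids:
                raise ValueError(f"excluded id {sid!r} not in the data")
        tab = self.design_matrix(tuple(exclude_ids))
        y = tab.pop("__y__")
        X = tab
        if len(X) < len(self.columns):
            raise ValueError(
                f"{len(X)} duplexes cannot identify {len(self.columns)} terms")
        rank = int(np.linalg.matrix_rank(X.to_numpy()))
        if rank < len(self.columns):
            # name terms not identifiable from the data
            _, _, vt = np.linalg.svd(X.to_numpy())
            null = vt[rank:]
            bad = [c for k, c in enumerate(self.columns)
                   if np.abs(null[:, k]).max() > 1e-8]
            raise ValueError("rank-deficient design matrix; unidentifiable "
                             f"terms: {', '.join(bad)}")
        res = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
        estimates = pd.Series(res.params, index=self.columns)
        stderrs = pd.Series(res.bse, index=self.columns)
        resid = pd.Series(res.resid, index=X.index)
        return StackFitResults(
            model=self, estimates=estimates, stderrs=stderrs,
            residuals=resid, design_matrix_rank=rank,
            excluded=tuple(exclude_ids), nobs=len(X),
            s2=float(res.mse_resid) if len(X) > len(self.columns) else 0.0)


@dataclass
class StackFitResults:
    """Estimates, standard errors of the regression, and residuals."""

    model: StackRegression
    estimates: pd.Series
    stderrs: pd.Series
    residuals: pd.Series
    design_matrix_rank: int
    excluded: tuple[str, ...]
    nobs: int
    s2: float = 0.0

    def conf_int(self, n_sigma: float = 1.96) -> pd.DataFrame:
        lo = self.estimates - n_sigma * self.stderrs
        hi = self.estimates + n_sigma * self.stderrs
        return pd.DataFrame({"lower": lo, "upper": hi})

    def largest_residual(self) -> tuple[str, float]:
        idx = self.residuals.abs().idxmax()
        return str(idx), float(self.residuals.loc[idx])

    def summary(self) -> str:
        units = {"pz": "kcal/mol", "gz": "kcal/mol",
                 "dh-pz": "kcal/mol", "ds-pz": "cal/(mol.K)"}[self.model.stage.stage]
        lines = [
            f"Stack nearest-neighbor fit (stage {self.model.stage.stage}, "
            f"n = {self.nobs}, rank = {self.design_matrix_rank})",
            f"{'term':>14s} {'estimate':>10s} {'stderr':>8s}   [{units}]",
        ]
        for name in self.estimates.index:
            lines.append(f"{name:>14s} {self.estimates[name]:>10.3f} "
                         f"{self.stderrs[name]:>8.3f}")
        sid, r = self.largest_residual()
        lines.append(f"largest |residual|: {sid} ({r:+.2f})")
        if self.excluded:
            lines.append(f"excluded: {', '.join(self.excluded)}")
        return "\n".join(lines)


def end_penalty_report(data: list[MeltSummary], params: ParameterSet,
                       stage: FitStage | None = None) -> dict:
    """Fit with and without the terminal P-Z end-correction column.

    Reports both fits' penalty estimate (where present), standard errors,
    and the duplex with the largest absolute residual in each fit.
    """
    base = stage or FitStage("pz")
    if not any(_terminal_pz_count(s.duplex, params) for s in data):
        raise ValueError("no duplexes with terminal P-Z pairs in the data")
    with_pen = StackRegression(
        data, FitStage(base.stage, include_end_penalty=True), params).fit()
    without = StackRegression(
        data, FitStage(base.stage, include_end_penalty=False), params).fit()
    return {
        "with_penalty": with_pen,
        "without_penalty": without,
        "penalty_estimate": float(with_pen.estimates[END_PENALTY_TERM]),
        "penalty_stderr": float(with_pen.stderrs[END_PENALTY_TERM]),
        "largest_residual_with": with_pen.largest_residual(),
        "largest_residual_without": without.largest_residual(),
    }
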