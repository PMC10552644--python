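"""Molecular-efficacy scoring and clinical calibration.

The condition-level score of a model is the sign-weighted mean predicted
activity over the condition's effector set,

    tSignal = (1/n) * sum_i v_i * y_i,

where v_i is the pathological sign of effector i, y_i its predicted activity
and n counts only the effectors with non-zero signal.  tSignal ranges over
[-1, 1]: +1 means the model fully reproduces the disease state, -1 its
complete reversal.

Calibration against a clinical endpoint (PASI75) is an ordinary linear
regression, efficacy = A * tSignal + B, with Pearson correlation as the fit
metric; effectors that distort the relation can be pruned by a greedy
best-first loop that maximizes |rho|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .activity import ActivityMatrix, ProteinDefinition

__all__ = [
    "TSignalResult",
    "CalibrationResult",
    "tsignal",
    "tsignal_per_model",
    "calibrate",
    "optimize_definition",
    "severity_correlations",
    "correlation_band",
]


class UndefinedSignalError(ValueError):
    """All effectors carry zero signal: tSignal is undefined."""


@dataclass(frozen=True)
class TSignalResult:
    value: float
    n_used: int
    condition: str = ""

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.value <= 1.0 + 1e-9:
            raise ValueError("tSignal must lie in [-1, 1]")
        if self.n_used < 1:
            raise ValueError("n_used must be >= 1")


@dataclass(frozen=True)
class CalibrationResult:
    slope: float  # A in efficacy = A * tSignal + B
    intercept: float  # B
    rho: float  # Pearson correlation
    retained: tuple = ()
    discarded: tuple = ()  # in removal order
    status: str = "ok"


def tsignal(y, definition: ProteinDefinition,
            fixed_denominator: bool = False) -> TSignalResult:
    """Sign-weighted mean activity over the effector set.

    ``y`` is a mapping / Series of protein id -> activity covering every
    definition protein.  By default ``n`` counts only effectors with non-zero
    signal (a silent effector neither supports nor contradicts the disease
    state); ``fixed_denominator=True`` divides by the full set size instead.
    """
    y = pd.Series(y)
    missing = [p for p in definition.ids if p not in y.index]
    if missing:
        raise KeyError(f"activities missing for definition proteins: {missing}")
    vals = y.loc[definition.ids].to_numpy(dtype=float)
    signs = definition.signs
    nonzero = vals != 0
    n = len(vals) if fixed_denominator else int(nonzero.sum())
    if n == 0 or not nonzero.any():
        raise UndefinedSignalError(
            f"all {len(vals)} effectors have zero signal for {definition.label!r}"
        )
    value = float(np.sum(signs[nonzero] * vals[nonzero]) / n)
    return TSignalResult(value=value, n_used=n, condition=definition.label)


def _signed_means(values: pd.DataFrame, definition: ProteinDefinition) -> np.ndarray:
    """Vectorized per-row tSignal over a frame that contains the definition
    columns; rows where every effector is zero raise."""
    missing = [p for p in definition.ids if p not in values.columns]
    if missing:
        raise KeyError(f"activities missing for definition proteins: {missing}")
    signed = values[definition.ids].to_numpy(dtype=float) * definition.signs
    nonzero = signed != 0
    n = nonzero.sum(axis=1)
    if np.any(n == 0):
        bad = list(values.index[n == 0])
        raise UndefinedSignalError(f"all effectors zero for models {bad}")
    return signed.sum(axis=1) / n


def tsignal_per_model(matrix: ActivityMatrix,
                      definition: ProteinDefinition) -> pd.Series:
    """tSignal for every patient-arm model row of an activity matrix."""
    return pd.Series(_signed_means(matrix.values, definition),
                     index=matrix.values.index, name="tsignal")


def calibrate(tsignals, efficacy) -> CalibrationResult:
    """OLS fit of efficacy = A * tSignal + B with Pearson rho (no pruning)."""
    x = np.asarray(tsignals, dtype=float)
    y = np.asarray(efficacy, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 drugs to calibrate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    fit = stats.linregress(x, y)
    return CalibrationResult(slope=float(fit.slope), intercept=float(fit.intercept),
                             rho=float(fit.rvalue))


def _panel_rho(panel: pd.DataFrame, efficacy: np.ndarray,
               definition: ProteinDefinition) -> float:
    ts = _signed_means(panel, definition)
    if np.ptp(ts) == 0:
        return 0.0
    return float(stats.pearsonr(ts, efficacy)[0])


def optimize_definition(
    panel: pd.DataFrame,
    efficacy,
    definition: ProteinDefinition,
    min_size: int = 2,
    min_improvement: float = 5e-5,
) -> CalibrationResult:
    """Greedy best-first pruning of the effector set.

    At each step the single protein whose removal most increases |rho|
    between per-drug tSignal and efficacy is discarded (ties broken by
    protein id); the loop stops when no removal improves |rho| by at least
    ``min_improvement``, or the set would shrink below ``min_size``.  The
    improvement floor keeps bibliography-curated effectors from being
    discarded for sampling-noise-sized correlation gains.
    """
    eff = np.asarray(efficacy, dtype=float)
    current = definition
    discarded: list = []
    status = "ok"
    best_rho = abs(_panel_rho(panel, eff, current))
    while True:
        if len(current.entries) <= min_size:
            status = "degenerate"
            break
        candidates = []
        for pid in current.ids:
            trial = current.subset(set(current.ids) - {pid})
            try:
                r = abs(_panel_rho(panel, eff, trial))
            except UndefinedSignalError:
                continue
            candidates.append((r, pid, trial))
        if not candidates:
            break
        # max |rho|, ties by lexicographic protein id
        candidates.sort(key=lambda t: (-t[0], t[1]))
        r_best, pid_best, trial_best = candidates[0]
        if r_best < best_rho + min_improvement:
            break
        best_rho, current = r_best, trial_best
        discarded.append(pid_best)

    ts = _signed_means(panel, current)
    fit = stats.linregress(ts, eff)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rho=float(fit.rvalue),
        retained=tuple(current.ids),
        discarded=tuple(discarded),
        status=status,
    )


def correlation_band(rho: float) -> str:
    """Correlation-strength band: strong |rho|>0.8; moderate (0.5, 0.8];
    low (0.3, 0.5]; negligible <= 0.3."""
    a = abs(rho)
    if a > 0.8:
        return "strong"
    if a > 0.5:
        return "moderate"
    if a > 0.3:
        return "low"
    return "negligible"


def severity_correlations(
    matrix: ActivityMatrix,
    definition: ProteinDefinition,
    markers,
) -> pd.DataFrame:
    """Correlate candidate severity-marker activities with the per-model
    tSignal, separately per trial arm.

    Returns one row per marker with Pearson rho and Benjamini-Hochberg q per
    arm plus a strength band assigned from the weaker of the per-arm
    correlations (the band that holds for both dosing schemes).
    """
    markers = list(markers)
    missing = [m for m in markers if m not in matrix.values.columns]
    if missing:
        raise KeyError(f"markers not in activity matrix: {missing}")
    ts = tsignal_per_model(matrix, definition)
    arms = sorted(matrix.arms.unique())
    out = pd.DataFrame({"protein": markers}).set_index("protein")
    for arm in arms:
        rows = matrix.arms[matrix.arms == arm].index
        if len(rows) < 3:
            raise ValueError(f"arm {arm!r} has fewer than 3 models")
        sub = matrix.values.loc[rows, markers]
        tsub = ts.loc[rows]
        rhos, ps = [], []
        for m in markers:
            x = sub[m].to_numpy()
            if np.ptp(x) == 0 or np.ptp(tsub.to_numpy()) == 0:
                rhos.append(np.nan)
                ps.append(1.0)
            else:
                r, p = stats.pearsonr(x, tsub)
                rhos.append(float(r))
                ps.append(float(p))
        q = multipletests(ps, method="fdr_bh")[1]
        out[f"rho_{arm}"] = rhos
        out[f"q_{arm}"] = q
    min_abs = out[[f"rho_{a}" for a in arms]].abs().min(axis=1)
    out["band"] = [correlation_band(r) if np.isfinite(r) else "negligible"
                   for r in min_abs]
    return out.reset_index()
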