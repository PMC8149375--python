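"""Four-parameter logistic dose-response fitting and per-drug screen metrics.

The anchored combination screen measures each drug at a fixed dose ladder,
alone and on top of a constant anchor dose.  This module turns each
(viability vs dose) series into the derived quantities the screen selects on:

* GI50 -- the dose at which the fitted curve crosses 50% viability relative to
  vehicle, censored at the highest tested dose when the curve never gets there;
* AUC -- trapezoidal area under the viability curve over a unit-spaced dose
  index (so an 8-point series has a maximum area of 7);
* fold change of GI50 between the single agent and the combination,
  AUC difference and AUC percent change, the minimum viability (Ymin of the
  fitted curve), and within-cell-line z-scores of those quantities.

The 4PL model is v(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill),
decreasing in dose for hill > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import SchemaError

__all__ = [
    "DoseSeries",
    "FitResult4PL",
    "ScreenMetrics",
    "four_pl",
    "fit_4pl",
    "compute_gi50",
    "compute_auc",
    "screen_metrics",
    "zscores",
    "metrics_table",
    "add_zscores",
]


@dataclass(frozen=True)
class DoseSeries:
    """One drug's viability-vs-dose vector in one cell line under one condition.

    ``condition`` is ``"alone"`` for the single agent or ``"plus_anchor"``
    for drug plus the fixed anchor dose.  Viability is the fraction relative
    to the vehicle control; replicates are expected to be averaged upstream.
    """

    drug_id: str
    cell_line: str
    condition: str
    doses: np.ndarray
    viability: np.ndarray

    def __post_init__(self) -> None:
        doses = np.asarray(self.doses, dtype=float)
        viability = np.asarray(self.viability, dtype=float)
        object.__setattr__(self, "doses", doses)
        object.__setattr__(self, "viability", viability)
        if self.condition not in ("alone", "plus_anchor"):
            raise SchemaError(
                f"condition must be 'alone' or 'plus_anchor', got {self.condition!r}"
            )
        if doses.ndim != 1 or viability.ndim != 1:
            raise SchemaError("doses and viability must be 1-D")
        if len(doses) != len(viability):
            raise SchemaError("doses and viability must have equal length")
        if len(doses) < 4:
            raise SchemaError("a dose series needs at least 4 doses")
        if not np.all(doses > 0):
            raise SchemaError("doses must be strictly positive")
        if not np.all(np.diff(doses) > 0):
            raise SchemaError("doses must be strictly increasing")
        if not np.all(np.isfinite(viability)):
            raise SchemaError("viability values must be finite")

    @property
    def inhibition(self) -> np.ndarray:
        """Inhibition fraction 1 - viability, clipped to [0, 1]."""
        return 1.0 - np.clip(self.viability, 0.0, 1.0)


@dataclass(frozen=True)
class FitResult4PL:
    top: float
    bottom: float
    ec50: float
    hill: float
    converged: bool
    rss: float


@dataclass
class ScreenMetrics:
    """Per (drug, cell line) derived metrics of the anchored screen."""

    drug_id: str
    cell_line: str
    gi50_single: float
    gi50_combo: float
    gi50_single_censored: bool
    gi50_combo_censored: bool
    fold_change_gi50: float
    auc_single: float
    auc_combo: float
    auc_diff: float
    auc_pct_change: float
    min_viability: float
    z_auc_combo: float = field(default=np.nan)
    z_gi50_combo: float = field(default=np.nan)
    z_gi50_fold: float = field(default=np.nan)


def four_pl(d: np.ndarray, top: float, bottom: float, ec50: float, hill: float) -> np.ndarray:
    """Evaluate the four-parameter logistic at doses ``d``."""
    d = np.asarray(d, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ec50) ** hill)


def _fallback_fit(series: DoseSeries) -> FitResult4PL:
    """Non-parametric stand-in used when the optimizer fails.

    Top/bottom from the observed extremes, ec50 from the interpolated
    midpoint crossing (max dose when the series never crosses), hill 1.
    """
    v = series.viability
    top, bottom = float(np.max(v)), float(np.min(v))
    mid = 0.5 * (top + bottom)
    ec50 = float(series.doses[-1])
    below = np.nonzero(v <= mid)[0]
    if below.size and below[0] > 0:
        i = below[0]
        d0, d1 = series.doses[i - 1], series.doses[i]
        v0, v1 = v[i - 1], v[i]
        if v0 != v1:
            frac = (v0 - mid) / (v0 - v1)
            ec50 = float(np.exp(np.log(d0) + frac * (np.log(d1) - np.log(d0))))
    elif below.size:
        ec50 = float(series.doses[0])
    pred = four_pl(series.doses, top, bottom, ec50, 1.0)
    return FitResult4PL(top, bottom, ec50, 1.0, False, float(np.sum((v - pred) ** 2)))


def fit_4pl(series: DoseSeries) -> FitResult4PL:
    """Least-squares 4PL fit of one dose series.

    Never raises on optimizer failure: the result carries ``converged=False``
    and fallback parameters estimated non-parametrically, so downstream
    metrics stay computable for every drug in a large screen.
    """
    if len(np.unique(series.doses)) < 4:
        raise SchemaError("fit_4pl requires at least 4 distinct doses")
    d, v = series.doses, series.viability
    guess = _fallback_fit(series)
    p0 = [max(guess.top, guess.bottom + 1e-3), guess.bottom, guess.ec50, 1.0]
    lo = [-0.5, -0.5, d[0] / 1e4, 0.05]
    hi = [1.5, 1.5, d[-1] * 1e4, 20.0]
    p0 = [min(max(p, l), h) for p, l, h in zip(p0, lo, hi)]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                four_pl, d, v, p0=p0, bounds=(lo, hi), maxfev=5000
            )
        top, bottom, ec50, hill = (float(x) for x in popt)
        if bottom > top:  # decreasing-curve convention
            top, bottom = bottom, top
        pred = four_pl(d, top, bottom, ec50, hill)
        rss = float(np.sum((v - pred) ** 2))
        if not np.isfinite(rss):
            return guess
        return FitResult4PL(top, bottom, ec50, hill, True, rss)
    except (RuntimeError, ValueError):
        return guess


def compute_gi50(fit: FitResult4PL, dose_range: tuple[float, float],
                 level: float = 0.5) -> tuple[float, bool]:
    """Dose at which the fitted curve crosses ``level`` viability.

    Returns ``(dose, censored)``.  When the curve never reaches the level --
    flat curve, bottom above the level, or the analytic crossing beyond the
    highest tested dose -- the GI50 is censored at the max tested dose with
    ``censored=True``, which keeps fold changes computable while flagging them.
    A crossing below the lowest tested dose is returned at face value: the
    drug is simply more potent than the ladder resolves.
    """
    dmin, dmax = float(dose_range[0]), float(dose_range[1])
    top, bottom = fit.top, fit.bottom
    if not (top > level > bottom) or fit.hill <= 0 or fit.ec50 <= 0:
        return dmax, True
    x = (top - level) / (level - bottom)
    d = fit.ec50 * x ** (1.0 / fit.hill)
    if not np.isfinite(d) or d > dmax:
        return dmax, True
    return float(d), False


def compute_auc(series: DoseSeries) -> float:
    """Trapezoidal area of viability over the unit-spaced dose index.

    Viability is clipped to [0, 1] first, so the maximum area for an
    n-point series is n - 1.
    """
    v = np.clip(series.viability, 0.0, 1.0)
    return float(np.trapezoid(v, dx=1.0))


def screen_metrics(single: DoseSeries, combo: DoseSeries) -> ScreenMetrics:
    """All per-drug screen metrics from one single-agent / combination pair.

    Fold change is GI50(single) / GI50(combination) -- a value above 1 means
    the anchor left-shifts the curve.  AUC percent change is
    100 * (AUC_single - AUC_combo) / AUC_single.
    """
    if single.drug_id != combo.drug_id or single.cell_line != combo.cell_line:
        raise SchemaError("single and combo series must be the same drug and cell line")
    if len(single.doses) != len(combo.doses) or not np.allclose(single.doses, combo.doses):
        raise SchemaError("single and combo series must share the dose grid")
    dose_range = (float(single.doses[0]), float(single.doses[-1]))

    fit_s = fit_4pl(single)
    fit_c = fit_4pl(combo)
    gi50_s, cen_s = compute_gi50(fit_s, dose_range)
    gi50_c, cen_c = compute_gi50(fit_c, dose_range)
    auc_s = compute_auc(single)
    auc_c = compute_auc(combo)
    auc_diff = auc_s - auc_c
    pct = 100.0 * auc_diff / auc_s if auc_s > 0 else 0.0
    if fit_c.converged:
        ymin = float(np.clip(fit_c.bottom, 0.0, 1.0))
    else:
        ymin = float(np.clip(np.min(combo.viability), 0.0, 1.0))
    return ScreenMetrics(
        drug_id=single.drug_id,
        cell_line=single.cell_line,
        gi50_single=gi50_s,
        gi50_combo=gi50_c,
        gi50_single_censored=cen_s,
        gi50_combo_censored=cen_c,
        fold_change_gi50=gi50_s / gi50_c,
        auc_single=auc_s,
        auc_combo=auc_c,
        auc_diff=auc_diff,
        auc_pct_change=pct,
        min_viability=ymin,
    )


def zscores(values: np.ndarray) -> np.ndarray:
    """Standard scores (x - mean) / sd with sample sd (ddof=1).

    A zero-variance vector yields all-zero scores with a warning rather than
    NaNs, so a degenerate cell line does not poison the vote.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise SchemaError("zscores requires at least 3 values")
    sd = float(np.std(values, ddof=1))
    if sd == 0.0 or not np.isfinite(sd):
        warnings.warn("zero variance in zscores; returning all-zero scores")
        return np.zeros_like(values)
    return (values - values.mean()) / sd


_METRIC_COLUMNS = [
    "drug_id", "cell_line", "gi50_single", "gi50_combo",
    "gi50_single_censored", "gi50_combo_censored", "fold_change_gi50",
    "auc_single", "auc_combo", "auc_diff", "auc_pct_change", "min_viability",
]


def metrics_table(pairs: list[tuple[DoseSeries, DoseSeries]]) -> pd.DataFrame:
    """Screen metrics for a collection of (single, combo) pairs, with
    within-cell-line z-score columns appended."""
    rows = [vars(screen_metrics(s, c)) for s, c in pairs]
    df = pd.DataFrame(rows)
    return add_zscores(df)


def add_zscores(df: pd.DataFrame) -> pd.DataFrame:
    """Append z_auc_combo, z_gi50_combo and z_gi50_fold computed across drugs
    within each cell line.  GI50 z-scores use log10 doses so the standardizing
    scale matches the log-spaced ladder."""
    df = df.copy()
    for col, src, log in [
        ("z_auc_combo", "auc_combo", False),
        ("z_gi50_combo", "gi50_combo", True),
        ("z_gi50_fold", "fold_change_gi50", True),
    ]:
        parts = []
        for _, sub in df.groupby("cell_line", sort=False):
            x = sub[src].to_numpy(dtype=float)
            if log:
                x = np.log10(np.maximum(x, 1e-300))
            parts.append(pd.Series(zscores(x), index=sub.index))
        df[col] = pd.concat(parts).reindex(df.index)
    return df
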