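"""Bliss independence and Chou-Talalay combination-index synergy scoring.

The secondary screen measures each nominated combination on a 6 x 8 dose
matrix (six anchor doses by eight drug doses) with single-agent margins.  Two
complementary null models quantify synergy:

* **Bliss independence** -- expected combined inhibition
  ``E = E_A + E_B - E_A * E_B``; the per-cell excess (observed - expected)
  is positive for greater-than-additive combinations.
* **Chou-Talalay median effect** -- each single agent is summarized by the
  median-effect line ``log(fa/fu) = m log(D) - m log(Dm)``; at each matrix
  cell with observed affected fraction fa, the combination index is
  ``CI = d1/Dx1 + d2/Dx2`` with ``Dx_i = Dm_i (fa/(1-fa))^(1/m_i)``
  (mutually exclusive form).  CI < 1 is synergistic, 1 additive, > 1
  antagonistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, SchemaError

__all__ = [
    "DoseMatrix", "MedianEffectFit", "CIResult",
    "bliss_expected", "bliss_excess", "fit_median_effect",
    "median_effect_fa", "combination_index", "rank_synergy",
    "secondary_signature_count",
]

FA_EPS = 1e-4


@dataclass(frozen=True)
class DoseMatrix:
    """Anchor x drug inhibition-fraction grid with single-agent margins.

    ``inhibition[i, j]`` is the combined inhibition at
    (anchor dose i, drug dose j); ``anchor_alone`` / ``drug_alone`` are the
    corresponding single-agent inhibitions (the dose-0 row/column of the
    plate layout).
    """

    combination_id: str
    cell_line: str
    anchor_doses: np.ndarray
    drug_doses: np.ndarray
    inhibition: np.ndarray
    anchor_alone: np.ndarray
    drug_alone: np.ndarray

    def __post_init__(self) -> None:
        for name in ("anchor_doses", "drug_doses", "inhibition",
                     "anchor_alone", "drug_alone"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        na, nd = len(self.anchor_doses), len(self.drug_doses)
        if self.inhibition.shape != (na, nd):
            raise SchemaError(
                f"inhibition grid shape {self.inhibition.shape} does not match "
                f"({na} anchor doses, {nd} drug doses)")
        if len(self.anchor_alone) != na or len(self.drug_alone) != nd:
            raise SchemaError("single-agent margins must match the dose axes")
        if np.any(np.diff(self.anchor_doses) <= 0) or np.any(np.diff(self.drug_doses) <= 0):
            raise SchemaError("dose axes must be strictly increasing")
        if np.any(self.inhibition < -1e-9) or np.any(self.inhibition > 1 + 1e-9):
            raise SchemaError("inhibition fractions must lie in [0, 1]")


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect line of one agent: fa/fu = (D/Dm)^m."""

    Dm: float
    m: float
    r2: float
    n_points_used: int


@dataclass
class CIResult:
    """Per-cell combination indices for one dose matrix.

    ``ci`` is NaN where the observed fa falls outside (eps, 1-eps) and the
    index is undefined; the summary counts only defined cells.
    """

    combination_id: str
    cell_line: str
    fa: np.ndarray
    dx1: np.ndarray
    dx2: np.ndarray
    ci: np.ndarray
    n_defined: int = field(init=False)
    n_synergistic: int = field(init=False)

    def __post_init__(self) -> None:
        defined = np.isfinite(self.ci)
        self.n_defined = int(defined.sum())
        self.n_synergistic = int(np.sum(self.ci[defined] < 1.0))

    @property
    def frac_synergistic(self) -> float:
        return self.n_synergistic / self.n_defined if self.n_defined else np.nan

    @property
    def mean_ci(self) -> float:
        defined = np.isfinite(self.ci)
        return float(np.mean(self.ci[defined])) if defined.any() else np.nan


def bliss_expected(ea, eb):
    """Expected combined inhibition under Bliss independence."""
    ea = np.asarray(ea, dtype=float)
    eb = np.asarray(eb, dtype=float)
    if np.any((ea < 0) | (ea > 1)) or np.any((eb < 0) | (eb > 1)):
        raise SchemaError("Bliss inputs must be inhibition fractions in [0, 1]")
    out = ea + eb - ea * eb
    return float(out) if out.ndim == 0 else out


def bliss_excess(matrix: DoseMatrix) -> tuple[np.ndarray, float]:
    """Observed minus Bliss-expected inhibition per cell, and its mean.

    A positive mean excess calls the combination greater-than-additive.
    """
    expected = bliss_expected(
        matrix.anchor_alone[:, None], matrix.drug_alone[None, :]
    )
    excess = matrix.inhibition - expected
    return excess, float(excess.mean())


def median_effect_fa(doses, Dm: float, m: float) -> np.ndarray:
    """Affected fraction of the median-effect model at the given doses."""
    d = np.asarray(doses, dtype=float)
    return 1.0 / (1.0 + (Dm / d) ** m)


def fit_median_effect(doses, fa, eps: float = FA_EPS) -> MedianEffectFit:
    """Least-squares median-effect line through (log D, logit fa).

    Points with fa outside (eps, 1-eps) are excluded (the logit diverges);
    at least two usable points are required.
    """
    d = np.asarray(doses, dtype=float)
    fa = np.asarray(fa, dtype=float)
    if d.shape != fa.shape:
        raise SchemaError("doses and fa must have equal length")
    usable = (fa > eps) & (fa < 1 - eps) & (d > 0)
    if usable.sum() < 2:
        raise FitError(
            f"median-effect fit needs >= 2 points with fa in ({eps}, {1 - eps}); "
            f"got {int(usable.sum())} after exclusion")
    x = np.log(d[usable])
    y = np.log(fa[usable] / (1.0 - fa[usable]))
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise FitError("median-effect slope m must be positive; data are not dose-responsive")
    pred = m * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return MedianEffectFit(Dm=float(np.exp(-intercept / m)), m=float(m),
                           r2=r2, n_points_used=int(usable.sum()))


def combination_index(
    matrix: DoseMatrix,
    fit_anchor: MedianEffectFit,
    fit_drug: MedianEffectFit,
    eps: float = FA_EPS,
) -> CIResult:
    """Combination index at every defined matrix cell.

    Uses the mutually exclusive Chou-Talalay form (no cross-term), evaluated
    at each cell's observed fa rather than along a fixed-ratio ray, to match
    the anchor-by-drug matrix layout.
    """
    for fit in (fit_anchor, fit_drug):
        if fit.Dm <= 0 or fit.m <= 0:
            raise FitError("combination_index requires valid median-effect fits (Dm, m > 0)")
    fa = np.asarray(matrix.inhibition, dtype=float)
    d1 = matrix.anchor_doses[:, None]
    d2 = matrix.drug_doses[None, :]
    defined = (fa > eps) & (fa < 1 - eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = fa / (1.0 - fa)
        dx1 = fit_anchor.Dm * ratio ** (1.0 / fit_anchor.m)
        dx2 = fit_drug.Dm * ratio ** (1.0 / fit_drug.m)
        ci = d1 / dx1 + d2 / dx2
    ci = np.where(defined, ci, np.nan)
    dx1 = np.where(defined, dx1, np.nan)
    dx2 = np.where(defined, dx2, np.nan)
    return CIResult(matrix.combination_id, matrix.cell_line, fa, dx1, dx2, ci)


def rank_synergy(results: dict[str, list[CIResult]]) -> list[tuple[str, int, float]]:
    """Rank combinations by synergy across cell lines.

    Descending by the total count of CI < 1 cells, ties broken by mean CI
    ascending, then by identifier.  Returns (id, n_synergistic, mean_ci).
    """
    if not results:
        raise SchemaError("rank_synergy requires at least one CI result")
    rows = []
    for comb_id, ci_list in results.items():
        n_syn = sum(r.n_synergistic for r in ci_list)
        cis = np.concatenate([r.ci[np.isfinite(r.ci)] for r in ci_list]) \
            if ci_list else np.array([])
        mean_ci = float(cis.mean()) if cis.size else np.inf
        rows.append((str(comb_id), n_syn, mean_ci))
    rows.sort(key=lambda r: (-r[1], r[2], r[0]))
    return rows


def secondary_signature_count(
    n_drugs: int = 28,
    n_anchor_doses: int = 6,
    n_drug_doses: int = 8,
    n_cell_lines: int = 5,
) -> int:
    """Number of dose-response signatures in the secondary screen design:
    one per matrix cell per drug per cell line."""
    return n_drugs * n_anchor_doses * n_drug_doses * n_cell_lines
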