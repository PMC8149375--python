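"""Nested-model tests for drug-interaction effects in omics data.

Two drugs given alone and together define a 2 x 2 design (vehicle, drug d,
drug c, d+c).  A feature responds *interactively* when its combination
response is not the sum (on the log scale) of the single-drug responses:

* RNA-seq counts: per-gene negative-binomial GLM with a log2 link,
  mean = size_factor * 2^(b0 + x_d*b_d + x_c*b_c + x_dc*b_dc);
  the full model (with the interaction term) is compared to the reduced
  model (without it) by a likelihood-ratio test against chi-square(1).
* Log-intensity data (phosphoproteomics): ordinary least squares on log10
  intensities with the same design, compared by a nested F-test.

Benjamini-Hochberg correction is applied across tested features; genes are
then ranked by the signed interaction coefficient for enrichment analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import SchemaError

__all__ = [
    "size_factors", "estimate_dispersion", "fit_interaction_glm",
    "lrt_interaction", "intensity_interaction", "rank_by_interaction",
    "preprocess_intensities", "bh_adjust",
]

LN2 = np.log(2.0)
_DESIGN_COLS = ["x_d", "x_c", "x_dc"]


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    The pseudo-reference is the per-gene geometric mean over samples,
    computed on genes nonzero in every sample.  If no such gene exists the
    estimate falls back to library-size ratios with a warning.
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = np.all(mat > 0, axis=1)
    if all_nonzero.any():
        sub = mat[all_nonzero]
        log_ref = np.mean(np.log(sub), axis=1)
        ratios = np.log(sub) - log_ref[:, None]
        log_sf = np.median(ratios, axis=0)
    else:
        warnings.warn(
            "no gene is nonzero in all samples; falling back to library-size ratios")
        lib = mat.sum(axis=0)
        if np.any(lib <= 0):
            raise SchemaError("every sample needs at least one nonzero count")
        log_sf = np.log(lib)
    log_sf = log_sf - log_sf.mean()  # geometric mean 1
    return pd.Series(np.exp(log_sf), index=counts.columns, name="size_factor")


def _design_matrix(design: pd.DataFrame, full: bool) -> np.ndarray:
    cols = _DESIGN_COLS if full else _DESIGN_COLS[:2]
    X = design[cols].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def estimate_dispersion(
    counts: pd.DataFrame, design: pd.DataFrame, sf: pd.Series,
    floor: float = 1e-8,
) -> np.ndarray:
    """Per-gene method-of-moments NB dispersion.

    Counts are normalized by size factors, cell means estimated per design
    arm, and alpha solved from var = mu + alpha * mu^2 on the pooled
    residuals, floored at ``floor``.  Deliberately unshrunken.
    """
    z = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    arms = [tuple(r) for r in design[_DESIGN_COLS].to_numpy()]
    inv_sf_mean = float(np.mean(1.0 / sf.to_numpy()))
    num = np.zeros(len(counts))
    den = np.zeros(len(counts))
    df = 0
    for arm in sorted(set(arms)):
        cols = np.array([k == arm for k in arms])
        m = cols.sum()
        if m < 2:
            continue
        zc = z[:, cols]
        mu = zc.mean(axis=1)
        resid2 = ((zc - mu[:, None]) ** 2).sum(axis=1)
        # Poisson part of the variance on the normalized scale is ~ mu / s
        num += resid2 - (m - 1) * mu * inv_sf_mean
        den += (m - 1) * mu ** 2
        df += m - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = num / den
    alpha[~np.isfinite(alpha)] = floor
    return np.maximum(alpha, floor)


def _fit_nb(y: np.ndarray, X: np.ndarray, alpha: float, offset: np.ndarray):
    """NB GLM with fixed dispersion; returns (params, llf, converged)."""
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100, tol=1e-9)
            return res.params, float(res.llf), True
        except Exception:
            return np.full(X.shape[1], np.nan), np.nan, False


def fit_interaction_glm(
    y: np.ndarray,
    design: pd.DataFrame,
    dispersion: float,
    sf: pd.Series | np.ndarray | None = None,
) -> dict:
    """Full and reduced NB fits for one feature.

    Coefficients are reported on the log2 scale (the natural-log GLM
    coefficients divided by ln 2); the size-factor offset enters on the
    natural-log scale.  An all-zero feature yields NaN results flagged
    ``converged=False``.
    """
    y = np.asarray(y, dtype=float)
    if sf is None:
        sf = np.ones(len(y))
    sf = np.asarray(sf, dtype=float)
    if np.all(y == 0):
        return {"beta_d": np.nan, "beta_c": np.nan, "beta_dc": np.nan,
                "ll_full": np.nan, "ll_reduced": np.nan, "converged": False}
    offset = np.log(sf)
    Xf = _design_matrix(design, full=True)
    Xr = _design_matrix(design, full=False)
    params_r, llr, ok_r = _fit_nb(y, Xr, dispersion, offset)
    if np.all(design["x_dc"].to_numpy() == 0):
        # degenerate design: the models coincide, the interaction is zero
        params_f = np.append(params_r, 0.0)
        llf, ok_f = llr, ok_r
    else:
        if np.linalg.matrix_rank(Xf) < Xf.shape[1]:
            raise SchemaError("design matrix is rank deficient")
        params_f, llf, ok_f = _fit_nb(y, Xf, dispersion, offset)
    return {
        "beta_d": params_f[1] / LN2, "beta_c": params_f[2] / LN2,
        "beta_dc": params_f[3] / LN2,
        "ll_full": llf, "ll_reduced": llr, "converged": ok_f and ok_r,
    }


def _check_design(design: pd.DataFrame) -> None:
    missing = [c for c in _DESIGN_COLS if c not in design.columns]
    if missing:
        raise SchemaError(f"design table missing columns: {missing}")
    arms = design[["x_d", "x_c"]].apply(tuple, axis=1)
    for cell in [(0, 0), (1, 0), (0, 1), (1, 1)]:
        if not (arms == cell).any():
            raise SchemaError(f"design cell (x_d, x_c) = {cell} is unpopulated")


def lrt_interaction(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    alpha_q: float = 0.01,
    dispersion: float | np.ndarray | None = None,
) -> pd.DataFrame:
    """Likelihood-ratio test of the interaction term for every gene.

    ``dispersion`` may be a known scalar/array (e.g. from simulation truth);
    when omitted it is estimated per gene by method of moments.  Returns one
    row per gene with log2-scale coefficients, the LRT statistic, chi2(1)
    p-value, BH q-value and the ``better_explained_by_full`` flag (q <
    ``alpha_q``).  All-zero genes are reported NaN and excluded from testing.
    """
    _check_design(design)
    if list(counts.columns) != list(design.index):
        raise SchemaError("counts columns must match design index (same order)")
    sf = size_factors(counts)
    if dispersion is None:
        disp = estimate_dispersion(counts, design, sf)
    else:
        disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (len(counts),))

    rows = []
    sf_arr = sf.to_numpy()
    mat = counts.to_numpy(dtype=float)
    for i, gene in enumerate(counts.index):
        fit = fit_interaction_glm(mat[i], design, float(disp[i]), sf_arr)
        if not np.isfinite(fit["ll_full"]) or not np.isfinite(fit["ll_reduced"]):
            lrt = p = np.nan
        else:
            lrt = max(2.0 * (fit["ll_full"] - fit["ll_reduced"]), 0.0)
            p = float(stats.chi2.sf(lrt, df=1))
        rows.append({"feature": gene, "beta_d": fit["beta_d"],
                     "beta_c": fit["beta_c"], "beta_dc": fit["beta_dc"],
                     "lrt_statistic": lrt, "p_value": p})
    out = pd.DataFrame(rows).set_index("feature")
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["better_explained_by_full"] = out["q_value"] < alpha_q
    return out


def intensity_interaction(
    intensities: pd.DataFrame,
    design: pd.DataFrame,
    alpha_q: float = 0.05,
) -> pd.DataFrame:
    """Nested OLS F-test of the interaction term on log-intensity data.

    ``intensities`` is features x samples, already log-transformed and
    imputed.  The F statistic compares the full linear model (intercept,
    x_d, x_c, x_dc) to the reduced one without the interaction; p-values are
    F(1, n - 4) tails, BH-corrected.  Vectorized across features through the
    shared hat matrices.
    """
    _check_design(design)
    if list(intensities.columns) != list(design.index):
        raise SchemaError("intensity columns must match design index (same order)")
    Y = intensities.to_numpy(dtype=float).T  # samples x features
    if not np.all(np.isfinite(Y)):
        raise SchemaError("intensities must be finite; impute missing values first")
    n = Y.shape[0]
    Xf = _design_matrix(design, full=True)
    Xr = _design_matrix(design, full=False)
    df_resid = n - Xf.shape[1]
    if df_resid < 1:
        raise SchemaError("zero residual degrees of freedom in the full model")

    beta_f, *_ = np.linalg.lstsq(Xf, Y, rcond=None)
    beta_r, *_ = np.linalg.lstsq(Xr, Y, rcond=None)
    rss_f = np.sum((Y - Xf @ beta_f) ** 2, axis=0)
    rss_r = np.sum((Y - Xr @ beta_r) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (rss_r - rss_f) / (rss_f / df_resid)
    f_stat = np.maximum(f_stat, 0.0)
    zero_resid = rss_f <= 1e-300
    p = np.where(zero_resid & (rss_r - rss_f <= 1e-300), 1.0,
                 stats.f.sf(f_stat, 1, df_resid))
    out = pd.DataFrame({
        "beta_d": beta_f[1], "beta_c": beta_f[2], "beta_dc": beta_f[3],
        "f_statistic": f_stat, "p_value": p,
    }, index=intensities.index)
    out.index.name = "feature"
    out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["better_explained_by_full"] = out["q_value"] < alpha_q
    return out


def rank_by_interaction(results: pd.DataFrame) -> pd.Series:
    """Features ordered by signed interaction coefficient, descending.

    NaN coefficients are dropped; ties break deterministically by feature id.
    The returned Series (id -> beta_dc) is the preranked input for
    enrichment.
    """
    sub = results.dropna(subset=["beta_dc"]).copy()
    sub = sub.sort_index().sort_values("beta_dc", ascending=False, kind="mergesort")
    return sub["beta_dc"]


def preprocess_intensities(
    raw: pd.DataFrame, log_transform: bool = True
) -> pd.DataFrame:
    """log10-transform, median-impute within feature, quantile-normalize.

    Standard mass-spec preprocessing: missing values are replaced by the
    feature's median across samples (features missing everywhere are
    dropped), then rank-mean quantile normalization aligns the per-sample
    distributions.
    """
    df = raw.copy().astype(float)
    if log_transform:
        df = np.log10(df.where(df > 0))
    med = df.median(axis=1)
    df = df.apply(lambda col: col.fillna(med), axis=0)
    df = df.dropna(axis=0, how="any")
    ranks = df.rank(axis=0, method="average")
    # rank-mean: average the sorted values across samples, then map back
    sorted_vals = np.sort(df.to_numpy(), axis=0)
    rank_means = sorted_vals.mean(axis=1)
    out = np.empty_like(df.to_numpy())
    interp_x = np.arange(1, len(df) + 1)
    for j in range(df.shape[1]):
        out[:, j] = np.interp(ranks.iloc[:, j].to_numpy(), interp_x, rank_means)
    return pd.DataFrame(out, index=df.index, columns=df.columns)
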