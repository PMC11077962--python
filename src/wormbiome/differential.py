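"""Negative-binomial Wald tests for differential abundance.

A deliberately compact NB-GLM stage for count features (taxa or
trait-derived functions): median-of-ratios size factors enter as offsets,
a log-link negative binomial GLM with source and time as categorical
factors is fitted per feature, the per-feature dispersion is estimated by
Cox-Reid-adjusted maximum likelihood (method-of-moments initialization,
floor 1e-8), and a Wald statistic tests the requested source contrast,
with Benjamini-Hochberg adjustment across features.  There is no
dispersion shrinkage toward a trend, no fold-change shrinkage and no
independent filtering; the stage is meant to be calibrated and
transparent, not numerically identical to any particular release of the
heavyweight tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .core_io import SOURCES, SampleMetadata, ValidationError

logger = logging.getLogger("wormbiome")

_ALPHA_FLOOR = 1e-8
_ALPHA_CEIL = 1e2


@dataclass
class DifferentialResult:
    """Per-contrast differential abundance table plus bookkeeping."""

    table: pd.DataFrame  # feature, baseMean, log2FC, se, stat, p, padj
    contrast: tuple[str, str]
    skipped: tuple[str, ...]  # all-zero or non-converged features


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios normalization (features x samples).

    s_j = median over features (with positive geometric mean) of
    K_ij / geomean_i.  No further rescaling is applied.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValidationError("counts must be a features x samples matrix")
    with np.errstate(divide="ignore"):
        logs = np.log(counts)
    ok = np.all(np.isfinite(logs), axis=1)  # features positive in every sample
    if not ok.any():
        raise ValidationError(
            "no feature is nonzero in every sample; median-of-ratios undefined "
            "(consider a pseudo-reference)"
        )
    log_geomean = logs[ok].mean(axis=1)
    ratios = logs[ok] - log_geomean[:, None]
    return np.exp(np.median(ratios, axis=0))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up with monotonicity; NaNs pass through."""
    p = np.asarray(p_values, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    pv = p[ok]
    m = pv.size
    if m:
        order = np.argsort(pv)
        ranked = pv[order] * m / np.arange(1, m + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        res = np.empty(m)
        res[order] = np.minimum(adj, 1.0)
        out[ok] = res
    return out


def build_design(metadata: SampleMetadata, design: str = "source+time") -> pd.DataFrame:
    """Treatment-coded design matrix with 'control' as the source reference.

    ``design`` is a '+'-joined subset of {source, time}; both enter as
    categorical factors (time has one level per sampling point).
    """
    terms = [t.strip() for t in design.split("+") if t.strip()]
    bad = set(terms) - {"source", "time"}
    if bad:
        raise ValidationError(f"unknown design term(s) {sorted(bad)}")
    if "source" not in terms:
        raise ValidationError("design must include 'source'")
    cols = {"intercept": np.ones(len(metadata))}
    src = metadata.source.to_numpy()
    src_levels = [s for s in SOURCES if s in set(src)]
    if len(src_levels) < 2:
        raise ValidationError("need >= 2 source levels")
    for lev in src_levels[1:]:  # first present level (control if there) = reference
        cols[f"source[{lev}]"] = (src == lev).astype(float)
    if "time" in terms:
        times = metadata.time_h.to_numpy()
        for lev in sorted(set(times))[1:]:
            cols[f"time[{lev:g}]"] = (times == lev).astype(float)
    return pd.DataFrame(cols, index=list(metadata.sample_ids))


def _contrast_vector(
    design_cols: pd.Index, contrast: tuple[str, str]
) -> np.ndarray:
    """c such that c @ beta = log-fold-change of contrast[0] over contrast[1]."""
    c = np.zeros(len(design_cols))

    def coef(level: str) -> None:
        name = f"source[{level}]"
        if name in design_cols:
            c[design_cols.get_loc(name)] += sign
        # reference level contributes 0

    sign = 1.0
    coef(contrast[0])
    sign = -1.0
    coef(contrast[1])
    if not c.any():
        raise ValidationError(f"contrast {contrast} is identically zero")
    return c


def _nb_loglik_cr(alpha: float, y: np.ndarray, mu: np.ndarray, X: np.ndarray) -> float:
    """Cox-Reid-adjusted NB log-likelihood in the dispersion alpha (mu fixed)."""
    r = 1.0 / alpha
    ll = float(scipy.stats.nbinom.logpmf(y, r, r / (r + mu)).sum())
    W = mu / (1.0 + alpha * mu)
    xtwx = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(xtwx)
    if sign <= 0:
        return -np.inf
    return ll - 0.5 * logdet


def _estimate_alpha(y: np.ndarray, mu: np.ndarray, X: np.ndarray) -> float:
    """Per-feature dispersion by CR-adjusted ML over log alpha."""
    # method-of-moments initialization bounds the search sensibly but the
    # optimum is found over the full (floor, ceil) range anyway
    res = minimize_scalar(
        lambda la: -_nb_loglik_cr(np.exp(la), y, mu, X),
        bounds=(np.log(_ALPHA_FLOOR), np.log(_ALPHA_CEIL)),
        method="bounded",
    )
    return float(np.exp(res.x))


def _fit_feature(
    y: np.ndarray, X: np.ndarray, offset: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Fit one NB GLM; returns (beta, cov, alpha) or None on failure."""
    try:
        pois = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        mu = np.maximum(pois.fittedvalues, 1e-8)
        alpha = _estimate_alpha(y, mu, X)
        for _ in range(2):  # alternate beta | alpha
            fam = sm.families.NegativeBinomial(alpha=max(alpha, _ALPHA_FLOOR))
            fit = sm.GLM(y, X, family=fam, offset=offset).fit(
                start_params=pois.params, maxiter=100
            )
            mu = np.maximum(fit.fittedvalues, 1e-8)
            alpha = _estimate_alpha(y, mu, X)
        if not fit.converged:
            return None
        return np.asarray(fit.params), np.asarray(fit.cov_params()), alpha
    except Exception:
        return None


def nb_wald(
    counts: pd.DataFrame,
    metadata: SampleMetadata,
    design: str = "source+time",
    contrast: tuple[str, str] = ("host", "control"),
) -> DifferentialResult:
    """NB Wald test for one source contrast across all features.

    ``counts`` is a features x samples frame (columns = sample IDs matching
    the metadata).  Features that are all-zero, or whose IRLS does not
    converge, are excluded from the result table and listed in ``skipped``
    (non-converged features keep a row with p = NaN).
    """
    if list(counts.columns) != list(metadata.sample_ids):
        missing = set(metadata.sample_ids) ^ set(counts.columns)
        if missing:
            raise ValidationError(f"counts/metadata sample mismatch: {sorted(missing)}")
        counts = counts[list(metadata.sample_ids)]
    mat = counts.to_numpy(dtype=float)
    if np.any(mat < 0):
        raise ValidationError("counts must be non-negative")
    feature_ids = list(counts.index)
    nonzero = mat.sum(axis=1) > 0
    skipped = [f for f, ok in zip(feature_ids, nonzero) if not ok]
    if skipped:
        logger.info("excluding %d all-zero features", len(skipped))
    mat_nz = mat[nonzero]
    kept_ids = [f for f, ok in zip(feature_ids, nonzero) if ok]
    s = size_factors(mat_nz)
    offset = np.log(s)
    Xdf = build_design(metadata, design)
    for lev in contrast:
        if lev not in set(metadata.source):
            raise ValidationError(f"contrast level {lev!r} absent from metadata")
    X = Xdf.to_numpy()
    c = _contrast_vector(Xdf.columns, contrast)
    base_mean = (mat_nz / s).mean(axis=1)
    rows = []
    for fid, y, bm in zip(kept_ids, mat_nz, base_mean):
        res = _fit_feature(y, X, offset)
        if res is None:
            skipped.append(fid)
            rows.append(
                {
                    "feature": fid,
                    "baseMean": bm,
                    "log2FC": np.nan,
                    "se": np.nan,
                    "stat": np.nan,
                    "p": np.nan,
                }
            )
            continue
        beta, cov, _alpha = res
        lfc_ln = float(c @ beta)
        se_ln = float(np.sqrt(c @ cov @ c))
        stat = lfc_ln / se_ln if se_ln > 0 else np.nan
        p = 2.0 * scipy.stats.norm.sf(abs(stat)) if np.isfinite(stat) else np.nan
        ln2 = np.log(2.0)
        rows.append(
            {
                "feature": fid,
                "baseMean": bm,
                "log2FC": lfc_ln / ln2,
                "se": se_ln / ln2,
                "stat": stat,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    table["padj"] = bh_adjust(table["p"].to_numpy()) if len(table) else []
    return DifferentialResult(
        table=table, contrast=tuple(contrast), skipped=tuple(skipped)
    )
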