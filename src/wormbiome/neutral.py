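"""Neutral community model fit to occurrence-frequency data.

Under a neutral (drift + immigration) assembly model, the long-run
distribution of a taxon's local relative abundance is approximately
Beta(Nm*p, Nm*(1-p)), where p is its metacommunity relative abundance and
Nm the fundamental dispersal number (community size x immigration
probability per birth-death event).  The probability of *detecting* the
taxon (relative abundance above a detection limit d) is therefore

    F(p) = 1 - I_d(Nm*p, Nm*(1-p)),

with I the regularized incomplete beta function.  Fitting F to the
observed occurrence frequencies across samples yields Nm, the dispersal
probability m = Nm / N, and a goodness-of-fit R^2 measuring how much of
the occurrence-frequency pattern drift and dispersal alone explain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betainc

from .core_io import AbundanceTable, SampleMetadata, ValidationError

logger = logging.getLogger("wormbiome")

_LOG_NM_BOUNDS = (np.log(1e-2), np.log(1e7))


@dataclass
class NeutralFitResult:
    """One neutral-model fit (optionally per (source, time) group)."""

    group: tuple[str, float] | None
    Nm: float
    N: float
    m: float  # Nm / N, clamped into [0, 1] with a warning
    d: float  # detection threshold (relative abundance)
    r_squared: float
    n_taxa: int
    per_taxon: pd.DataFrame  # columns: taxon, p, freq, predicted
    degenerate: bool = False  # SST == 0, r_squared undefined (reported as nan)
    at_bound: bool = False  # optimizer ended at a parameter bound
    Nm_ci: tuple[float, float] | None = None  # bootstrap CI over taxa


def occurrence_frequencies(table: AbundanceTable, d: float) -> pd.DataFrame:
    """Per-taxon mean relative abundance p and occurrence frequency.

    freq_t = fraction of samples where taxon t's relative abundance
    exceeds the detection threshold d; taxa with p = 0 are dropped.
    """
    if table.n_samples < 2:
        raise ValidationError("occurrence frequencies need >= 2 samples")
    if not 0 < d < 1:
        raise ValidationError("detection threshold d must lie in (0, 1)")
    rel = table.relative()
    p = rel.mean(axis=0)
    freq = (rel > d).mean(axis=0)
    keep = p > 0
    return pd.DataFrame(
        {
            "taxon": np.asarray(table.taxon_ids)[keep],
            "p": p[keep],
            "freq": freq[keep],
        }
    ).reset_index(drop=True)


def sloan_expected_frequency(p, Nm: float, d: float):
    """Expected occurrence frequency F(p) = 1 - I_d(Nm*p, Nm*(1-p)).

    Accepts a scalar or array of metacommunity relative abundances p,
    each strictly inside (0, 1).
    """
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr <= 0) | (p_arr >= 1)):
        raise ValidationError("p must lie strictly in (0, 1)")
    if Nm <= 0:
        raise ValidationError("Nm must be > 0")
    if not 0 < d < 1:
        raise ValidationError("d must lie in (0, 1)")
    out = 1.0 - betainc(Nm * p_arr, Nm * (1.0 - p_arr), d)
    return float(out) if np.isscalar(p) else out


def _fit_nm(
    p: np.ndarray,
    freq: np.ndarray,
    d: float,
    method: str = "least_squares",
    n_samples: int | None = None,
) -> tuple[float, bool]:
    """Nm by bounded scalar optimization over log Nm.

    ``method="least_squares"`` (default) minimizes the squared deviation of
    observed occurrence frequencies from the expected curve, matching the
    standard practice for this fit; ``method="binomial"`` maximizes the
    binomial likelihood of the observed detection counts (requires
    ``n_samples``).
    """
    if method == "least_squares":

        def objective(log_nm: float) -> float:
            pred = 1.0 - betainc(np.exp(log_nm) * p, np.exp(log_nm) * (1.0 - p), d)
            return float(((freq - pred) ** 2).sum())

    elif method == "binomial":
        if not n_samples:
            raise ValidationError("binomial likelihood fit requires n_samples")
        k = np.round(freq * n_samples)

        def objective(log_nm: float) -> float:
            pred = 1.0 - betainc(np.exp(log_nm) * p, np.exp(log_nm) * (1.0 - p), d)
            pred = np.clip(pred, 1e-12, 1.0 - 1e-12)
            return -float(
                (k * np.log(pred) + (n_samples - k) * np.log1p(-pred)).sum()
            )

    else:
        raise ValidationError("method must be 'least_squares' or 'binomial'")

    res = minimize_scalar(objective, bounds=_LOG_NM_BOUNDS, method="bounded")
    log_nm = float(res.x)
    at_bound = (
        log_nm <= _LOG_NM_BOUNDS[0] + 1e-6 or log_nm >= _LOG_NM_BOUNDS[1] - 1e-6
    )
    return float(np.exp(log_nm)), at_bound


def fit_neutral_model(
    table: AbundanceTable,
    d: float | None = None,
    N: float | None = None,
    n_boot: int = 500,
    seed: int = 0,
    group: tuple[str, float] | None = None,
    method: str = "least_squares",
) -> NeutralFitResult:
    """Fit the neutral occurrence curve to one sample group.

    Defaults: d = 1 / median(library size) (one read at typical depth) and
    N = median library size, both logged with the result.  R^2 is computed
    against the mean observed frequency; a bootstrap over taxa (``n_boot``
    resamples, seeded; 0 disables) gives a CI for Nm.  ``method`` selects
    the least-squares curve fit (default) or a binomial likelihood.
    """
    med_depth = float(np.median(table.library_sizes))
    if d is None:
        d = 1.0 / med_depth
    if N is None:
        N = med_depth
    occ = occurrence_frequencies(table, d)
    p = occ["p"].to_numpy()
    freq = occ["freq"].to_numpy()
    informative = int(((freq > 0) & (freq < 1)).sum())
    if informative < 5:
        logger.warning(
            "only %d taxa with intermediate occurrence frequency; "
            "the neutral fit may be poorly constrained",
            informative,
        )
    nm, at_bound = _fit_nm(p, freq, d, method=method, n_samples=table.n_samples)
    if at_bound:
        logger.warning("neutral fit: optimizer at parameter bound (Nm=%.3g)", nm)
    pred = sloan_expected_frequency(p, nm, d)
    sse = float(((freq - pred) ** 2).sum())
    sst = float(((freq - freq.mean()) ** 2).sum())
    degenerate = sst == 0.0
    if degenerate:
        logger.warning("neutral fit: all occurrence frequencies identical (SST=0)")
        r2 = float("nan")
    else:
        r2 = 1.0 - sse / sst
    m = nm / N
    if m > 1.0:
        logger.warning("fitted Nm (%.3g) exceeds N (%.3g); clamping m to 1", nm, N)
        m = 1.0
    ci = None
    if n_boot > 0 and len(p) >= 2:
        rng = np.random.default_rng(seed)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, len(p), size=len(p))
            nm_b, _ = _fit_nm(
                p[idx], freq[idx], d, method=method, n_samples=table.n_samples
            )
            boots.append(nm_b)
        ci = tuple(np.quantile(boots, [0.025, 0.975]))
    per_taxon = occ.assign(predicted=pred)
    return NeutralFitResult(
        group=group,
        Nm=nm,
        N=float(N),
        m=float(m),
        d=float(d),
        r_squared=r2,
        n_taxa=len(p),
        per_taxon=per_taxon,
        degenerate=degenerate,
        at_bound=at_bound,
        Nm_ci=ci,
    )


def neutral_fit_by_group(
    table: AbundanceTable,
    metadata: SampleMetadata,
    d: float | None = None,
    n_mode: str = "median_depth",
    N_fixed: float | None = None,
    n_boot: int = 0,
    seed: int = 0,
) -> list[NeutralFitResult]:
    """One neutral fit per (source, time) group, ordered by source then time.

    ``n_mode`` is ``"median_depth"`` (N = the group's median library size)
    or ``"fixed"`` (N = ``N_fixed``).  Groups with fewer than 3 samples are
    skipped with a warning.
    """
    if n_mode not in ("median_depth", "fixed"):
        raise ValidationError("n_mode must be 'median_depth' or 'fixed'")
    if n_mode == "fixed" and not N_fixed:
        raise ValidationError("n_mode='fixed' requires N_fixed")
    results: list[NeutralFitResult] = []
    for (source, time_h), ids in metadata.groups(("source", "time_h")):
        if len(ids) < 3:
            logger.warning(
                "group (%s, %s): only %d samples, skipped", source, time_h, len(ids)
            )
            continue
        sub = table.subset_samples(ids)
        N = N_fixed if n_mode == "fixed" else None
        results.append(
            fit_neutral_model(
                sub, d=d, N=N, n_boot=n_boot, seed=seed, group=(source, float(time_h))
            )
        )
    if not results:
        raise ValidationError("no (source, time) group had >= 3 samples")
    return results


def neutral_results_frame(results: Sequence[NeutralFitResult]) -> pd.DataFrame:
    """Flatten fit results into one row per group for reporting."""
    rows = []
    for r in results:
        src, t = r.group if r.group is not None else (None, None)
        rows.append(
            {
                "source": src,
                "time_h": t,
                "Nm": r.Nm,
                "N": r.N,
                "m": r.m,
                "d": r.d,
                "r_squared": r.r_squared,
                "n_taxa": r.n_taxa,
                "degenerate": r.degenerate,
                "at_bound": r.at_bound,
            }
        )
    return pd.DataFrame(rows)
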