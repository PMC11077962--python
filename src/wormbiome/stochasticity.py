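"""Normalized stochasticity ratio (tNST) with null-model randomization.

For each within-group sample pair the observed dissimilarity D_ij is
compared with its expectation E_ij under a null model that randomizes
community composition while preserving chosen observed structure.  The
selection strength

    SS_ij = (E_ij - D_ij) / E_ij            if D_ij < E_ij
    SS_ij = (D_ij - E_ij) / (D_max - E_ij)  otherwise  (D_max = 1)

measures how far the observed pair departs from the null in either
direction; NST_ij = 1 - SS_ij, and the group's tNST is the mean over
pairs.  Values above 0.5 read as stochasticity-dominated assembly, below
0.5 as determinism-dominated.

The default null model "PF" keeps each sample's richness Fixed and draws
taxa with Probability proportional to their regional occurrence frequency;
abundances are then assigned by a multinomial draw of the sample's library
size over the drawn taxa, proportional to regional relative abundances
(each drawn taxon is first given one read so realized richness is exact).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .core_io import AbundanceTable, ValidationError

logger = logging.getLogger("wormbiome")

NULL_MODELS = ("PF",)
NST_METRICS = ("jaccard", "bray_curtis")


@dataclass
class NSTResult:
    """Per-group tNST with its pairwise decomposition and settings."""

    group: str
    pairs: pd.DataFrame  # sample_i, sample_j, observed, null_mean, ss, nst
    group_nst: float
    settings: dict


def _pairwise(counts: np.ndarray, metric: str) -> np.ndarray:
    if metric == "jaccard":
        return squareform(pdist(counts > 0, metric="jaccard"), checks=False)
    if metric == "bray_curtis":
        d = pdist(counts.astype(float), metric="braycurtis")
        return squareform(np.nan_to_num(d, nan=0.0), checks=False)
    raise ValidationError(f"unknown metric {metric!r}; allowed: {NST_METRICS}")


def null_randomize(
    table: AbundanceTable, null_model: str = "PF", seed: int = 0
) -> AbundanceTable:
    """One null draw of the table under the given null model (seeded)."""
    if null_model not in NULL_MODELS:
        raise ValidationError(
            f"unknown null model {null_model!r}; supported: {NULL_MODELS}"
        )
    rng = np.random.default_rng(seed)
    counts = table.counts
    occ = (counts > 0).mean(axis=0)  # regional occurrence frequency
    regional = counts.sum(axis=0).astype(float)
    regional_rel = regional / regional.sum()
    S = counts.shape[1]
    out = np.zeros_like(counts)
    for i in range(counts.shape[0]):
        k = int((counts[i] > 0).sum())
        lib = int(counts[i].sum())
        if k == 0:
            continue
        probs = occ / occ.sum()
        chosen = rng.choice(S, size=k, replace=False, p=probs)
        out[i, chosen] = 1  # guarantee realized richness == k
        if lib > k:
            w = regional_rel[chosen]
            out[i, chosen] += rng.multinomial(lib - k, w / w.sum())
    return AbundanceTable.from_arrays(out, table.sample_ids, table.taxon_ids)


def expected_dissimilarity(
    table: AbundanceTable,
    metric: str = "jaccard",
    n_null: int = 1000,
    seed: int = 0,
    null_model: str = "PF",
) -> np.ndarray:
    """Pairwise null-mean dissimilarity matrix over ``n_null`` randomizations."""
    if n_null < 2:
        raise ValidationError("n_null must be >= 2")
    if n_null < 100:
        logger.warning("n_null=%d is small; >= 100 recommended", n_null)
    acc = np.zeros((table.n_samples, table.n_samples))
    seeds = np.random.SeedSequence(seed).generate_state(n_null) % 2**31
    for s in seeds:
        null = null_randomize(table, null_model=null_model, seed=int(s))
        acc += _pairwise(null.counts, metric)
    return acc / n_null


def selection_strength(d_ij: float, e_ij: float, d_max: float = 1.0) -> float:
    """Pairwise selection strength in [0, 1].

    Similarity excess (observed pair more similar than the null) is
    normalized by the null expectation; dissimilarity excess by the
    remaining range up to ``d_max``.  ``d_ij == e_ij`` (including both 0
    or both ``d_max``) gives 0: the pair is indistinguishable from the
    null.  NST of the pair is ``1 - selection_strength``.
    """
    if d_ij == e_ij:
        return 0.0
    if d_ij < e_ij:
        ss = (e_ij - d_ij) / e_ij
    else:
        ss = (d_ij - e_ij) / (d_max - e_ij) if e_ij < d_max else 0.0
    return min(max(ss, 0.0), 1.0)


def nst(
    table: AbundanceTable,
    groups: Sequence[str],
    metric: str = "jaccard",
    null_model: str = "PF",
    n_null: int = 1000,
    seed: int = 0,
    d_max: float = 1.0,
) -> list[NSTResult]:
    """tNST per group; pairs are within-group only, nulls drawn per group.

    Groups with fewer than 3 samples are skipped with a warning.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != table.n_samples:
        raise ValidationError("groups length must match the table")
    results: list[NSTResult] = []
    for gi, g in enumerate(pd.unique(groups)):
        ids = [s for s, lab in zip(table.sample_ids, groups) if lab == g]
        if len(ids) < 3:
            logger.warning("group %r: only %d samples, skipped", g, len(ids))
            continue
        sub = table.subset_samples(ids)
        obs = _pairwise(sub.counts, metric)
        null_mean = expected_dissimilarity(
            sub, metric=metric, n_null=n_null, seed=int(seed) + gi, null_model=null_model
        )
        rows = []
        n = len(ids)
        for i in range(n):
            for j in range(i + 1, n):
                d_ij, e_ij = float(obs[i, j]), float(null_mean[i, j])
                ss = selection_strength(d_ij, e_ij, d_max)
                rows.append(
                    {
                        "sample_i": ids[i],
                        "sample_j": ids[j],
                        "observed": d_ij,
                        "null_mean": e_ij,
                        "ss": ss,
                        "nst": 1.0 - ss,
                    }
                )
        pairs = pd.DataFrame(rows)
        results.append(
            NSTResult(
                group=str(g),
                pairs=pairs,
                group_nst=float(pairs["nst"].mean()),
                settings={
                    "metric": metric,
                    "null_model": null_model,
                    "n_null": n_null,
                    "seed": int(seed),
                    "d_max": d_max,
                },
            )
        )
    if not results:
        raise ValidationError("no group had >= 3 samples")
    return results


class BootstrapCompareResult(NamedTuple):
    delta_nst: float  # mean NST(A) - mean NST(B)
    p_value: float
    n_boot: int


def nst_bootstrap_compare(
    res_a: NSTResult, res_b: NSTResult, n_boot: int = 1000, seed: int = 0
) -> BootstrapCompareResult:
    """Two-sided bootstrap test for a difference in group tNST.

    Resamples each group's pairwise NST values with replacement ``n_boot``
    times; the p-value is twice the smaller tail fraction of replicate
    differences on either side of zero, with the +1 finite-sample
    correction, capped at 1.
    """
    a = res_a.pairs["nst"].to_numpy()
    b = res_b.pairs["nst"].to_numpy()
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("both groups need >= 3 pairwise NST values")
    if n_boot < 100:
        logger.warning("n_boot=%d is small; >= 100 recommended", n_boot)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    for i in range(n_boot):
        deltas[i] = (
            rng.choice(a, size=len(a), replace=True).mean()
            - rng.choice(b, size=len(b), replace=True).mean()
        )
    p_low = (1 + int((deltas <= 0).sum())) / (1 + n_boot)
    p_high = (1 + int((deltas >= 0).sum())) / (1 + n_boot)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return BootstrapCompareResult(float(a.mean() - b.mean()), p, n_boot)


def nst_results_frame(results: Sequence[NSTResult]) -> pd.DataFrame:
    rows = [
        {
            "group": r.group,
            "group_nst": r.group_nst,
            "n_pairs": len(r.pairs),
            "metric": r.settings["metric"],
            "null_model": r.settings["null_model"],
            "n_null": r.settings["n_null"],
        }
        for r in results
    ]
    return pd.DataFrame(rows)
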