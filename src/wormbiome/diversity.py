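"""Alpha/beta diversity, ordination and group comparisons.

Covers within-sample diversity (Shannon in nats, Simpson as 1 - dominance,
bias-corrected Chao1), pairwise dissimilarity (Bray-Curtis, Aitchison =
Euclidean on CLR-transformed compositions, normalized weighted UniFrac),
principal-coordinates analysis by Gower double-centering, a
permutation-based PERMANOVA (with exhaustive enumeration on tiny designs),
paired between-source distance trends, Spearman time trends, and
ANOVA / Tukey HSD group comparisons.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.spatial.distance import pdist, squareform
from skbio.diversity import beta_diversity as _skbio_beta
from skbio.diversity.alpha import chao1 as _skbio_chao1

from .core_io import (
    AbundanceTable,
    DistanceMatrix,
    PhyloTree,
    SampleMetadata,
    ValidationError,
)

logger = logging.getLogger("wormbiome")

ALPHA_METRICS = ("shannon", "simpson", "chao1")
BETA_METRICS = ("bray_curtis", "aitchison", "weighted_unifrac")


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(counts: np.ndarray, metric: str) -> float:
    """One alpha-diversity value for one sample's count vector.

    shannon = -sum p_i ln p_i (nats, zero terms dropped);
    simpson = 1 - sum p_i^2; chao1 = S_obs + F1(F1-1)/(2(F2+1))
    (bias-corrected, F1/F2 = singleton/doubleton counts).
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValidationError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValidationError("all-zero count vector")
    if metric == "shannon":
        p = counts[counts > 0] / total
        return float(-(p * np.log(p)).sum())
    if metric == "simpson":
        p = counts / total
        return float(1.0 - (p**2).sum())
    if metric == "chao1":
        return float(_skbio_chao1(counts.astype(int), bias_corrected=True))
    raise ValidationError(f"unknown alpha metric {metric!r}; allowed: {ALPHA_METRICS}")


def alpha_diversity_table(
    table: AbundanceTable, metrics: Sequence[str] = ALPHA_METRICS
) -> pd.DataFrame:
    """Long-format per-sample alpha diversity (sample_id, metric, value)."""
    rows = [
        {"sample_id": sid, "metric": m, "value": alpha_diversity(row, m)}
        for sid, row in zip(table.sample_ids, table.counts)
        for m in metrics
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------


def clr_transform(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform after adding ``pseudocount`` to every cell."""
    x = np.asarray(counts, dtype=float) + float(pseudocount)
    if np.any(x <= 0):
        raise ValidationError(
            "CLR requires strictly positive entries; increase the pseudocount"
        )
    logx = np.log(x)
    return logx - logx.mean(axis=-1, keepdims=True)


def beta_diversity(
    table: AbundanceTable,
    metric: str,
    tree: PhyloTree | None = None,
    pseudocount: float = 0.5,
) -> DistanceMatrix:
    """Pairwise sample dissimilarity matrix under one metric.

    ``bray_curtis`` operates on raw counts; ``aitchison`` is the Euclidean
    distance between CLR vectors (pseudocount added to every cell first);
    ``weighted_unifrac`` is the normalized branch-weighted form and
    requires a rooted tree covering every taxon in the table.
    """
    ids = list(table.sample_ids)
    if metric == "bray_curtis":
        d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    elif metric == "aitchison":
        clr = clr_transform(table.counts, pseudocount=pseudocount)
        d = squareform(pdist(clr, metric="euclidean"))
    elif metric == "weighted_unifrac":
        if tree is None:
            raise ValidationError("weighted_unifrac requires a tree")
        missing = sorted(set(table.taxon_ids) - set(tree.leaf_names))
        if missing:
            raise ValidationError(f"taxa absent from tree: {missing}")
        dm = _skbio_beta(
            "weighted_unifrac",
            table.counts,
            ids=ids,
            taxa=list(table.taxon_ids),
            tree=tree.tree,
            normalized=True,
        )
        d = dm.data
    else:
        raise ValidationError(f"unknown beta metric {metric!r}; allowed: {BETA_METRICS}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(tuple(ids), d, metric)


# ---------------------------------------------------------------------------
# Ordination
# ---------------------------------------------------------------------------


class PCoAResult(NamedTuple):
    coordinates: pd.DataFrame  # samples x k
    eigenvalues: np.ndarray  # all n eigenvalues, descending (negatives kept)


def pcoa(D: DistanceMatrix, k: int) -> PCoAResult:
    """Principal coordinates via Gower double-centering.

    B = -1/2 J (D o D) J with J the centering matrix; coordinates are
    eigvec * sqrt(eigval) for positive eigenvalues.  All eigenvalues are
    returned so that negative ones (non-Euclidean input) are visible.
    """
    n = D.n_samples
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > n - 1:
        raise ValidationError(f"k must be <= n-1 = {n - 1}")
    d2 = D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = scipy.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    n_neg = int((eigval < -1e-10 * max(1.0, abs(eigval[0]))).sum())
    if n_neg:
        logger.warning("PCoA: %d negative eigenvalues (non-Euclidean distances)", n_neg)
    coords = eigvec[:, :k] * np.sqrt(np.clip(eigval[:k], 0.0, None))
    frame = pd.DataFrame(
        coords, index=list(D.sample_ids), columns=[f"PC{i + 1}" for i in range(k)]
    )
    return PCoAResult(frame, eigval)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


class PermanovaResult(NamedTuple):
    pseudo_f: float
    p_value: float
    n_permutations: int
    exhaustive: bool


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        mask = codes == g
        n_g = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    a = n_groups
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


def permanova(
    D: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix.

    pseudo-F follows the classic sums-of-squares decomposition of squared
    distances; the p-value uses seeded label permutations with the
    (1 + exceedances)/(1 + n_perm) estimator, switching to exhaustive
    enumeration of all distinct label arrangements when there are at most
    ``n_perm`` of them (the p-value is then exact: exceedances / total,
    with the observed arrangement included).
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != D.n_samples:
        raise ValidationError("groups length must match the distance matrix")
    levels, codes = np.unique(groups, return_inverse=True)
    if len(levels) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        raise ValidationError("every group needs >= 2 samples")
    d2 = D.values**2
    f_obs = _pseudo_f(d2, codes, len(levels))
    n = len(codes)
    # number of distinct arrangements: n! / prod(n_g!)
    log_total = math.lgamma(n + 1) - sum(math.lgamma(s + 1) for s in sizes)
    exhaustive = log_total <= math.log(max(n_perm, 1)) + 1e-9
    if exhaustive:
        exceed = 0
        total = 0
        for perm in _multiset_permutations(codes):
            f = _pseudo_f(d2, perm, len(levels))
            total += 1
            if f >= f_obs - 1e-12:
                exceed += 1
        return PermanovaResult(float(f_obs), exceed / total, total, True)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f = _pseudo_f(d2, rng.permutation(codes), len(levels))
        if f >= f_obs - 1e-12:
            exceed += 1
    return PermanovaResult(float(f_obs), (1 + exceed) / (1 + n_perm), n_perm, False)


def _multiset_permutations(codes: np.ndarray):
    """All distinct arrangements of the label multiset (as code arrays)."""
    n = len(codes)
    levels, sizes = np.unique(codes, return_counts=True)

    def rec(free: tuple[int, ...], li: int, arr: np.ndarray):
        if li == len(levels) - 1:
            out = arr.copy()
            out[list(free)] = levels[li]
            yield out
            return
        for combo in itertools.combinations(free, int(sizes[li])):
            arr2 = arr.copy()
            arr2[list(combo)] = levels[li]
            rest = tuple(i for i in free if i not in combo)
            yield from rec(rest, li + 1, arr2)

    yield from rec(tuple(range(n)), 0, np.empty(n, dtype=codes.dtype))


# ---------------------------------------------------------------------------
# Paired distance trends
# ---------------------------------------------------------------------------


def paired_distance_trend(
    D: DistanceMatrix,
    metadata: SampleMetadata,
    source_pair: tuple[str, str],
    pair_mode: str = "plate",
    n_rep: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean between-source sample distance per time point.

    ``plate`` mode pairs samples of the two sources sharing a plate ID;
    ``random`` mode averages over ``n_rep`` seeded random bijections
    between the two source groups at each time.  Returns a frame with
    columns (time_h, mean, sd, n_pairs).  Time points without pairable
    samples are omitted with a warning.
    """
    if pair_mode not in ("plate", "random"):
        raise ValidationError("pair_mode must be 'plate' or 'random'")
    src_a, src_b = source_pair
    md = metadata.to_dataframe()
    rng = np.random.default_rng(seed)
    rows = []
    for t in sorted(md["time_h"].unique()):
        at = md[(md["time_h"] == t) & (md["source"] == src_a)]
        bt = md[(md["time_h"] == t) & (md["source"] == src_b)]
        dists: list[float] = []
        if pair_mode == "plate":
            shared = sorted(set(at["plate"].dropna()) & set(bt["plate"].dropna()))
            n_skipped = (len(at) - len(shared)) + (len(bt) - len(shared))
            if n_skipped:
                logger.info(
                    "t=%s: %d unpaired %s/%s samples skipped", t, n_skipped, src_a, src_b
                )
            for plate in shared:
                ia = at.index[at["plate"] == plate][0]
                ib = bt.index[bt["plate"] == plate][0]
                dists.append(D.pair(ia, ib))
        else:
            ids_a, ids_b = list(at.index), list(bt.index)
            if ids_a and ids_b:
                k = min(len(ids_a), len(ids_b))
                for _ in range(n_rep):
                    pa = rng.permutation(ids_a)[:k]
                    pb = rng.permutation(ids_b)[:k]
                    dists.extend(D.pair(a, b) for a, b in zip(pa, pb))
        if not dists:
            logger.warning("t=%s: no pairable samples for (%s, %s)", t, src_a, src_b)
            continue
        arr = np.asarray(dists)
        rows.append(
            {
                "time_h": float(t),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
                "n_pairs": len(arr),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trends and group tests
# ---------------------------------------------------------------------------


class TrendResult(NamedTuple):
    rho: float
    p_value: float
    constant: bool  # True when the values were constant (rho undefined -> 0)


def diversity_trend(values: Sequence[float], time: Sequence[float]) -> TrendResult:
    """Spearman rank correlation (midrank ties, t-approximation p-value)."""
    values = np.asarray(values, dtype=float)
    time = np.asarray(time, dtype=float)
    if len(values) != len(time) or len(values) < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.all(values == values[0]) or np.all(time == time[0]):
        return TrendResult(0.0, 1.0, True)
    rho, p = scipy.stats.spearmanr(time, values)
    return TrendResult(float(rho), float(p), False)


def anova_tukey(
    values: Sequence[float],
    factor_a: Sequence[str],
    factor_b: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fixed-effects ANOVA (type-I SS, no interaction) plus Tukey HSD.

    Returns ``(anova_table, tukey_table)``; Tukey compares the levels of
    ``factor_a`` using the studentized range distribution.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.asarray(values, dtype=float)
    fa = np.asarray([str(x) for x in factor_a])
    if len(np.unique(fa)) < 2:
        raise ValidationError("factor_a needs >= 2 levels")
    for lev, cnt in zip(*np.unique(fa, return_counts=True)):
        if cnt < 2:
            raise ValidationError(f"level {lev!r} has < 2 observations")
    df = pd.DataFrame({"value": values, "a": fa})
    formula = "value ~ C(a)"
    if factor_b is not None:
        df["b"] = np.asarray([str(x) for x in factor_b])
        formula += " + C(b)"
    model = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(model, typ=1)
    tukey = pairwise_tukeyhsd(df["value"], df["a"])
    tukey_df = pd.DataFrame(
        {
            "group1": [str(g) for g in tukey.groupsunique[tukey._multicomp.pairindices[0]]],
            "group2": [str(g) for g in tukey.groupsunique[tukey._multicomp.pairindices[1]]],
            "meandiff": tukey.meandiffs,
            "p_adj": tukey.pvalues,
            "lower": tukey.confint[:, 0],
            "upper": tukey.confint[:, 1],
            "reject": tukey.reject,
        }
    )
    return anova, tukey_df
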