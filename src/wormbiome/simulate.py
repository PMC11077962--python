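"""Synthetic community generator for defined-microbiome time courses.

Emulates the statistical structure of a worm microbiome colonization
experiment: three sample sources (worm-free control plates, worm-associated
substrate lawns, and hosts), six sampling times, and about ten replicates
per condition, yielding 180 samples over a 43-taxon species pool.

The generative model, bottom to top:

1. a metacommunity (species pool) with lognormal relative abundances,
2. per-sample local community dynamics as a Moran birth-death process with
   immigration: at each of the ``N`` replacement events per generation a
   uniformly chosen individual dies and is replaced, with probability ``m``,
   by an immigrant drawn from the metacommunity (weighted by the source's
   fitness vector) and otherwise by the offspring of a local individual
   (weighted likewise).  With all-ones fitness this is exactly the neutral
   model whose stationary occurrence curve the fitting stage assumes,
3. multinomial read sampling at a fixed sequencing depth,
4. a binary taxon x function trait table over eight subsystems in which
   carriage of "gut" functions is enriched among a designated set of
   host-adapted taxa; the host source's fitness vector is then *derived*
   from gut-trait carriage, so host enrichment of gut functions downstream
   is an emergent property of the dynamics rather than being painted on.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numba import njit
from skbio import TreeNode

from .core_io import (
    SOURCES,
    SUBSYSTEMS,
    AbundanceTable,
    PhyloTree,
    SampleMetadata,
    TraitTable,
    ValidationError,
)

import pandas as pd

__all__ = [
    "SimulationConfig",
    "sample_metacommunity",
    "simulate_assembly",
    "sample_reads",
    "generate_trait_table",
    "generate_dataset",
    "random_tree",
]

#: Default number of trait functions drawn for each of the eight subsystems.
DEFAULT_FUNCTIONS_PER_SUBSYSTEM: dict[str, int] = {s: 10 for s in SUBSYSTEMS}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic experiment.

    Defaults reproduce the emulated study design: 43 taxa, 3 sources x
    6 time points (16–186 h) x 10 replicates = 180 samples, local
    communities of ``N`` = 10 000 individuals sequenced to 10 000 reads.

    ``fitness`` maps each source to a length-``S`` vector of positive
    per-capita reproductive weights; ``None`` means all-ones (neutral) for
    control and substrate while the host vector is derived from gut-trait
    carriage with effect size ``gut_link``.
    """

    S: int = 43
    metacommunity_sigma: float = 1.5
    N: int = 10_000
    m: float = 0.1
    fitness: Mapping[str, np.ndarray] | None = None
    generations_per_hour: float = 1.0
    time_points_h: tuple[float, ...] = (16.0, 42.0, 66.0, 90.0, 138.0, 186.0)
    replicates: int = 10
    depth: int = 10_000
    gut_link: float = 2.0
    n_host_fit_taxa: int = 20
    functions_per_subsystem: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_FUNCTIONS_PER_SUBSYSTEM)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValidationError("S must be >= 2")
        if not 0.0 <= self.m <= 1.0:
            raise ValidationError("m must lie in [0, 1]")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.N < 1:
            raise ValidationError("N must be >= 1")
        if self.fitness is not None:
            for src, w in self.fitness.items():
                w = np.asarray(w, dtype=float)
                if w.shape != (self.S,) or np.any(w <= 0):
                    raise ValidationError(
                        f"fitness[{src!r}] must be {self.S} positive values"
                    )


def _spawn_seed(seed: int, *tokens: int) -> int:
    """Derive a child integer seed (< 2**31) from a parent seed and tokens."""
    return int(np.random.SeedSequence([seed, *tokens]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# Metacommunity
# ---------------------------------------------------------------------------


def sample_metacommunity(S: int, sigma: float, seed: int) -> np.ndarray:
    """Lognormal(0, sigma^2) relative abundances over ``S`` taxa, normalized."""
    if S < 2:
        raise ValidationError("S must be >= 2")
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    x = rng.lognormal(mean=0.0, sigma=sigma, size=S)
    return x / x.sum()


# ---------------------------------------------------------------------------
# Moran dynamics (numba kernel)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _moran_run(
    slots: np.ndarray,  # int32[N], taxon id of each individual
    n: np.ndarray,  # int64[S], taxon counts (consistent with slots)
    w: np.ndarray,  # float64[S], fitness weights
    cum_meta_w: np.ndarray,  # float64[S], cumsum of meta*w, normalized to 1
    m: float,
    neutral: bool,  # True when w is all-ones (enables O(1) local births)
    checkpoints: np.ndarray,  # int64[T], cumulative event counts to record at
    out: np.ndarray,  # int64[T, S], recorded counts
    seed: int,
) -> None:
    np.random.seed(seed)
    N = slots.size
    S = n.size
    tot_w = 0.0
    for i in range(S):
        tot_w += n[i] * w[i]
    ev = 0
    for t in range(checkpoints.size):
        target = checkpoints[t]
        while ev < target:
            # death: uniformly chosen individual
            idx = int(np.random.random() * N)
            if idx == N:
                idx = N - 1
            d = slots[idx]
            n[d] -= 1
            tot_w -= w[d]
            # birth
            if np.random.random() < m:
                r = np.random.random()
                b = 0
                for i in range(S):
                    if r < cum_meta_w[i]:
                        b = i
                        break
                    b = i
            elif neutral:
                # offspring of a uniformly chosen surviving individual
                j = int(np.random.random() * (N - 1))
                if j >= idx:
                    j += 1
                if j >= N:
                    j = N - 1
                b = slots[j]
            else:
                r = np.random.random() * tot_w
                acc = 0.0
                b = 0
                for i in range(S):
                    acc += n[i] * w[i]
                    if r < acc:
                        b = i
                        break
                    b = i
            slots[idx] = b
            n[b] += 1
            tot_w += w[b]
            ev += 1
        for i in range(S):
            out[t, i] = n[i]


def simulate_assembly(
    meta: np.ndarray,
    config: SimulationConfig,
    source: str,
    seed: int,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate one local community trajectory.

    Returns an integer array of shape (n_time_points, S): the latent
    individual counts at each configured sampling time.  Counts sum to
    ``config.N`` at every recorded time.

    ``init`` optionally fixes the initial taxon counts (summing to ``N``);
    the default is an even split across taxa, mirroring a defined inoculum.
    """
    meta = np.asarray(meta, dtype=float)
    S = meta.size
    if S != config.S:
        raise ValidationError(f"meta has {S} taxa, config.S = {config.S}")
    N = int(config.N)
    if N == 0:
        raise ValidationError("empty community (N=0)")
    w = _fitness_for(config, source)
    if init is None:
        base = N // S
        n0 = np.full(S, base, dtype=np.int64)
        n0[: N - base * S] += 1
    else:
        n0 = np.asarray(init, dtype=np.int64).copy()
        if n0.sum() != N or np.any(n0 < 0):
            raise ValidationError("init must be non-negative and sum to N")
    # individual slot array consistent with n0
    slots = np.repeat(np.arange(S, dtype=np.int32), n0)
    gens = np.asarray(
        [round(t * config.generations_per_hour) for t in config.time_points_h],
        dtype=np.int64,
    )
    if np.any(np.diff(gens) < 0):
        raise ValidationError("time_points_h must be non-decreasing")
    checkpoints = gens * N
    meta_w = meta * w
    cum_meta_w = np.cumsum(meta_w)
    cum_meta_w /= cum_meta_w[-1]
    neutral = bool(np.all(w == w[0]))
    if neutral and w[0] != 1.0:
        w = np.ones_like(w)  # uniform fitness is scale-free
    out = np.zeros((len(checkpoints), S), dtype=np.int64)
    n = n0.copy()
    _moran_run(
        slots,
        n,
        np.asarray(w, dtype=float),
        cum_meta_w,
        float(config.m),
        neutral,
        checkpoints,
        out,
        int(seed) % 2**31,
    )
    return out


def sample_reads(latent: np.ndarray, depth: int, seed: int) -> np.ndarray:
    """Multinomial read sampling of a latent community at fixed depth."""
    latent = np.asarray(latent, dtype=float)
    total = latent.sum()
    if total <= 0:
        raise ValidationError("latent community is empty")
    if depth < 1:
        raise ValidationError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(int(depth), latent / total)


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------


def generate_trait_table(
    S: int,
    functions_per_subsystem: Mapping[str, int],
    host_fit_taxa: Sequence[int],
    gut_link: float,
    seed: int,
    base_rate: float = 0.3,
    taxon_ids: Sequence[str] | None = None,
) -> TraitTable:
    """Bernoulli trait table with gut-function enrichment in host-fit taxa.

    Presence is Bernoulli(``base_rate``); for functions in the "gut"
    subsystem the *odds* of presence are multiplied by ``gut_link`` for
    taxa listed in ``host_fit_taxa`` (0-based indices).  Functions carried
    by no taxon are redrawn so every column has at least one carrier.
    """
    if not functions_per_subsystem:
        raise ValidationError("functions_per_subsystem must not be empty")
    bad = sorted(set(functions_per_subsystem) - set(SUBSYSTEMS))
    if bad:
        raise ValidationError(f"unknown subsystem(s) {bad}; allowed: {set(SUBSYSTEMS)}")
    host_fit = np.asarray(sorted(set(int(i) for i in host_fit_taxa)), dtype=int)
    if host_fit.size and (host_fit.min() < 0 or host_fit.max() >= S):
        raise ValidationError("host_fit_taxa indices out of range")
    rng = np.random.default_rng(seed)
    if taxon_ids is None:
        taxon_ids = [f"T{i:02d}" for i in range(S)]
    base_odds = base_rate / (1.0 - base_rate)
    gut_rate = (base_odds * gut_link) / (1.0 + base_odds * gut_link)
    cols: dict[str, np.ndarray] = {}
    subsystem: dict[str, str] = {}
    for sub in SUBSYSTEMS:
        n_fun = int(functions_per_subsystem.get(sub, 0))
        for k in range(n_fun):
            p = np.full(S, base_rate)
            if sub == "gut":
                p[host_fit] = gut_rate
            col = (rng.random(S) < p).astype(np.int8)
            while col.sum() == 0:  # every function must have >=1 carrier
                col = (rng.random(S) < p).astype(np.int8)
            fid = f"{sub}_{k:02d}"
            cols[fid] = col
            subsystem[fid] = sub
    presence = pd.DataFrame(cols, index=list(taxon_ids))
    return TraitTable(presence, subsystem)


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def random_tree(taxon_ids: Sequence[str], seed: int) -> PhyloTree:
    """Random bifurcating rooted tree with exponential(1) branch lengths.

    Coalescent-style construction: repeatedly join two uniformly chosen
    lineages under a new internal node.  Only meant to exercise
    phylogenetic distances, not to mimic any real phylogeny.
    """
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=str(t), length=float(rng.exponential(1.0))) for t in taxon_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = int(i), int(j)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(length=float(rng.exponential(1.0)))
        parent.extend([a, b])
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# Whole-dataset generation
# ---------------------------------------------------------------------------


def _fitness_for(config: SimulationConfig, source: str) -> np.ndarray:
    if source not in SOURCES:
        raise ValidationError(f"unknown source {source!r}; allowed: {set(SOURCES)}")
    if config.fitness is not None and source in config.fitness:
        return np.asarray(config.fitness[source], dtype=float)
    return np.ones(config.S)


def derive_host_fitness(traits: TraitTable, gut_link: float) -> np.ndarray:
    """Host fitness from gut-trait carriage: w_t = 1 + (gut_link-1) * carriage_t.

    ``carriage_t`` is the fraction of gut-subsystem functions taxon ``t``
    carries, so taxa encoding more gut functions are favored inside hosts
    and downstream functional enrichment emerges from the dynamics.
    """
    gut_funs = traits.functions_in_subsystem("gut")
    if not gut_funs:
        return np.ones(len(traits.taxon_ids))
    pres = traits.to_dataframe()[gut_funs].to_numpy()
    carriage = pres.mean(axis=1)
    return 1.0 + (gut_link - 1.0) * carriage


def generate_dataset(
    config: SimulationConfig,
) -> tuple[AbundanceTable, SampleMetadata, TraitTable, PhyloTree]:
    """Generate a full synthetic experiment from one config.

    One sample per source x time x replicate; host and substrate replicates
    of the same index share a plate ID (they come from the same physical
    plate in the emulated design), controls have their own plates.
    """
    seed = int(config.seed)
    taxon_ids = [f"T{i:02d}" for i in range(config.S)]
    meta = sample_metacommunity(config.S, config.metacommunity_sigma, _spawn_seed(seed, 0))
    rng = np.random.default_rng(_spawn_seed(seed, 1))
    host_fit_taxa = rng.choice(config.S, size=min(config.n_host_fit_taxa, config.S), replace=False)
    traits = generate_trait_table(
        config.S,
        config.functions_per_subsystem,
        host_fit_taxa,
        config.gut_link,
        _spawn_seed(seed, 2),
        taxon_ids=taxon_ids,
    )
    fitness = dict(config.fitness) if config.fitness is not None else {}
    if "host" not in fitness:
        fitness = {**fitness, "host": derive_host_fitness(traits, config.gut_link)}
    for src in ("control", "substrate"):
        if src not in fitness:
            fitness[src] = np.ones(config.S)
    cfg = replace(config, fitness=fitness)

    rows: list[np.ndarray] = []
    sample_ids: list[str] = []
    md_rows: list[dict] = []
    for src_i, source in enumerate(SOURCES):
        for rep in range(config.replicates):
            traj = simulate_assembly(
                meta, cfg, source, _spawn_seed(seed, 10, src_i, rep)
            )
            for t_i, t in enumerate(config.time_points_h):
                reads = sample_reads(
                    traj[t_i], config.depth, _spawn_seed(seed, 20, src_i, rep, t_i)
                )
                sid = f"{source}_t{int(t)}_r{rep:02d}"
                sample_ids.append(sid)
                rows.append(reads)
                plate = (
                    f"p{rep:02d}" if source in ("host", "substrate") else f"c{rep:02d}"
                )
                md_rows.append(
                    {
                        "sample_id": sid,
                        "source": source,
                        "time_h": float(t),
                        "replicate": f"r{rep:02d}",
                        "plate": plate,
                    }
                )
    abundance = AbundanceTable.from_arrays(
        np.vstack(rows), sample_ids, taxon_ids
    )
    metadata = SampleMetadata(pd.DataFrame(md_rows).set_index("sample_id"))
    tree = random_tree(taxon_ids, _spawn_seed(seed, 3))
    return abundance, metadata, traits, tree
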