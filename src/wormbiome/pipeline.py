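"""End-to-end pipeline: simulate/ingest -> diversity -> neutral fit ->
stochasticity -> functional profiles -> differential abundance ->
taxon contribution, as one reproducible, configured run.

A single global seed deterministically spawns per-stage seeds (via
``SeedSequence([seed, stage_index])``), so every stage can also be re-run
standalone with the same result.  Every output file carries a header
comment with the package version, the seed and a hash of the resolved
configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import (
    ValidationError,
    read_abundance_table,
    read_metadata,
    read_trait_table,
    read_tree,
    write_table,
    write_tree,
)
from .differential import nb_wald
from .diversity import (
    alpha_diversity_table,
    beta_diversity,
    diversity_trend,
    pcoa,
    permanova,
)
from .functions import function_abundance, functional_diversity, taxon_contribution
from .neutral import neutral_fit_by_group, neutral_results_frame
from .simulate import SimulationConfig, generate_dataset, _spawn_seed
from .stochasticity import nst, nst_results_frame

logger = logging.getLogger("wormbiome")

_STAGES = ("simulate", "diversity", "neutral", "nst", "functions", "diffabund")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    out_dir: str = "wormbiome_run"
    seed: int = 0
    # either simulate=True (synthetic inputs) or paths to on-disk tables
    simulate: bool = True
    simulation: Mapping[str, Any] = field(default_factory=dict)
    abundance_path: str | None = None
    metadata_path: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    stages: tuple[str, ...] = _STAGES
    beta_metrics: tuple[str, ...] = ("aitchison", "bray_curtis")
    alpha: float = 0.05
    d: float | None = None  # neutral detection threshold; None = 1/median depth
    n_null: int = 200
    n_perm: int = 999
    contrasts: tuple[tuple[str, str], ...] = (
        ("host", "control"),
        ("host", "substrate"),
        ("control", "substrate"),
    )

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        bad = set(self.stages) - set(_STAGES)
        if bad:
            raise ValidationError(f"unknown stage(s): {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "beta_metrics" in raw:
            raw["beta_metrics"] = tuple(raw["beta_metrics"])
        if "contrasts" in raw:
            raw["contrasts"] = tuple(tuple(c) for c in raw["contrasts"])
        return cls(**raw)

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, np.ndarray):
                return [float(v) for v in x]
            if isinstance(x, Mapping):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x

        d = dataclasses.asdict(self)
        d["simulation"] = clean(dict(d["simulation"]))
        d["stages"] = list(d["stages"])
        d["beta_metrics"] = list(d["beta_metrics"])
        d["contrasts"] = [list(c) for c in d["contrasts"]]
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _header(config: RunConfig) -> str:
    return (
        f"wormbiome {__version__} seed={config.seed} config={config.config_hash()}"
    )


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the enabled stages in dependency order.

    Writes per-stage TSVs under ``config.out_dir`` plus a ``report.tsv``
    summarizing alpha-diversity trends, the neutral dispersal parameter m
    per (source, time) group, the group tNST values, and differential
    feature counts per contrast.  Returns the in-memory result bundle.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hdr = _header(config)
    bundle: dict[str, Any] = {}
    report_rows: list[dict] = []

    def stage_seed(i: int) -> int:
        return _spawn_seed(config.seed, 100 + i)

    t0 = _time.time()
    # ---- inputs -----------------------------------------------------------
    if config.simulate and "simulate" in config.stages:
        sim_cfg = SimulationConfig(**{**dict(config.simulation), "seed": stage_seed(0)})
        abundance, metadata, traits, tree = generate_dataset(sim_cfg)
        write_table(abundance, out / "abundance.tsv", hdr)
        write_table(metadata, out / "metadata.tsv", hdr)
        write_table(traits, out / "traits.tsv", hdr)
        write_tree(tree, out / "tree.nwk")
        with open(out / "config_resolved.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh)
        logger.info("simulate: %d samples in %.1fs", abundance.n_samples, _time.time() - t0)
    else:
        if not (config.abundance_path and config.metadata_path):
            raise ValidationError("need abundance_path and metadata_path when not simulating")
        abundance = read_abundance_table(config.abundance_path)
        metadata = read_metadata(config.metadata_path)
        traits = read_trait_table(config.traits_path) if config.traits_path else None
        tree = read_tree(config.tree_path) if config.tree_path else None
    metadata = metadata.subset(abundance.sample_ids)
    bundle.update(abundance=abundance, metadata=metadata, traits=traits, tree=tree)

    # ---- diversity --------------------------------------------------------
    if "diversity" in config.stages:
        t = _time.time()
        alpha = alpha_diversity_table(abundance)
        write_table(alpha, out / "alpha.tsv", hdr)
        bundle["alpha"] = alpha
        sh = alpha[alpha["metric"] == "shannon"].set_index("sample_id")["value"]
        for source in sorted(set(metadata.source)):
            ids = [s for s in abundance.sample_ids if metadata.source[s] == source]
            trend = diversity_trend(
                sh.loc[ids].to_numpy(), metadata.time_h.loc[ids].to_numpy()
            )
            report_rows.append(
                {
                    "section": "alpha_trend",
                    "group": source,
                    "quantity": "spearman_rho_shannon_vs_time",
                    "value": trend.rho,
                    "extra": f"p={trend.p_value:.3g}",
                }
            )
        dms = {}
        for metric in config.beta_metrics:
            dm = beta_diversity(abundance, metric, tree=tree)
            write_table(dm, out / f"dist_{metric}.tsv", hdr)
            dms[metric] = dm
            coords, eigvals = pcoa(dm, k=min(3, dm.n_samples - 1))
            write_table(coords, out / f"pcoa_{metric}.tsv", hdr)
            perm = permanova(
                dm, metadata.source.to_numpy(), n_perm=config.n_perm, seed=stage_seed(1)
            )
            report_rows.append(
                {
                    "section": "permanova",
                    "group": metric,
                    "quantity": "p_value_by_source",
                    "value": perm.p_value,
                    "extra": f"pseudo_F={perm.pseudo_f:.3g}",
                }
            )
        bundle["distances"] = dms
        logger.info("diversity: %d metrics in %.1fs", len(dms), _time.time() - t)

    # ---- neutral model ----------------------------------------------------
    if "neutral" in config.stages:
        t = _time.time()
        fits = neutral_fit_by_group(
            abundance, metadata, d=config.d, n_boot=0, seed=stage_seed(2)
        )
        frame = neutral_results_frame(fits)
        write_table(frame, out / "neutral.tsv", hdr)
        bundle["neutral"] = fits
        for _, row in frame.iterrows():
            report_rows.append(
                {
                    "section": "neutral_m",
                    "group": f"{row['source']}@{row['time_h']:g}h",
                    "quantity": "dispersal_m",
                    "value": row["m"],
                    "extra": f"R2={row['r_squared']:.3g}",
                }
            )
        logger.info("neutral: %d fits in %.1fs", len(fits), _time.time() - t)

    # ---- stochasticity ----------------------------------------------------
    if "nst" in config.stages:
        t = _time.time()
        md = metadata.to_dataframe()
        labels = [
            f"{md.at[s, 'source']}@{md.at[s, 'time_h']:g}h" for s in abundance.sample_ids
        ]
        nst_res = nst(
            abundance,
            labels,
            metric="bray_curtis",
            n_null=config.n_null,
            seed=stage_seed(3),
        )
        frame = nst_results_frame(nst_res)
        write_table(frame, out / "nst.tsv", hdr)
        bundle["nst"] = nst_res
        for r in nst_res:
            report_rows.append(
                {
                    "section": "tnst",
                    "group": r.group,
                    "quantity": "group_tNST",
                    "value": r.group_nst,
                    "extra": f"n_pairs={len(r.pairs)}",
                }
            )
        logger.info("nst: %d groups in %.1fs", len(nst_res), _time.time() - t)

    # ---- functional profiles ----------------------------------------------
    F = None
    if "functions" in config.stages and traits is not None:
        t = _time.time()
        F = function_abundance(abundance, traits)
        write_table(F.values, out / "functions.tsv", hdr)
        fd = functional_diversity(F)
        write_table(fd.to_frame(), out / "functional_alpha.tsv", hdr)
        contrib = taxon_contribution(abundance, F, seed=stage_seed(4))
        write_table(contrib.subsystem_summary, out / "contributions.tsv", hdr)
        bundle.update(function_abundance=F, contribution=contrib)
        logger.info("functions: %d functions in %.1fs", len(F.function_ids), _time.time() - t)

    # ---- differential abundance -------------------------------------------
    if "diffabund" in config.stages:
        t = _time.time()
        targets = {"taxa": abundance.to_dataframe().T}
        if F is not None:
            targets["functions"] = F.values.T
        for what, counts in targets.items():
            for contrast in config.contrasts:
                res = nb_wald(counts, metadata, contrast=tuple(contrast))
                name = f"diff_{what}_{contrast[0]}_vs_{contrast[1]}.tsv"
                write_table(res.table, out / name, hdr)
                sig = res.table[
                    (res.table["padj"] <= config.alpha) & res.table["padj"].notna()
                ]
                report_rows.append(
                    {
                        "section": "differential",
                        "group": f"{what}:{contrast[0]}_vs_{contrast[1]}",
                        "quantity": f"n_significant_padj<={config.alpha:g}",
                        "value": float(len(sig)),
                        "extra": f"n_tested={len(res.table)}",
                    }
                )
                if what == "functions" and F is not None:
                    for sub in sorted(set(F.subsystem.values())):
                        in_sub = sig["feature"].map(F.subsystem.get) == sub
                        report_rows.append(
                            {
                                "section": "differential_by_subsystem",
                                "group": f"{sub}:{contrast[0]}_vs_{contrast[1]}",
                                "quantity": f"n_significant_padj<={config.alpha:g}",
                                "value": float(in_sub.sum()),
                                "extra": "",
                            }
                        )
                bundle[f"diff_{what}_{contrast[0]}_vs_{contrast[1]}"] = res
        logger.info("diffabund done in %.1fs", _time.time() - t)

    report = pd.DataFrame(report_rows)
    write_table(report, out / "report.tsv", hdr)
    bundle["report"] = report
    logger.info("pipeline finished in %.1fs", _time.time() - t0)
    return bundle
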