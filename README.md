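# wormbiome

Assembly dynamics, stochasticity, and trait-based functional profiling for
time-resolved defined microbial communities — built for host-colonization
experiments in which the same species pool is tracked across three
compartments (worm-free **control** plates, the worm-associated
**substrate** lawn, and the **host** animals) over the host's lifetime.

Given a sample × taxon count table, per-sample metadata and a binary
taxon × function trait table, the package answers, with one reproducible
pipeline:

* **How do the communities change?** α-diversity (Shannon, Simpson,
  bias-corrected Chao1), β-diversity (Bray–Curtis, Aitchison/CLR,
  normalized weighted UniFrac), PCoA ordination, PERMANOVA, paired
  between-source distance trends, Spearman time trends, ANOVA/Tukey.
* **How stochastic is assembly?** A Sloan-style neutral-model fit of the
  occurrence curve `F(p) = 1 − I_d(Nm·p, Nm(1−p))` per (source, time)
  group, yielding the dispersal number `Nm`, the dispersal probability
  `m = Nm/N` and a goodness-of-fit R²; plus the taxonomic normalized
  stochasticity ratio (tNST) against a richness-fixed,
  occupancy-proportional ("PF") null model, with pair-level bootstrap
  group comparisons.  tNST > 0.5 reads as stochasticity-dominated,
  < 0.5 as determinism-dominated.
* **What do the selected taxa do?** Trait-table projection of abundances
  into functional profiles over eight subsystems (cazyme, exchange, gut,
  interactions, medium, metabolism, uast, virulence), functional
  diversity, negative-binomial Wald tests for differentially abundant
  taxa/functions (median-of-ratios size factors, Cox–Reid dispersion,
  Benjamini–Hochberg), and cross-validated ridge attribution of functions
  to taxa.

A fully seeded synthetic-community generator (Moran birth–death dynamics
with immigration and optional selection, multinomial sequencing, trait
tables with gut-function enrichment in host-adapted taxa) emulates the
experimental design — 43 taxa, 3 sources × 6 time points × 10 replicates
= 180 samples — so the entire pipeline is testable without any downloads.
See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from wormbiome import (
    SimulationConfig, generate_dataset, beta_diversity, permanova,
    neutral_fit_by_group, neutral_results_frame, nst, function_abundance,
    nb_wald,
)

ab, md, traits, tree = generate_dataset(SimulationConfig(seed=3))

dm = beta_diversity(ab, "aitchison")
print(permanova(dm, md.source.to_numpy(), n_perm=499, seed=1))
# PermanovaResult(pseudo_f=45.12, p_value=0.002, n_permutations=499, exhaustive=False)

fits = neutral_fit_by_group(ab, md)
print(neutral_results_frame(fits)[["source", "time_h", "m", "r_squared"]].head(3))
#     source  time_h         m  r_squared
# 0  control    16.0  1.000000        NaN
# 1  control    42.0  0.042297   0.935555
# 2  control    66.0  0.108071   0.872271

labels = [f"{md.source[s]}@{md.time_h[s]:g}" for s in ab.sample_ids]
res = nst(ab, labels, metric="bray_curtis", n_null=100, seed=2)
print({r.group: round(r.group_nst, 2) for r in res if r.group.startswith("host")})
# {'host@16': 0.94, 'host@42': 0.93, 'host@66': 0.91,
#  'host@90': 0.53, 'host@138': 0.72, 'host@186': 0.72}

F = function_abundance(ab, traits)
diff = nb_wald(F.values.T, md, contrast=("host", "control"))
gut = [f for f in F.function_ids if F.subsystem[f] == "gut"]
tab = diff.table.set_index("feature")
print(int(((tab.loc[gut, "padj"] <= 0.05) & (tab.loc[gut, "log2FC"] > 0)).sum()), "of", len(gut))
# 9 of 10
```

Reading the output: the three sources differ significantly in composition
(PERMANOVA p = 0.002); the neutral occurrence curve fits most groups well
(R² ≈ 0.87–0.94; the first time point is degenerate because every taxon is
still present everywhere, so R² is flagged NaN); host communities drop
toward deterministic tNST values after 90 h while staying near 0.9 in the
worm-free controls; and 9 of 10 gut-subsystem functions are significantly
enriched in hosts versus controls, while the identically-assembled
control/substrate contrast yields none.

## Command line

```sh
wormbiome simulate --seed 1 --out data/
wormbiome diversity --abundance data/abundance.tsv --metadata data/metadata.tsv --out div/
wormbiome neutral   --abundance data/abundance.tsv --metadata data/metadata.tsv --out neutral.tsv
wormbiome nst       --abundance data/abundance.tsv --metadata data/metadata.tsv --metric bray_curtis --out nst.tsv
wormbiome functions --abundance data/abundance.tsv --traits data/traits.tsv --out fun/
wormbiome diffabund --counts fun/functions.tsv --metadata data/metadata.tsv --contrast host,control --out diff.tsv
wormbiome pipeline  --config run.yaml          # everything, one seed, one report
```

Every output TSV carries a header comment with the package version, seed
and config hash; identical config + seed reruns are byte-identical.

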