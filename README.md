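# sector5

Five-sector resource-allocation partition of genome-wide expression,
with the genetic and epigenetic analyses that quantify how specific
regulation deviates genes from the global growth program.

## The problem

The cell's expression machinery (polymerases, ribosomes, cofactors) is
limited, so expression is a resource-allocation problem: as growth
conditions change, some genes gain fractional expression at the cost of
others. Two classic partitions describe this — a three-sector split by
growth response (positive / invariant / negative) and a two-sector
split by condition specificity (nonspecific / specific). `sector5`
implements their integration: a **five-sector** genome partition —
*repressed, negative, invariant, positive, activated* — and the
downstream machinery for asking which transcription factors (TFs) and
chromatin modifiers drive each sector away from the global program.

It is aimed at computational biologists working with growth-series
expression designs (chemostat series over several limiting nutrients,
promoter-activity libraries over growth conditions) and regulatory
networks in budding yeast or comparable systems.

## The model

Within one nutrient, fractional expression
`f_i = log10(1e6 · g_i / Σ_j g_j)` across growth rates `μ` is
approximated by the top two SVD components,

    f_i(μ) ≈ a_i · v1(μ) + b_i · v2(μ),

with `v1` the baseline direction and `v2` the monotone growth
direction. A gene is **nonspecific** when its baseline loading `a_i` is
conserved (within 3 SD of all gene differences) in ≥ 9 of the 15
nutrient pairs, else **specific**. Per nutrient, the genes with
smallest `|b_i|` (a fixed quota) are **invariant**, the rest positive
or negative by `sign(b_i)`; majority votes over nutrients assign
nonspecific genes to *invariant* / *positive* / *negative* and specific
genes to *activated* / *repressed*. Downstream analyses score each
sector against gene-label randomization nulls (10000-fold, ±2 SD
bands): regulators per gene, **regulatory coherence** (mean Pearson
correlation between a target's growth profile and its regulators', with
a profile-permutation null and one-sided z > 2 calls), TF–sector
enrichment, promoter-feature enrichment, chromatin-modifier strength
and signed effects (activator / dual / repressor classification), and
removal of the slow-growth expression signature by orthogonal
projection.

A synthetic-data generator plants ground truth for every input —
expression with rank-2 per-nutrient structure, coherently wired
networks, effect-patterned modifier compendia, promoter-activity
tables, score tracks and a slow-growth reference — so each stage is
verifiable end to end without external downloads.

## Worked example

```python
import sector5 as s5

cfg = s5.SimulationConfig(n_genes=2000, n_tfs=120, seed=0)
dataset, truth = s5.generate_expression(cfg)
network = s5.generate_network(cfg, truth)

est = s5.FiveSectorPartitioner(n_invariant=cfg.n_invariant_planted)
est.fit(dataset.raw, dataset.samples)
print("sector counts:", est.partition_.sector_counts().to_dict())
print("recovered planted labels:", f"{(est.labels_ == truth.sector).mean():.1%}")

frac = s5.fractional_expression(dataset.raw)
coh = s5.coherence_null(frac, dataset.samples, network, "glucose", n=1000, seed=0)
print("significantly coherent targets (z > 2):", int(coh["significant"].sum()),
      "of", len(coh))

summ, ks = s5.regulators_per_sector(network, est.partition_, n=2000, seed=0)
row = ks.iloc[0]
print(f"mean regulators, specific vs nonspecific: "
      f"{row['mean_a']:.2f} vs {row['mean_b']:.2f} (KS p = {row['ks_p']:.2e})")
```

prints

```
sector counts: {'repressed': 22, 'negative': 800, 'invariant': 559, 'positive': 612, 'activated': 7}
recovered planted labels: 100.0%
significantly coherent targets (z > 2): 744 of 2000
mean regulators, specific vs nonspecific: 4.93 vs 3.04 (KS p = 4.47e-06)
```

The sector counts follow the planted proportions (negative and positive
genes dominate the nonspecific bulk; specific genes are rare); every
planted label is recovered at the default noise level. 744 of 2000
targets are significantly coherent — the generator wires ~30% of
growth-responsive targets coherently, and with strong shared growth
structure some randomly wired targets are genuinely coherent too.
Specific genes carry ~1.9 more regulators on average than nonspecific
ones, and the KS test confirms the in-degree distributions differ.

A command-line interface mirrors the stages:

```sh
sector5 simulate --n-genes 2000 --seed 0 --outdir synthetic
sector5 partition-svd --expr synthetic/expression.tsv --meta synthetic/samples.tsv --n-invariant 559
sector5 regulate --expr synthetic/expression.tsv --meta synthetic/samples.tsv \
    --network synthetic/network.tsv --partition partition.tsv
sector5 chromatin --partition partition.tsv --compendium synthetic/compendium.tsv \
    --classes synthetic/modifier_classes.tsv
```

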