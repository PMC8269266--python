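# ecoassembly

Inference of microbial community assembly processes from OTU tables, for
microbial ecologists working with amplicon surveys (the motivating system is
archaeal 16S data from mangrove sediment cores sampled along a latitudinal
gradient, but nothing in the package is specific to that system).

The package answers the questions an assembly study asks of a taxa × samples
count table, a phylogeny, and sample metadata:

- **How neutral is the community?** Sloan's neutral community model predicts
  a taxon's detection frequency across samples from its mean relative
  abundance *p* via the immigration rate *m*:
  `freq(p) = 1 − B(d; N·m·p, N·m·(1−p))`, with *N* the reads per sample,
  *d* the detection limit, and *B* the regularized incomplete beta CDF.
  `SloanNCM(counts).fit()` estimates *Nm* by bounded least squares, reports a
  generalized *R²*, and partitions taxa against 95% Wilson bands
  (above / within / below the neutral expectation).
- **Which processes dominate pairwise turnover?** Abundance-weighted βMNTD
  and its standardized effect size βNTI (tip-shuffling null), plus the
  Bray-Curtis Raup-Crick metric RC_bray (probabilistic assembly null),
  classify every sample pair: βNTI < −2 homogeneous selection, βNTI > 2
  heterogeneous selection, and for |βNTI| ≤ 2, RC_bray > 0.95 dispersal
  limitation, < −0.95 homogenizing dispersal, otherwise undominated.
- **Which taxa are core to the interaction structure?** A co-occurrence
  network from pairwise maximal information coefficients (MIC, implemented
  from the classic grid-search algorithm) with permutation FDR, edge signs
  from Spearman ρ, Louvain modules, and keystoneness = mean of min-max-scaled
  degree, (1 − betweenness), and closeness.
- Supporting statistics: rarefaction, dominant / conditionally-rare /
  always-rare classification (0.01% and 1% per-sample cutoffs), alpha
  diversity (richness, Shannon H′, Chao1, Pielou J), Hellinger + Bray-Curtis
  distances, PCoA, PERMANOVA, ANOSIM, Mantel tests, great-circle distances,
  distance-decay regression, and Spearman environment correlations.

A synthetic survey generator (`ecoassembly.synthetic`) emulates the study
design the analyses assume — 7 locations along a coastline, 6–7 sites each,
3 depth layers, read depths in 19,206–43,750 — with a Yule phylogeny,
Brownian trait optima, and tunable neutral / selection / dispersal-limited
regimes, so every stage can be validated against a known ground truth.

## Worked example

```python
import dataclasses
import ecoassembly as ea

# a 300-taxon regional pool and the 129-sample survey design, all neutral
model = ea.MetacommunityModel.simulate(n_taxa=300, seed=42)
design = dataclasses.replace(ea.default_design(), depth_range=(19206, 19206))
counts, meta, tree = ea.simulate_dataset(
    design, model, ea.RegimeSpec("neutral", m=0.3), seed=42
)

fit = ea.SloanNCM(counts).fit()
print(fit.summary())

classes = ea.classify_taxa(ea.relative_abundance(counts))
print("class counts:", classes.counts())

r, p, slope = ea.distance_decay(
    counts, meta["latitude"], meta["longitude"], n_perm=999, seed=1
)
print(f"distance decay: r={r:.3f}, p={p:.4g}")
```

prints

```
Sloan neutral community model fit
======================================
samples                       129
taxa                          300
reads per sample (N)      19206.0
Nm                        5000.53
immigration rate m         0.2604
R-squared                  0.9576
above / within / below   144   156     0
class counts: {'dominant': 244, 'conditionally_rare': 56, 'always_rare': 0}
distance decay: r=-0.004, p=0.92
```

The fitted immigration rate (0.26) recovers the simulated one (0.3); the
high *R²* says occurrence frequencies sit on the neutral curve; and there is
no distance decay (p = 0.92), as expected when dispersal is global. Note
that *m* is defined relative to the reads per sample: if depths vary and the
table is rarefied, *Nm* reflects the native community size while *m* divides
by the rarefaction depth.

Under a selection regime with identical environments the same machinery
yields a median βNTI below −2 and homogeneous selection as the modal
process; under divergent environments, between-block pairs flip to βNTI > 2
(see `scripts/acceptance.py` and the test suite).

## Command line

Every stage is also a subcommand of a single executable:

```bash
ecoassembly simulate --regime selection --m 0.01 --selection-strength 0.5 \
    --n-taxa 300 --seed 1 --out-prefix sim
ecoassembly classify sim.counts.tsv --depth 19206 --out classes.tsv
ecoassembly ncm rarefied.tsv --out-prefix ncm
ecoassembly processes rarefied.tsv sim.tree.nwk --metadata sim.metadata.tsv \
    --group-by location --out-prefix proc
ecoassembly network rarefied.tsv --out-prefix net
ecoassembly run --config pipeline.yaml --out results/
```

`run` executes the full flow (rarefy → classify → α/β diversity → NCM →
βNTI/RC_bray → process partition → network) from a YAML config, writes TSV
and JSON outputs plus a manifest with per-stage seeds and digests, and is
byte-reproducible for a fixed config.

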