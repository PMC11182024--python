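# cryonet

**Soil microbiome communities, co-occurrence networks and soil quality for
freeze–thaw microcosm experiments.**

Agricultural soils in cold regions cycle through freezing and thawing every
winter, and practices such as maize residue retention reshape the soil
microbiome under exactly those conditions. Studies of this kind share one
analysis skeleton: a factorial microcosm (residue treatment × freeze–thaw
intensity × number of cycles × replicates), rarefied ASV count tables per
organism group, and a chain of downstream statistics. `cryonet` implements
that chain as one reusable, tested Python pipeline:

* **community** — richness, Bray–Curtis dissimilarity, principal-coordinates
  analysis, one-way and sequential factorial PERMANOVA, Mantel tests
  (seeded permutations, exhaustive enumeration for tiny designs);
* **assembly** — the normalized stochasticity ratio (NST): a null model that
  preserves per-sample richness and draws occupants by occurrence frequency,
  with per-pair NST = (1−G)/(1−E) for G ≥ E else G/E on Ruzicka
  dissimilarities, group means reported in percent (> 50 % ⇒
  stochastic-dominated assembly);
* **network** — Spearman co-occurrence networks (edges at |ρ| ≥ 0.6 and
  BH-adjusted p ≤ 0.01), greedy-modularity modules, Guimerà–Amaral Zi/Pi
  node roles with the Zi > 2.5 / Pi > 0.625 keystone rule, robustness under
  random node removal, connectedness, positive/negative link ratio, and
  per-treatment subnetworks;
* **soilquality** — the composite soil quality index (mean of z-scores of
  13 chemical, enzymatic and respiration variables) and random-forest
  feature importance (%IncMSE with out-of-bag bookkeeping and
  permuted-target significance) linking network modules and diversity to
  quality;
* **synthetic** — a generator for the full 96-sample factorial design with
  planted correlation modules, a copiotroph/oligotroph residue response, a
  competing-guild pair (negative links), a deterministic-assembly shift and
  a module → soil-quality pathway, so every downstream claim can be checked
  against known ground truth;
* **cli / pipeline** — a config-driven `cryonet` command that runs the whole
  analysis with a manifest and byte-reproducible outputs.

See `docs/methods.md` for the models, conventions and parameter defaults.

## Worked example

Generate a synthetic 96-sample microcosm at the default study conditions and
run the main stages:

```python
from cryonet import assembly, community, network, soilquality, synthetic, tables

design = synthetic.generate_design(synthetic.DesignSpec())          # 96 samples
table, truth = synthetic.generate_community(design, synthetic.CommunityParams(), seed=7)
soil = synthetic.generate_soil_properties(
    design, seed=8, mediator=synthetic.module_mediator(table, truth, design))

graph = network.build_cooccurrence_network(tables.prevalence_filter(table))
modules = network.detect_modules(graph)
nst = assembly.pairwise_nst(table, design["residue"],
                            assembly.NullModelSpec(n_draws=200, seed=0))
quality = soilquality.quality_index(soil)
```

Printed results (seed 7):

```
network: 498 nodes, 2793 edges (2274 +, 519 -), modularity 0.516
P/N ratio 4.38, connectedness 0.0279, robustness 0.163
NST: CK 41.1%  RR 31.9%  (Welch t = 22.5, p = 1e-100)
soil quality: CK -0.167  RR +0.167  (p = 4e-06)
planted residue-enriched module detected as Module_2 (size 30)
ARI vs planted modules: 1.00
forest OOB variance explained: 44%
Module_2              66.2
Module_4               6.9
Module_1               4.4
Module_3               1.9
community_richness    -3.6
```

Reading the numbers: residue retention (RR) lowers the stochasticity ratio
by ~9 points — assembly becomes more deterministic under residue amendment —
and raises the composite soil quality index (Welch t-test, p ≈ 4×10⁻⁶).
Module detection recovers the four planted modules exactly (adjusted Rand
index 1.0); the residue-enriched planted module (detected as Module_2, its
id assigned by size rank) dominates the random-forest importance for soil
quality (%IncMSE 66) while community richness contributes nothing — the
network-module signal, not diversity, carries the soil-function information,
as designed into the generator's module → quality pathway.

The same analysis from the shell:

```bash
cryonet run --synthetic --seed 7 --outdir out/
cryonet simulate --seed 1 --outdir data/          # just the dataset
cryonet network --table data/asv_table.tsv --outdir out/net/
```

`run` writes every artifact (metadata, counts, distance matrices,
PERMANOVA table, per-group NST, edge list, modules, Zi/Pi topology, network
metrics, quality index, feature importances) as tab-separated or JSON files
plus a `manifest.json` with SHA-256 digests; identical config + seed
reproduces identical bytes.

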