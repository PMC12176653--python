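# morphomap

Quantitative morphometry and phenotype mapping for single-cell-derived
**branched organoids** (pancreatic-cancer organoids grown in floating
collagen gels).  These cultures produce a striking spread of
morphologies — epithelial families such as the terminal-end-bud
branching organoid (TEBBO), cystic branched, thick branched and
tree-like forms, and mesenchymal families such as branched mesenchymal,
firework and star-like organoids — and the shape an organoid takes
carries biological information about EMT state, clonogenic potency and
drug response.  `morphomap` turns brightfield images and the assays
around them into numbers, for computational biologists who want every
step scripted, seeded and testable:

* **Skeleton-graph morphometry** (`morphomap.morphometry`): segment a
  dark-phase organoid, thin it to a skeleton graph, and read off the
  descriptors usually collected by hand in ImageJ — major axis length,
  core-branch thickness, main branches, branch points (nodes),
  endpoints, terminal end buds, spiky invasive branches, micro-lumen
  count and area, core circularity, granularity — plus a fixed-order
  rule list that assigns the phenotype family.
* **Phenotype mapping** (`morphomap.profiling`): per-organoid feature
  matrices (classical descriptors or the penultimate layer of a small
  CNN trained on a surrogate line-identity task), PCA + t-SNE
  embedding, elbow-selected k-means clusters, per-group kernel-density
  overlays, phenotype-composition shifts between treatment arms
  (Jensen–Shannon divergence + chi-square), and dose-response
  summaries (AUC, GI50, per-drug z-scores).
* **Limiting-dilution potency** (`morphomap.elda`): the single-hit
  Poisson model `P(well negative | dose d) = exp(-f d)`, fitted as a
  binomial GLM with complementary log-log link and log-dose offset;
  potency is reported as "1 in x cells" with Wald or profile CIs and a
  likelihood-ratio test of the single-hit assumption.
* **Phenotype gene signatures** (`morphomap.signatures`): one-vs-rest
  negative-binomial Wald tests with median-of-ratios size factors and
  gene-wise Cox–Reid dispersions, signature membership at BH-adjusted
  p < 0.05 and log2 fold change > 2 with shared genes removed, and
  rank-based recovery-curve AUC activity scores in [0, 1].
* **Synthetic ground truth** (`morphomap.synth`): seeded generators for
  every input — organoid images rendered from explicit geometry (so
  every descriptor has an exact known value), limiting-dilution well
  tables, NB count matrices with planted marker genes, and 7-point
  3-fold dose-response curves.  They make every stage of the pipeline
  verifiable without any microscope.

## Worked example

Estimate organoid-forming potency from a 4-density limiting-dilution
assay (`examples/limiting_dilution.py`):

```python
from morphomap.elda import fit_single_hit
from morphomap.synth import generate_limiting_dilution

table = generate_limiting_dilution(true_frequency=1/3,
                                   doses=(20, 10, 3, 1),
                                   wells_per_dose=8, seed=7)
est = fit_single_hit(table, ci="wald")
```

```
 dose  tested  responding
   20       8           8
   10       8           7
    3       8           4
    1       8           1

potency 1/4.66  (95% CI 1/8.19 - 1/2.66)
single-hit slope test p = 0.66
```

One in ~4.7 seeded cells founded an organoid in this simulated assay
(truth: 1 in 3; eight wells per density leave a wide CI, which the
interval honestly reflects), and the slope test finds no evidence
against single-hit kinetics.

Measuring a rendered TEBBO organoid
(`examples/render_and_measure.py`) recovers the generator's geometry:

```
phenotype truth='TEBBO'  predicted='TEBBO' (margin 3)
descriptor                        truth   measured
major_axis_um                     732.5      734.1
n_nodes                             6.0        6.0
n_endpoints                         8.0        8.0
n_terminal_end_buds                 5.0        5.0
```

Branch points and endpoints are exact; lengths agree to rasterization
error.  The other scripts in `examples/` walk through the mapping chain
(`phenotype_map.py`), signature derivation and scoring
(`signatures_demo.py`), drug-response summaries (`drug_response.py`)
and CNN extractor training (`train_extractor.py`).

A thin CLI mirrors the library for shell use:
`morphomap synth images|wells|counts|doseresponse`, `morphomap measure`,
`morphomap elda`, `morphomap features|embed|cluster|overlay|shift|drugs`
and `morphomap signatures derive|score`.

## Layout

```
src/morphomap/
  archetypes.py      phenotype families and their geometric parameters
  synth/             image / wells / counts / dose-response generators
  morphometry/       segment -> skeleton graph -> measure -> classify
  profiling/         features, embedding, clustering, densities, drugs, CNN
  elda.py            single-hit potency estimation
  signatures.py      NB differential expression + signature scoring
  pipeline.py        cohort-level conveniences
  cli.py             thin command-line layer
```
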