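# rhizopart

Attribution of soil microbial community variation to plant species identity,
soil chemistry, spatial location and plant phylogeny.

## The problem

Soil bacteria and fungi sampled from the root zones of wild plants vary from
sample to sample, and several explanations compete: plants may cultivate
species-specific microbial communities (e.g. via root exudates), microbes may
track soil chemistry niches, dispersal limitation may make nearby communities
similar ("everything" is *not* "everywhere"), and closely related plants may
host similar communities if relevant traits are phylogenetically conserved.
`rhizopart` implements the full statistical chain used to weigh these
explanations against each other in a paired-congener field design (7 plant
genera × 2 species × 6 collection locations, two DNA fingerprinting
subsamples per soil sample):

1. **Ordination** — rare-OTU filtering (presence in ≤ 7 % of subsamples),
   subsample averaging, Bray–Curtis dissimilarities
   (`1 − 2Σmin/(ΣA+ΣB)`), and non-metric multidimensional scaling (Kruskal
   stress-1, isotonic regression + SMACOF, 20 starts), keeping the smallest
   dimensionality with stress < 0.20.  A permutation matrix-regression test
   reports how much community structure the retained axes represent.
2. **Eigenvector predictors** — phylogenetic eigenvector regression (PVR):
   PCoA (Gower centering, `−½·C·D²·C`) of the patristic distance matrix,
   first seven axes screened, values broadcast from species to samples; two
   spatial eigenvectors from PCoA of the geographic distance matrix;
   standardized soil chemistry.
3. **Per-axis linear models** — each ordination axis against each predictor
   class separately (species and genus factors, AIC-selected chemistry,
   spatial eigenvectors, P < 0.05-retained phylogenetic eigenvectors), with
   exact F class tests, likelihood-ratio tests, and VIF diagnostics.
   Phylogeny and chemistry are never mixed in one model.
4. **Variance partitioning** — adjusted-R² inclusion–exclusion over the
   seven subset models of {phylogeny, chemistry, space}: three unique,
   three pairwise-shared, one three-way fraction plus residual, summing to
   one per axis.

A synthetic-study generator with independently controllable signal channels
(species / chemistry / space / phylogeny weights) stands in for field data,
so every stage is verifiable by parameter recovery.  See `docs/methods.md`
for the model details and design choices.

## Worked example

Generate a synthetic two-community study and analyse it:

```bash
rhizopart simulate --out demo/data --seed 0
rhizopart -v analyze \
    --otu-table bacterial=demo/data/bacterial_otus.tsv \
    --otu-table fungal=demo/data/fungal_otus.tsv \
    --metadata demo/data/metadata.tsv \
    --chemistry demo/data/chemistry.tsv \
    --tree demo/data/tree.nwk \
    --out demo/results --seed 0
```

which prints (numbers from this exact invocation):

```
bacterial: k=4 stress=0.181 fit=57.5% (p=0.000999)
fungal: k=4 stress=0.174 fit=59.9% (p=0.000999)
```

i.e. both communities need four ordination axes to bring stress under the
0.20 ceiling; those four axes jointly represent ~58–60 % of the Bray–Curtis
structure, and the permutation test (1000 shuffles) puts that fit far
outside chance.  `demo/results/` then contains, per community, the stress
profile, ordination scores, the per-axis × per-class results grid
(`*_results_table.txt`, adjusted R² with class p-values; entries below 0.01
shown as `<0.01`, significant cells starred), the variance-partition table,
plots, and a JSON manifest with seeds, timings and derived counts.  The
bacterial grid of that run:

```
bacterial
  predictor                 MDS1              MDS2              MDS3              MDS4
  species        0.29 (P=0.000)*   0.17 (P=0.013)*   0.57 (P=0.000)*   0.05 (P=0.212)
  chemistry      0.19 (P=0.005)*   0.29 (P=0.000)*  <0.01 (P=0.948)    0.10 (P=0.167)
  space         <0.01 (P=0.757)   <0.01 (P=0.293)   <0.01 (P=0.731)    0.08 (P=0.014)*
  phylogeny     <0.01 (P=0.801)   <0.01 (P=0.490)    0.12 (P=0.051)   <0.01 (P=0.595)
  genus         <0.01 (P=0.718)   <0.01 (P=0.557)    0.10 (P=0.032)*  <0.01 (P=0.614)
```

Plant species identity is the strongest predictor on three of the four axes,
soil chemistry second, spatial location and plant relatedness weaker — the
qualitative ranking the synthetic defaults are calibrated to produce.

The same machinery is scriptable from Python (`rhizopart.run_analysis`,
`rhizopart.simulate_study`), and `rhizopart benchmark` measures per-class
power and false-positive rates over signal-weight scenarios.

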