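# Methods

`rhizopart` implements the inference chain used to ask how much of the
variation in soil microbial communities sampled from plant root zones can be
attributed to four competing explanations: the identity of the plant species
above the sample, the chemistry of the soil, the geographic position of the
sample, and the evolutionary relatedness of the plants.  This note documents
the statistical procedures, the synthetic testbed, the numerical choices, and
the limits of what the tests demonstrate.

## The inference chain

**Ordination.**  Community profiles (relative TRFLP peak areas per OTU) are
filtered — an OTU present in at most 7 % of DNA subsamples is removed, with
presence meaning abundance strictly greater than zero and the comparison made
before subsample averaging — then averaged across the two subsamples of each
soil sample, and converted to a Bray–Curtis dissimilarity matrix,
`D_ij = 1 − 2·Σ_k min(x_ik, x_jk) / (Σ_k x_ik + Σ_k x_jk)`.  Non-metric
multidimensional scaling embeds the samples in k dimensions by minimizing
Kruskal stress-1 with alternating isotonic regression (primary approach to
ties) and SMACOF majorization; 20 starts are used (one principal-coordinates
start, 19 random) and the dimensionality chosen is the smallest k with stress
below 0.20, scanned up to k = 6.  How much community structure the retained
axes represent is assessed by matrix regression of the Bray–Curtis entries on
the Euclidean inter-sample distances in ordination space, with a permutation
p-value (1000 simultaneous row/column shuffles of the response matrix).  The
literature sometimes labels this a partial Mantel test; only two matrices
enter here, so it is plain two-matrix regression, though the implementation
accepts the general case.

**Eigenvector predictors.**  Because species identity, chemistry, space and
phylogeny live on different supports, all four are expressed as sample-level
regression designs.  Phylogenetic predictors come from phylogenetic
eigenvector regression: the patristic distance matrix of the 14-species tree
is Gower-centred (`G = −½·C·(D∘D)·C`) and eigendecomposed; the first seven
axes (scaled by √eigenvalue) are screened, and each species' values are
broadcast to its samples.  Negative eigenvalues are reported but their axes
discarded, with no Lingoes/Cailliez correction — standard practice when the
leading positive axes are used as predictors.  The fixed screening depth of
seven mimics the reference analysis' scree-plot reading; an automated
largest-drop rule (`scree_break`) is available as an alternative.  Spatial
predictors are the two leading PCoA axes of the Euclidean distance matrix of
the planar site coordinates; for planar input these span exactly the centred
(x, y) plane.  Chemistry enters as ten column-standardized assays
(z-scores), since ppm, meq/100 g and pH are incommensurable.

**Per-axis class models.**  Each ordination axis is regressed on one
predictor class at a time: species (13 factor contrasts), genus (6
contrasts), chemistry, space, phylogeny.  Two classes undergo selection
before their adjusted R² is reported: chemistry by bidirectional stepwise
AIC from the full ten-variable model followed by removal of remaining terms
with p ≥ 0.05 (worst first, refitting after each drop), and phylogeny by
retaining the eigenvectors with coefficient p < 0.05 in the joint fit of
seven phylogenetic plus two spatial eigenvectors.  An empty selected set
reports adjusted R² = 0.  The class *p-value*, however, is the exact overall
F-test of the full, pre-selection class design against intercept-only.  A
likelihood-ratio test of the selected subset is also emitted for reference,
but it is not the headline p: a selected subset's LRT against the null is
strongly anti-conservative (any procedure that keeps terms because they look
significant and then asks whether they are significant rejects far above
α under the null), and the package's Monte-Carlo calibration requires the
reported class test to hold its size.  Phylogenetic eigenvectors and
chemistry never appear in one inference model: at species level they are
near-collinear in field data and the two hypotheses are tested separately.
Variance inflation factors (1/(1−R²) of each predictor on the rest) are
available for any design; perfect collinearity reports +inf.

**Variance partitioning.**  The explained variance of each axis is split
among phylogeny (retained eigenvectors), chemistry (AIC-selected subset) and
space (two eigenvectors) by fitting the seven non-empty subset models and
combining adjusted R² values by inclusion–exclusion into three unique, three
pairwise-shared, one three-way-shared and one residual fraction.  Adjusted
R² is used because the sets have different sizes; shared fractions can
therefore be negative (suppression) and are reported unclipped.  The eight
fractions sum to one by construction.  Species identity is not a fourth set:
at species level it is perfectly collinear with the phylogenetic
eigenvectors.  Partitioning is per axis; a joint multi-axis summary would
average per-axis fits and is deliberately not the default.

## The synthetic testbed

The generator reproduces the reference design: 7 genera × 2 congeneric
species × 6 collection locations (84 samples), 2 DNA subsamples per sample,
150 OTUs, sites at least 100 m apart in a 5 km square.  Its parts:

* **Tree** — a Kingman coalescent over genus ancestors, rescaled to unit
  height and warped so genus divergences sit deeper than 0.25 of tree
  height; each genus tip becomes a congener pair splitting at a uniform
  [0.05, 0.2] of height (capped below the parent node as a guard).  The tree
  is ultrametric by construction.
* **Sites** — a Gaussian patch per species (default sd = extent/2, i.e.
  only weak spatial clustering of conspecifics), with rejection sampling for
  the window and the 100 m minimum spacing; patch centres are clipped away
  from the window edge so tight patches remain feasible.  A "phylogenetic"
  patch rule makes congeners share a genus-level centre, for studying
  space–phylogeny confounding.
* **Chemistry** — each assay is a unit-variance mixture of exponential-
  covariance Gaussian fields (range = extent/5) plus a 30 % independent
  nugget, rescaled to a target marginal and clipped to a plausible range.
  pH (6.07 ± 0.46, clipped to [5.01, 8.03]), organic matter (4.2 %) and Na
  (91.8 ppm, [12, 390]) follow the reference site's printed summaries; the
  other assays use ordinary agronomic values.  K in ppm and meq/100 g are
  generated ~0.9-correlated, CEC tracks the major cations and organic
  matter loads weakly on it, giving the realistic mild collinearity the
  stepwise selection has to cope with.
* **Community** — for OTU j in sample i the log-affinity is
  `η_ij = w_species·S + w_chem·C + w_space·G + w_phylo·T + ε`, where S are
  iid per-species offsets, C = ⟨b_j, z_i⟩ with iid loadings on standardized
  chemistry, G is a broad Gaussian random field (range = extent/2), T a
  Brownian trait on the tree (tip covariance = shared branch length), and
  ε ~ N(0, noise_sd²).  Subsample rows add N(0, subsample_sd²).  Each
  channel is standardized to unit variance before weighting, so the weights
  are in common sd units.  A per-OTU baseline (sd 1) makes some OTUs
  common and some rare; the softmax compositions then pass a 0.2 % detection
  limit (each row's dominant peak always survives) and are renormalized —
  this is what gives the rare-taxon filter something to do.

**Channel orthogonalization.**  By default
(`orthogonal_channels=True`) each channel is residualized in-sample against
the other classes' design matrices (species against {1, phylo EVs, spatial
EVs, chemistry}; chemistry against {species indicators, spatial EVs}; space
against {species indicators, chemistry}; phylogeny against {1, chemistry,
spatial EVs}).  This is what makes "inject signal into exactly one class"
literal: without it, a strong signal in any channel leaks into every other
class design through chance subspace overlap (the expected spurious
noncentrality of a q-predictor design against an independent signal of
squared norm ‖μ‖² is ≈ (q/n)·‖μ‖², enough to push a 10-variable chemistry
model far past α under a strong species effect), and no single-channel
recovery experiment could hold the inactive classes at their nominal
false-positive rate.  With `orthogonal_channels=False` the channels keep
their natural confounding, which is the right setting for studying shared
variance fractions.  One confound is structural and survives any
projection: a phylogenetic trait is constant within species, so the species
factor always nests the phylogeny signal; a phylogeny-only scenario
therefore necessarily lights up the species F-test as well.

**Default weights.**  The reference study reports no effect sizes usable as
weights, so the defaults (w_species = 1.0, w_chem = 0.9, w_space = 1.0,
w_phylo = 0.7, noise_sd = 0.65, subsample_sd = 0.25) were chosen once so the
default study reproduces the *qualitative* structure of the reference
results: a four-axis ordination (stress ≈ 0.16–0.18 at k = 4, crossing the
0.20 ceiling between k = 3 and k = 4), plant species the strongest class on
most axes, chemistry second, space occasionally significant, and phylogeny
weak.  They are study conditions, not tuning knobs.

**Seeding.**  One master seed fans out to fixed per-purpose streams (tree,
sites, chemistry, community-0, community-1, ...), so changing one weight —
or toggling orthogonalization — leaves every other draw untouched, and two
communities of the same study are independent given the shared frame.

## Numerical choices

* NMDS convergence: relative stress-1 change < 1e-6, cap 500 iterations;
  stress-1 denominators of zero (degenerate all-equal configurations) return
  stress 0; coincident points get a tiny jitter before the first isotonic
  fit.  Solutions are centred, scaled to unit RMS, rotated to principal
  axes, and sign-pinned (largest-magnitude coordinate positive per column) —
  NMDS is only defined up to similarity transforms and tests need a
  canonical representative.
* PCoA keeps eigenvalues above 1e-9 × max|λ|; eigenvector signs are pinned
  the same way.
* Stepwise AIC uses `AIC = −2ℓℓ + 2(p+1)` (offsets cancel in comparisons);
  ties between candidate moves are broken by fixed column order, making the
  search deterministic.
* The LRT uses the χ² reference; at n = 84 and small df its size is ≈0.055,
  which the calibration suite tolerates.  The class tests use exact F.
* Rank deficiency is detected by matrix rank and reported with the aliased
  columns via pivoted QR; VIF reports +inf instead of raising.
* The equirectangular projection (R = 6371 km, about the mean latitude) is
  exact to sub-metre over a few kilometres; no datum handling is attempted.

## Benchmark problem sizes

The reduced-cost benchmark path (`benchmark_rep`) ordinates at k = 2 with 2
starts, uses 99 permutations, and evaluates ordination axis 1; class
inference conditions on the axis, so calibration is unaffected by the cheap
ordination settings.  The permutation test's size is measured by testing the
ordination against an *independently generated* community of the same soils
(`fit_null_p`): the self-fit p-value is significant by construction, since
the ordination optimizes exactly the fit being tested.  The calibration suite runs 400 null replicates at the
full design size (84 samples, 150 OTUs) and 100 replicates per
single-channel recovery scenario at 100 OTUs; the structural check runs the
complete default pipeline (two communities, 20 starts, k up to 6, 1000
permutations).

## What the tests do and do not show

Passing parameter recovery on this generator shows the chain detects and
correctly attributes independently injected signals at realistic design
sizes, and that each test holds its nominal size under the null.  It does
not show that field data behave this way: real predictors are confounded
(the generator's non-orthogonal mode exists to explore exactly that), TRFLP
fragment binning, PCR bias and peak-calling error are not modelled, OTU
responses to chemistry are monotone log-linear rather than unimodal, and the
spatial channel is a smooth field rather than patchy dispersal history.
Negative shared fractions, post-selection optimism in the *reported*
adjusted R² of selected chemistry subsets (the selection is the procedure
being mimicked, and its optimism is inherited), and the species/phylogeny
nesting are properties of the method itself, synthetic or not.
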