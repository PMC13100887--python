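# Methods

This note records the models, estimators, numerical choices and known
limitations behind `uhedge`, in the order data flows through the package.

## Genotype curation

Variant records carry the annotations the filter chain consumes: per-genotype
read depth (FORMAT DP), site quality (QUAL), mapping quality (INFO MQ) and a
capture-locus identifier (INFO LOCUS). The chain is two-level: genotype calls
with depth below the floor (default 5) are masked to missing *first*, and all
site-level statistics — minor allele count, call rate, mean depth — are then
computed on the masked matrix. This matters for order sensitivity: a site can
fail MAC only because low-depth calls were masked, and the test suite pins
that behaviour. Rule order is site quality ≥ 20 → mean depth ≥ 10 → mapping
quality ≥ 30 → MAC ≥ 3 → call rate ≥ 95% → biallelic-only → one SNP per
capture locus; each step's input/output counts are recorded so a run can be
audited like a filtering-table supplement. The chain is idempotent.

Threshold semantics are strict where the rule is phrased as an excess:
individuals are removed when their missing fraction is strictly *greater*
than 0.20 (exactly 20% is retained). The SNP-per-locus tie-break — highest
call rate, then lowest position — is this package's convention; upstream
tools rarely state one. An optional rule removing individuals with
heterozygosity z-scores above 3 (a contamination signature) exists but is
off by default.

Sample curation: localities are formed by single-linkage clustering with a
1 km chain radius (two samples share a label iff connected by a chain of
pairwise distances ≤ 1 km); over-sampled sites are thinned greedily by
descending collection date, skipping candidates whose relatedness to an
already-kept sample reaches the first-degree threshold (default 0.35 on the
Queller–Goodnight scale — a config knob, not an estimate).

## Population-genetic estimators

* **Hs** — heterozygous-site proportion divided by the mean proportion over
  included individuals; mean(Hs) = 1 exactly. Undefined when no individual
  carries a heterozygous site (0/0), flagged rather than propagated.
* **He** — mean over loci of 2p(1−p)·2n/(2n−1), n counted on non-missing
  genotypes per locus. The unbiased correction is load-bearing for
  reproducing published population tables; Fis = 1 − Ho/He.
* **Rarefied Ar** — the rarefaction unit is *genes* (2 per diploid), so
  "rarefied to 3 individuals" means g = 6 genes. Per locus,
  Ar = Σ_a [1 − C(N−N_a, g)/C(N, g)], computed in log-gamma space; loci with
  fewer than g genes in a population are skipped for that population. Ar is
  monotone non-decreasing in g (property-tested).
* **θ (Weir–Cockerham 1984)** — per-locus variance components a (among
  populations), b (among individuals within), c (within individuals), summed
  over loci before the ratio. Loci with fewer than two populated samples, or
  degenerate n_c, are skipped. The CI is a seeded percentile bootstrap over
  loci (1,000 resamples by default); the resampling unit is the locus because
  loci are the near-independent replicates in reduced-representation data.
  An independently coded scalar oracle (per-locus arithmetic, no shared
  code) pins the estimator to 1e-10 in the tests.
* **Queller–Goodnight relatedness** — reference allele frequencies are
  recomputed for every pair excluding the focal pair, and the two directional
  estimates are averaged. Heterozygous-focal loci contribute 0/0 and are
  resolved by summing numerators and denominators over loci before dividing.
  The estimator is invariant to locus order and ref/alt relabelling
  (property-tested); it carries the usual small-reference-sample bias, which
  is why calibration checks use pedigrees with ~40 founders.
* **Genetic distance** — Euclidean distance on 0/1/2 dosages over loci called
  in both individuals, rescaled by √(L/L_shared) so pairs with different
  missingness are comparable. The rescaling is this package's choice; pairs
  sharing no loci are flagged undefined.
* **Evanno ΔK** — |second difference of mean log-likelihood| divided by the
  replicate standard deviation at K. The group-mean form of the second
  difference is used (the standard formulation); ΔK is undefined at the end
  K values and where sd = 0.
* **Moran's I** — row-standardised weights, default 8-nearest-neighbour
  (distance-band available); expectation −1/(n−1), normal-approximation
  two-sided p-value, local I_i = (z_i/m₂)Σ_j w_ij z_j. The weight scheme is
  a knob because field studies rarely state theirs; a ±1 checkerboard under
  rook weights gives I = −1 exactly, which the tests use as a closed form.

## Resistance surfaces

Landcover classes map to per-cell resistances ≥ 1 or to absolute barriers;
barriers are *removed from the movement graph*, not given a large finite
cost (a `barrier_resistance` option substitutes a finite value for
sensitivity checks). The shipped hypothesis file holds: EMP, the empirical
urban-hedgehog surface (gardens/parks/cemeteries/allotments 1, lawn 5,
amenity 6, small streets 8, impervious 13, paths 14, unclassified 15,
railways/highways/large streets/linear water/wetland/woodland/farmland 100,
buildings and waterbodies barriers); NULL, uniform resistance 1 (isolation
by distance); and single-feature surfaces (RAILBAR/RAILCOR, ROADBAR,
GREENCOR, FARMBAR/FARMCOR, WATERBAR) that set one landcover group to 1 or
100 against the opposite background, buildings and waterbodies always
barriers. Mosaicking uses a precedence order (buildings first, gardens last)
so overlapping masks resolve deterministically; thin linear features can be
pre-dilated (chessboard metric) so rasterisation does not sever them.

Grid convention: row 0 is north, cell centres at
origin + ((col+0.5), −(row+0.5))·resolution, all distances in metres.
Raster I/O is plain-text ESRI ASCII grid plus a JSON legend sidecar —
deliberately dependency-light and diff-able. A majority-rule `resample` and
a window `clip` support coarse regional analyses; connectivity runs on the
native grid.

## Connectivity

The movement graph has one node per traversable cell and edges between
8-neighbours (4 by config) with conductance ((1/r_i + 1/r_j)/2)/d, d the
centre distance — so diagonal steps pay √2. Points snap to the nearest
traversable cell centre within 3 cell widths (configurable).

* **LCP** — Dijkstra with step cost 1/conductance; routes are recovered by a
  deterministic traceback scanning neighbours N, NE, E, SE, S, SW, W, NW, so
  tied optima resolve reproducibly. Disconnected pairs are ∞ and flagged.
* **Commute distance** — C_ij = 2m·R_eff(i,j) with m the summed edge
  conductance of the points' connected component and R_eff from sparse
  LU-factorised solves of the grounded Laplacian (one solve per point).
  Epsilon repair (default 1e-4, conductance-side) adds a constant to every
  adjacent traversable pair for commute/passage computations only — LCP
  never sees it. Epsilon cannot join regions separated by absolute barriers;
  the computation then restricts to the points' own component and errors if
  the points span components.
* **Passage maps** — for each origin–destination pair, unit current is
  injected and extracted, edge flows follow from the harmonic potential, and
  a cell's net passage is half the sum of absolute net currents on its
  incident edges (interior cells of a single corridor carry exactly 1; equal
  parallel branches carry 0.5). Net (not total) passages are reported, the
  standard corridor-mapping choice; maps average over the supplied pairs.

Both distance computations are pinned to independent oracles in the tests:
Floyd–Warshall for LCP, the dense Laplacian pseudoinverse for commute
(1e-8 relative on random grids up to 10×10).

## MLPE model selection

Pairwise tables hold one row per unordered pair: genetic distance as the
response, natural-log resistance distance per hypothesis as predictors, and
optionally untransformed straight-line distance. The mixed model is
y_ab = Xβ + u_a + u_b + ε with u ~ N(0, τ²) per individual and
ε ~ N(0, σ²). Fitting profiles the variance ratio λ = τ²/σ²: the pair
covariance is σ²(I + λZZᵀ), ZZᵀ is eigendecomposed once, and each λ
evaluation is a diagonal GLS step; the scalar profile likelihood is
maximised numerically with an explicit λ = 0 boundary check. Full ML (not
REML) is used throughout because compared models differ in fixed effects.
The parameter count k is #fixed effects + 2 (τ², σ²); n is the number of
pairs; AICc = AIC + 2k(k+1)/(n−k−1); R² is the squared correlation of the
fixed-effect predictions with the response (a likelihood-based pseudo-R² is
available). ρ = τ²/(2τ² + σ²) is the implied correlation between pairs
sharing one individual.

Suite conventions: within an algorithm block, pairs with an infinite LCP
distance under *any* hypothesis are dropped from all fits so ranked models
share the identical response; the NULL hypothesis keeps its distance-free
fit in the +distance column (its resistance distance already *is* distance,
and adding the covariate would be near-collinear); AICc ties fall to the
lower BIC.

## Synthetic data: what it emulates and what it does not

The generators mirror a desk-scale urban field study: ~70 diploid
individuals in 4–8 spatial clusters at ~1,400 biallelic SNPs with 5%
missingness and moderate differentiation.

* **Island model** (Balding–Nichols): ancestral p ~ U(0.1, 0.9), population
  frequencies Beta with mean p and variance Fst·p(1−p), genotypes
  Binomial(2, p). θ recovers the target within ±0.02 at 8×20×2,000
  (5 seeds), which is the calibration the acceptance checks use.
* **IBR model**: location-level logit-frequency deviations with covariance
  σ²·exp(−d/φ) in commute distance d on the generating surface;
  back-transformed frequencies clipped to [0.01, 0.99] (monomorphic loci
  retained — filtering is downstream's job); genotypes Binomial. Defaults
  σ² = 1 and φ = median pairwise commute distance were fixed once as
  calibration choices: they place the kernel in its informative range
  without saturating, and no field estimate of either exists to target.
  Individuals sharing a location are scattered over distinct nearby
  traversable cells, as field samples never share exact coordinates.
* **Pedigrees**: founder alleles Bernoulli(p), fair Mendelian transmission,
  optional clones; a relationship classifier labels pairs so relatedness
  estimators can be scored (clone 1, parent–offspring/full-sib 0.5,
  half-sib 0.25, unrelated 0).
* **Landscapes**: patch classes from one thresholded smoothed Gaussian noise
  field (quantiles proportional to class weights), linear features as
  optionally wandering strips spanning the grid. The default is a 24×24,
  5 m urban mosaic (gardens 0.35, buildings 0.15, impervious 0.25, parks
  0.25, one street, one railway).
* **VCF degradation**: Poisson read depths, Gaussian site qualities,
  constant mapping quality, seeded random missingness — enough structure to
  exercise every filter rule, no more.

This is deliberately not a coalescent simulator: there is no recombination,
no drift through time, no linkage, and the IBR covariance is stationary and
isotropic in commute distance. Passing tests therefore demonstrate that the
estimators and the model-selection machinery are correct and well
calibrated under their own assumptions — not that any particular field
system behaves like the generator.

The model-selection power conditions (the acceptance harness) use 20
individuals at 20 distinct locations on 24×24 grids with 1,500 SNPs and
commute-algorithm fits — the well-specified comparison for this generator —
and achieve ≥ 90% wins for the generating hypothesis under IBR truth and
≥ 80% NULL-competitiveness (ΔAICc ≤ 2) under uniform truth over 50 seeds.
Problem sizes throughout the suite (2,000-locus calibrations, 10×10 oracle
grids, 50-seed power runs) were chosen as the smallest sizes at which the
checks are statistically meaningful.

## Known limitations

* Movement is isotropic and time-invariant; no traffic volumes, no temporal
  resistance, no anisotropy.
* Resistance values are assigned, not estimated; there is no
  ResistanceGA-style optimisation of the class-to-resistance map.
* The clustering (admixture) MCMC itself is out of scope — only its
  replicate log-likelihood post-processing (ΔK) is implemented.
* MLPE comparisons are sensitive to the functional form linking genetic to
  resistance distance (the log transform is conventional, not derived);
  ranking reliability degrades when predictors are near-collinear across
  hypotheses, which is exactly when any method's answer is fragile.
* Inputs must share one projected CRS in metres; there is no reprojection
  and no vector-GIS processing.
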