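# Methods

## Problem and overall design

Genomic selection needs a reference population of genotyped *and*
phenotyped animals. Small indigenous breeds rarely have one, so the
practical question is whether several related small breeds can be pooled
into a single reference. `mbgp` studies this by simulation: it builds a
multi-breed genotype panel whose structure and LD resemble a dense
SNP-chip survey of 10 structured breeds, expands each breed to
training-population size without destroying its LD pattern, simulates
traits of known architecture, and scores GBLUP accuracy under different
reference compositions. Accuracy is always the Pearson correlation between
predicted (GEBV) and true (TBV) breeding values in held-out animals, so
the measured quantity is exact, not an estimate from phenotypes.

## Synthetic founder panel

Real small-breed panels (tens of animals per breed) are rarely
redistributable, so the founder stage is a forward-in-time Wright–Fisher
simulation with recombination and no mutation or selection:

* An ancestral population of Ne = 200 starts at linkage equilibrium with
  allele frequencies Uniform(0.05, 0.95) and drifts 100 generations,
  building LD with a realistic decay profile.
* It splits into 3 groups (Ne = 100, 100 generations), and each group
  splits into its breeds (Ne = 50, 15 generations); 4 + 3 + 3 breeds
  mirror a northern / southwestern / south-central grouping, with
  founder sample sizes 21–26 per breed by default.
* Meiosis places Poisson crossovers along the genetic map (no
  interference); chromosomes assort independently.

The genome is deliberately scaled down: 4 chromosomes × 5,000 markers with
exponential inter-marker gaps of mean 4 kb (~80 Mb total). Irregular
spacing matters: it populates the short-distance (0–2.5 kb) LD bins that a
regular 4 kb grid would leave empty, as on a real chip. Markers
monomorphic across all founders are dropped by default (they carry no
relationship information and break GRM scaling); ~25–30% of markers are
lost this way at the default drift depth, leaving ~14–15k segregating
markers.

### Calibration of the demography

A ~80 Mb genome cannot behave like a ~2.5 Gb genome at a 1 cM/Mb cattle
map: prediction accuracy is governed by the effective number of
independently segregating segments (Me), and by how quickly LD *phase*
decouples between diverging populations. Three parameters were therefore
calibrated, once, so that the emulation reproduces the qualitative regime
of a full-genome multi-breed study — high within-breed accuracy, near-null
across-breed accuracy, and a same-group advantage for pooled references:

* **recombination rate 50 cM/Mb** — sets within-breed haplotype diversity
  (hence Me and the within-breed accuracy level) and the clock on
  cross-breed phase decay;
* **group split 100 generations** — makes LD phase essentially
  breed-group-specific, so prediction across groups collapses;
* **breed split 15 generations** — keeps breeds within a group genuinely
  related, preserving the benefit of a same-group pooled reference.

These are properties of the emulation, not estimates of cattle history;
`FounderConfig` exposes them all. Under the defaults the panel shows
hierarchical FST (within-group pairs ≈ 0.1, cross-group pairs ≈ 0.2),
K-means on breed-centroid PC scores recovers the three groups exactly, and
within-breed LD (r²) decays monotonically across the 0–10 kb, 10–100 kb
and 100 kb–1 Mb bins.

## Block-resampling expansion

Each breed's 2·n founder haplotypes are expanded to 1,500 diploid
individuals: markers are partitioned into consecutive blocks of 500 within
each chromosome (the last block of a chromosome may be shorter; blocks
never span chromosomes), and each simulated gamete draws, per block, one
founder haplotype segment uniformly with replacement. Consequences, all
tested:

* within a block, haplotype frequencies — and therefore LD and phase —
  converge to the founder values at n = 1,500;
* allele frequencies are preserved in expectation (binomial sampling
  noise only);
* across block boundaries draws are independent, so long-range LD
  attenuates, emulating strong recombination hotspots;
* resampling is haplotype-level with the two gametes independent, which
  preserves Hardy–Weinberg proportions. Founders must therefore be
  phased and complete; missing founder calls are mode-imputed with a
  warning.

Blocks are fixed by marker index from each chromosome's start, so the
partition is deterministic given the map. Genotypes are simulated once per
study; traits and splits are redrawn per replicate.

## Trait simulation

QTL positions are drawn uniformly without replacement from the pooled
panel's markers, so QTL segregate in all breeds with breed-specific
frequencies. Architectures (total = small/medium/large):
I = 100 (0/0/100), II = 2,000 (1,361/614/25), III = 5,000 (4,595/390/15),
IV = 10,000 (10,000/0/0). Effects are Normal(0, c·σ²g) with
c = 10⁻⁴/10⁻³/10⁻² and σ²g = 1 nominal. The definition of σ²g is
otherwise circular (effects scaled by the variance they create), so the
nominal scale is used for sampling and the environmental variance is tied
to the *realized* genetic variance: env ~ N(0, Vg(1−h²)/h²) with
Vg = var(TBV) in the simulated population. This yields realized
heritability equal to the target in expectation; at n = 15,000 it lands
within ±0.03 of the target, which the tests assert.

## GBLUP

The genomic relationship matrix follows the Yang et al. (2010) estimator
(off-diagonals are averages of standardized-dosage products; diagonals use
the bias-corrected own-term form). Allele frequencies default to the
pooled analysis sample; the study computes one GRM over all 15,000
individuals with pooled-ten-breed frequencies and slices it per design,
which keeps frequencies fixed across replicates and lets one factorization
serve many traits. With sample frequencies and the plain
(`diagonal="vanraden"`) diagonal the all-entry sum of the GRM is exactly
zero — a centering identity the tests check at 1e-8; the Yang diagonal
trades that identity for lower bias on the diagonal itself.

The model is y = Xb + g + e with g ~ N(0, G σ²g), e ~ N(0, I σ²e).
A pedigree-based polygenic term is deliberately absent: resampled
individuals have no pedigree, so a numerator relationship matrix is
undefined and its variance would be absorbed by g and e. Fixed effects are
an overall mean, plus breed indicators when the reference is multi-breed.
Solving is by Cholesky factorization of V = G_rr + λI on the reference
block, with b̂ the GLS estimate and validation GEBVs by genomic regression
ĝ_v = G_vr V⁻¹(y − Xb̂); this equals the dense joint mixed-model equations
over all animals (tested at 1e-8). λ defaults to (1−h²)/h² from the
simulation's target heritability — using the truth removes
variance-estimation noise from design comparisons; EM-REML (eigenbasis
implementation, relative tolerance 1e-6, ≤200 iterations) is available
when λ must be estimated. A ridge of 1e-6 × mean diagonal stabilizes
near-duplicate resampled individuals.

### Causal markers and the GRM

At real chip density (hundreds of thousands of markers) it is immaterial
whether the handful of causal loci are themselves on the chip. At
desk scale it is not: 100–10,000 QTL among ~15k markers would carry an
unrealistically large share of the relationship signal, and — because a
marker's estimated effect transfers across breeds regardless of LD
phase — would prop up across-breed accuracy that a dense panel does not
show (measured here: across-breed 0.17 with causal markers in the GRM
versus 0.07 without). The grid runner therefore evaluates each trait with
the GRM recomputed as if that trait's QTL were not genotyped
(`exclude_qtl_from_grm=True`, implemented as an exact rank-downdate of the
required GRM blocks, or a rebuild from the complement markers when that is
cheaper — the two paths agree to float32 precision and are tested against
a from-scratch GRM). Setting the flag to `False` restores the
markers-include-QTL convention.

## Reference designs and the experiment grid

Every design phenotypes 1,200 reference animals: one breed (validation =
its 300 held-out animals, plus 300 random animals of every other breed for
across-breed accuracy); three breeds × 400 (same-group or one-per-group
composition); or ten breeds × 120. Splits are drawn without replacement
per replicate; reference and validation are disjoint by construction, and
the records carry design, composition, strategy, h², replicate and
validation breed. The grid reuses genotypes and the GRM across replicates
and redraws QTL, phenotypes and splits, with every seed spawned
deterministically from one master seed (re-running with the same seed is
bit-for-bit identical; tested). Cell failures are recorded per cell and
the grid continues. Reported summaries are unweighted means over
validation breeds, then replicates.

## Structure and phase diagnostics

PCA is computed on the column-centered dosage matrix; K-means (k-means++,
50 restarts, seeded) clusters *breed centroids* in the top-5 PC space,
because group membership is a breed-level, not individual-level,
assignment. Persistence of phase between two panels sharing a marker map
is the Pearson correlation, across marker pairs within a distance bin, of
the signed LD correlation r computed in each panel from haplotype
frequencies (signed r, not r², because sign agreement is exactly what
cross-population marker effects depend on; a dosage-based composite-LD
variant is available). Bins follow chip conventions: 2.5 kb steps to
10 kb, 10 kb steps to 100 kb, 100 kb steps to 1 Mb. Pairs monomorphic in
either panel are skipped; bins with fewer than two usable pairs report NaN
rather than zero.

## Scale of the standard study and observed behaviour

The packaged study (`mbgp.study.run_study`, also behind
`scripts/acceptance.py`) uses 25 founders per breed, ~20k simulated
markers (~14k after monomorphic dropping), 1,500 individuals per breed,
10 replicates, and heritabilities 0.1/0.3/0.6 — about 10–15 CPU-minutes.
Under the calibrated defaults the replicate means land at: within-breed
(strategy I, h² = 0.6) ≈ 0.63–0.65; across-breed ≈ 0.10; combined-ten
≈ 0.28; same-group three-breed ≈ 0.47 versus cross-group ≈ 0.43;
architecture-averaged within-breed ≈ 0.28 (h² = 0.1) and ≈ 0.46–0.49
(h² = 0.3); founder-vs-expansion phase persistence ≥ 0.99 in the 0–2.5 kb
bin. These are computed fresh by the tests and the acceptance script, not
constants of the package.

## Limitations

* The founder demography is generic (pure drift); it emulates structure
  and LD, not any real population's history. FST levels among the
  emulated breeds are calibration choices, not data.
* The scaled genome compresses Me by orders of magnitude; absolute
  accuracies are therefore calibrated, and only their ordering and
  response to design/heritability/architecture generalize.
* Block resampling cannot create new haplotypes: rare-variant dynamics,
  mutation and within-block recombination are absent, and relationships
  inside a simulated breed are bounded by the founder pool's diversity.
* The same-group advantage of pooled references emerges from shared
  descent only; real data add breed-specific trait differences, G×E and
  phenotype heterogeneity that the simulation does not model, so passing
  tests show internal consistency of the method comparison, not forecasts
  of realized accuracy in any particular breed.
* Phasing is assumed: synthetic founders are generated phased, and user
  panels must arrive phased (statistical phasing is out of scope).
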