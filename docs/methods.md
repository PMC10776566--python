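# Methods

This note documents the models, estimators and numerical choices behind
`seaconnect`, in the order the pipeline runs them, together with what the
synthetic-data generators do and do not emulate.

## Larval dispersal model

Larvae are modelled as passive surface particles in a 2-D velocity field
`(u, v)` in m/s on a regular lon/lat grid with daily time steps and a
boolean land mask. There is no vertical motion, diffusion, larval
behaviour, competency schedule or mortality: the model isolates what
advection alone implies about connectivity.

- **Space interpolation** is bilinear over the four surrounding grid nodes.
  Land nodes contribute zero velocity to the stencil; a stencil that is
  entirely land means the particle has run aground.
- **Time interpolation** is piecewise-constant per day: the forcing is
  daily and positions are updated hourly, so each hour uses the active
  day's field. (Linear-in-time blending was considered and rejected as the
  default because the daily forcing does not constrain sub-daily evolution;
  the piecewise-constant reading is the minimal assumption.)
- **Integration** is forward Euler with a default step of 1 h, converting
  velocities to angular displacements with a cos-latitude metric on a
  spherical Earth of radius 6371.0 km. A classical RK4 scheme is available
  (`method="rk4"`); the test suite uses it for the solid-rotation closure
  check, where Euler's systematic outward spiral at 1 h steps is of the
  same order as the 1 % tolerance.
- **Fates.** At each position (including the release position at hour 0)
  the particle is checked, in order: inside any site's settlement polygon →
  `settled` (first entry wins); stencil all land or inside a land polygon →
  `beached`; outside the grid → `lost_open_ocean`; after `max_days` (default
  30, the pelagic larval duration) → `expired`. A `min_age_hours`
  pre-competency knob (default 0) delays settlement eligibility; with the
  default, a particle released inside a settlement polygon settles
  immediately, which makes local retention of sheltered sites high by
  construction — raise `min_age_hours` to study transport-dominated
  regimes.
- **Release design.** Spawning polygons are rasterised into ~3 km cells
  (local equal-area approximation; cells with land centroids dropped); one
  or more particles start from every cell on every day of the site's
  spawning season in every simulated year. Settlement targets default to
  the spawning polygon buffered by 10 km, standing in for "the coastal
  area including the spawning location"; the buffer is configurable because
  settlement geometry is genuinely underdetermined.
- **Connectivity.** `P[i][j]` is the fraction of particles released at
  site i that settled at site j; rows of sites with zero releases are NaN
  rather than 0/0. Row sums ≤ 1 and fate conservation are asserted in the
  test suite on every simulation.
- **Distance statistics** use the haversine release→final distance. The
  reported SD is the population SD; the 95th percentile uses the
  linear-interpolation quantile convention.

## Nuclear-SNP statistics

Genotypes are minor-allele dosages {0, 1, 2} with −1 for missing; all
estimators are complete-case per locus.

- **QC** runs call rate → MAF → reproducibility, in that fixed order, with
  strict thresholds (a locus at exactly the threshold is removed); the
  order affects only the per-criterion removal counts, not the surviving
  set. MAF is pooled over all individuals.
- **Diversity.** Ho is the heterozygote fraction; He is 2p(1−p) corrected
  by 2n/(2n−1); allelic richness uses hypergeometric rarefaction
  Ar = Σ_alleles [1 − C(N−N_i, g)/C(N, g)] at g gene copies (default: the
  smallest locality's minimum non-missing copy count).
- **HWE** uses the exact conditional distribution of the heterozygote
  count given the allele counts (probabilities ∝ n!/(n_AA! n_Aa! n_aa!)·2^h,
  computed in log space); the two-sided p sums configurations no more
  probable than the observed one, and heterozygote deficiency is flagged
  from the one-sided lower tail.
- **LD** is a genotypic association test on the 3×3 genotype table per
  locality: exact conditional (Freeman–Halton-style) enumeration when the
  margin-constrained table count is small, otherwise seeded Monte Carlo
  with fixed margins. Exact conditional tests are valid but conservative
  under discreteness; the suite checks the type-I rate does not exceed the
  nominal bound.
- **F_ST** is Weir–Cockerham (1984): per-locus variance components a
  (among populations), b (among individuals within populations), c (within
  individuals), combined as the ratio estimator θ = Σa / Σ(a+b+c) over loci
  polymorphic in the populations compared. Significance is by permuting
  individuals between the two localities with the (1+count)/(1+N)
  estimator, so p is never reported as 0.
- **Standardised F_ST** follows Hedrick: θ/θ_max with
  θ_max = (k−1)(1−H_S)/(k−1+H_S), where H_S is the mean within-population
  expected heterozygosity of the pair (k = 2). Plain θ is always reported
  alongside, since the standardisation convention varies across software.
  The transect view places each pair at the midpoint of the two localities'
  along-coast positions.
- **Isolation by distance** is a simple Mantel test: Pearson correlation
  of the upper triangles, one-sided p from simultaneous row/column
  permutations. Geographic distances default to Euclidean on a local
  equirectangular projection (great-circle is available); a
  coastline-following distance is deliberately out of scope.
- **Outlier scan.** Per-locus multi-population θ is compared to a null
  built by shuffling locality labels (the same permutations for all loci,
  so the scan is vectorised). The permutation distribution of a per-locus θ
  is heavily tied — permuted allele-count splits coincide, especially at
  low MAF — which makes deterministic ≥/≤ counting visibly conservative in
  the lower tail. Ties are therefore split with one seeded uniform draw per
  locus (p_hi = (#{>} + u·(1+#{=}))/(N+1), p_lo with 1−u), which makes each
  one-sided tail exactly uniform under the null; the two-sided p doubles
  the smaller tail, and q-values are Benjamini–Hochberg. Note the null is
  "no structure at all": with genuine genome-wide differentiation the scan
  flags the upper tail of the θ distribution, so selection candidates
  should be read as loci far above the genome-wide θ, not merely rejections
  of panmixia.

## Mitochondrial statistics

- **Haplotype collapsing** labels distinct sequences H1, H2, … in order of
  discovery. The default ambiguity policy merges a sequence containing N or
  gaps into the first haplotype matching at all resolved sites (Hamming
  distance with pairwise deletion); a strict identity policy is available.
- **Diversity** is Nei's h = n/(n−1)(1 − Σp²), undefined below two
  samples.
- **Pairwise F_ST** is (H_T − H_S)/H_T over haplotype frequencies with
  small-sample corrections for haploid data: ĥ within each deme uses
  n/(n−1), H_S averages the two demes (harmonic mean ñ of sample sizes),
  and Ĥ_T = (1 − Σp̄²) + Ĥ_S/(2ñ). The estimator is slightly negative
  (≈ −1/2ñ) when the two demes are identical, like any unbiased F_ST
  estimator; two demes fixed for the same haplotype give 0 by definition.
  Significance permutes samples between the two localities.
- **Median-joining network.** Distances are Hamming counts. The displayed
  graph is the ε-relaxed minimum spanning network (ε = 0 ⇒ the union of all
  MSTs, so tied alternative connections are kept). Median (Steiner) vectors
  are the majority consensus of triplets linked in the current network and
  are accepted one per sweep — deterministically, in lexicographic order —
  whenever they reduce the *spanning* cost, i.e. the MST weight over the
  current node set; afterwards unused or non-shortening medians are pruned.
  Judging medians by spanning cost rather than by the summed MSN edge
  weight matters: the MSN's tied duplicate edges would otherwise mask
  genuine Steiner savings. The suite verifies the result against an
  exhaustive search over candidate median subsets on all bundled ≤5-
  haplotype fixtures.

## Clustering

- **Admixture model.** Each individual i carries membership fractions Q_i
  over K clusters; cluster k has allele frequency p_kl at locus l. The
  Gibbs sweep (i) assigns each of the two allele copies at each (i, l) a
  cluster of origin with probability ∝ Q_ik·p_kl (or 1−p_kl), (ii) redraws
  p_kl from Beta(1+n1, 1+n0) conjugate posteriors, (iii) redraws Q_i from
  Dirichlet(1 + per-cluster copy counts). Cluster allele frequencies are
  independent across clusters — the correlated-frequencies prior of the
  classical software is deliberately not implemented; the simpler model
  recovers clusters reliably at the divergence levels of interest
  (F_ST ≳ 0.1 at a few hundred loci) at a fraction of the implementation
  risk, and this divergence is documented here rather than hidden.
  Reported Q and p are posterior means over post-burn-in sweeps; the
  observed-data log-likelihood (binomial in Qp per genotype) is recorded
  every sweep. Desk-scale defaults are 10,000 sweeps with 2,000 burn-in;
  the examples and tests use smaller, stated values that already achieve
  the documented recovery. Label switching across runs is resolved by
  deterministic greedy matching of Q columns.
- **ΔK** is the Evanno second difference |L̄(K+1) − 2L̄(K) + L̄(K−1)| /
  sd(L(K)) over ≥3 replicate runs per K, undefined at the range ends and
  where sd = 0.
- **PCoA** delegates to scikit-bio's classical scaling (Gower centring +
  eigendecomposition); negative eigenvalues are reported, never clipped.
  The individual-level genetic distance is the allele-sharing distance
  |g_i − g_j|/2 averaged over loci non-missing in both individuals.
- **DAPC** is PCA (mean-imputed, centred dosages) keeping the smallest set
  of components explaining ≥90 % variance by default, followed by linear
  discriminant analysis; single-member groups trigger a warning and pooled
  covariance rather than an error.

## Telemetry

Positions are consumed as given — geolocation modelling is out of scope;
an optional per-record positional-uncertainty column is carried through.
Distances are haversine on the R = 6371 km sphere. "Annual" distance is
the maximum cumulative path length inside any sliding 365-day window, which
matches a "within a single year" reading without assuming calendar years.
Zones must be non-overlapping polygons; records outside every zone are
`offshore`, and transitions are consecutive records in different zones.

## Synthetic data: what it emulates and what it does not

The fixture module reproduces the *structure* of the study's inputs, not
their realism:

- Velocity fields are analytic (zero, uniform, double gyre, solid
  rotation) or random smooth streamfunction fields on a 0.08° grid. They
  exercise interpolation, integration and fate logic exactly (closed forms
  are asserted at every node), but contain no eddies, tides, coastal
  boundary layers or realistic shelf circulation — connectivity numbers
  from them say nothing about real coastlines.
- Genotypes follow the Balding–Nichols model: ancestral frequency p ~
  Uniform(maf range), subpopulation frequency ~ Beta(p(1−F)/F,
  (1−p)(1−F)/F) (the F → 0 limit returns p), genotypes are two binomial
  copies. The expected Weir–Cockerham θ equals F, giving a calibrated
  recovery target (±0.02 at 1,000 loci and 2×50 individuals, averaged over
  20 seeds). There is no linkage, no allele-frequency spectrum realism and
  no sequencing-error model; missingness is injected uniformly at random,
  which is exactly what a call-rate filter assumes. The per-locus
  reproducibility metric is treated as an abstract fraction in [0, 1]
  because its upstream definition is assay-internal.
- Haplotype alignments grow from an ancestral sequence by single
  substitutions at previously unused sites, so the true genealogy is a
  recorded tree and every pairwise Hamming distance is the tree-path
  length. Real control-region data have homoplasy and indels; the merge
  policy for ambiguous sites exists for them but is exercised only
  synthetically.
- Default design sizes mirror the motivating dataset (six localities,
  12/23/12/16/17/7 samples, 1,534 SNPs); the default F of 0.05 reflects
  the low-but-nonzero marine differentiation regime the methods are meant
  to resolve.
- One named RNG stream per fixture kind, all derived from the master seed
  via spawn keys: adding a fixture to a config never shifts another
  fixture's draws.

Passing tests on these fixtures demonstrates correctness of the estimators
and the simulation machinery under known ground truth — they do not
validate oceanographic realism or the demographic assumptions of any real
population.

## Numerical and reproducibility choices

- Permutation p-values use (1+count)/(1+N) and recorded seeds; N is chosen
  so the nominal α is attainable (e.g. 199 permutations make p = 0.05
  exactly reachable).
- All pipeline stage seeds derive from the master seed via
  `SeedSequence(entropy=seed, spawn_key=...)`, kept below 2³¹.
- Velocity NetCDF files are written through xarray with land as NaN fill
  plus an explicit mask variable; the bytes are deterministic, so run
  manifests can compare SHA-256 checksums across runs.
- Degenerate inputs are defined, not fatal: monomorphic loci are excluded
  from θ sums, He of a monomorphic locus is 0, haplotype diversity below
  two samples is NaN, an empty post-QC locus set returns an empty dataset
  with a warning, a site with zero releases gets a NaN connectivity row.
- Test problem sizes (e.g. 200-locus admixture panels, 3,000-sweep chains,
  1,000-replicate null calibrations at 199 permutations) are the package's
  own desk-scale choices: large enough that the documented recovery and
  calibration targets are met with margin, small enough to run routinely.

## Known limitations

- 2-D surface advection only; no diffusion kick, so dispersal spread is
  purely deterministic given the field.
- The no-structure permutation null of the outlier scan (see above) is not
  a genome-wide-background null like Bayesian outlier methods use.
- The LD exact test treats genotypes as unphased categories; it is not the
  haplotype-level composite-LD test of the classical population-genetics
  software it stands in for.
- The admixture sampler has no LOCPRIOR, linkage model or correlated
  frequencies; ΔK inherits the usual caveat of being undefined at K = 1
  and K_max.
- Geographic distances ignore coastline topology; for strongly concave
  coasts the Euclidean IBD axis compresses true along-shore separation.
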