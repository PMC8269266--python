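# Methods

This note documents the models, the null constructions, the synthetic data
generator, and the numerical and design choices behind `ecoassembly`.

## Sloan neutral community model

The model treats each local community as a sample of N reads whose true
relative abundance of taxon *i* fluctuates around the metacommunity mean
p_i under drift and immigration. At stationarity the local relative
abundance is Beta(N·m·p_i, N·m·(1−p_i)); the product Nm (community size ×
immigration rate) is the single free parameter. The classical occurrence
prediction integrates the Beta above a detection limit d = 1/N:
`freq = 1 − B(d; Nm·p, Nm·(1−p))` (`predict_frequency`, checked in tests
against direct quadrature of the Beta density).

**Fitting.** `SloanNCM.fit` minimizes the sum of squared deviations of
observed occurrence frequencies from the predicted curve over log10(Nm) ∈
[−1, 7]: a 33-point coarse grid brackets the optimum, then bounded Brent
refines it. The objective is unimodal in practice; the grid stage removes
any sensitivity to initialization. R² = 1 − SSres/SStot about the mean
observed frequency (a generalized R², it can be negative for badly
misspecified data). 95% bands are Wilson score intervals on the predicted
frequency with trials = number of samples; taxa are partitioned above /
within / below them.

**Detection model.** By default the fit uses the exact occurrence
probability under Beta-distributed abundance followed by an N-read
multinomial draw: P(detect) = 1 − B(a, b+N)/B(a, b) with a = Nm·p,
b = Nm·(1−p). The classical step approximation (abundance > 1/N) is
available as `fit(detection="threshold")`. The exact form is the package's
default because, against read-resampled data of exactly the kind the
generator produces, the step approximation overestimates m by roughly 30%
while the exact marginal recovers it to within a few percent; the two
options share every other part of the fit.

**Conventions.** N is the common column sum of a rarefied table; with
unequal sums the caller must pass N (the mean column sum is the usual
choice), and m = Nm/N is then defined relative to that N. A table in which
every taxon occurs in every sample carries no occurrence signal and is
rejected with a diagnostic rather than fitted.

## Phylogenetic turnover: βMNTD, βNTI

For samples k and l with relative abundances f and patristic distances d,

βMNTD = ½ [ Σ_{i∈k} f_ik · min_{j∈l} d_ij + Σ_{j∈l} f_jl · min_{i∈k} d_ij ],

abundance-weighted, with shared taxa contributing their zero self-distance.
The null shuffles taxon identities across the distance matrix (a
regional-pool randomization over all taxa in the table, abundances
untouched), 999 replicates by default; βNTI is the observed value's
z-score against the null (sd with one delta degree of freedom). Pairs whose
null distribution has zero spread — e.g. a star phylogeny, or two samples
that both contain every taxon — are reported as missing with a warning, not
as ±∞, and are excluded from (but counted alongside) the process fractions.

The implementation vectorizes βMNTD over all pairs: M[i, l] = min distance
from taxon i into sample l's taxa, then βMNTD = ½(A + Aᵀ) with A = FᵀM.
It is oracle-tested against a literal double loop.

## Raup-Crick on Bray-Curtis (RC_bray)

Each null replicate rebuilds every sample: its observed richness of taxa is
drawn without replacement with probability proportional to regional
occupancy (fraction of samples containing the taxon), and its observed read
total is then allocated multinomially with probability proportional to
regional relative abundance, restricted to the drawn taxa. Bray-Curtis is
computed between the rebuilt samples, and

RC = 2·[(#null < obs + ½·#ties)/n_null − ½] ∈ [−1, 1],

with half-weighted ties so RC is centred at 0 under exchangeability. The
regional pool defaults to the analyzed table; `occupancy`/`regional`
overrides let a caller hold the pool fixed across subsets (and make the
self-calibration test exact). Generating data by this very procedure and
scoring it yields |RC| ≤ 0.95 for ≈94% of pairs — slightly under the
nominal 95% because realized richness can fall below the drawn richness
when the multinomial assigns a chosen taxon zero reads.

## Process classification

βNTI < −2 → homogeneous selection; βNTI > 2 → heterogeneous selection;
otherwise RC_bray > 0.95 → dispersal limitation, < −0.95 → homogenizing
dispersal, and |RC| ≤ 0.95 → undominated. Fractions are reported over
classified pairs; the five classes partition them by construction.

## Beta-diversity statistics

Community distances default to Bray-Curtis on Hellinger-transformed
(square-root relative abundance) profiles; raw-proportion Bray-Curtis is a
flag (and is what the RC null uses, which operates on counts). PCoA is
classical scaling of the double-centered squared-distance matrix; negative
eigenvalues are retained in the reported spectrum but contribute no axes.
PERMANOVA is the one-factor pseudo-F; ANOSIM the rank statistic
R = (r̄_between − r̄_within)/(n(n−1)/4). Mantel, PERMANOVA, ANOSIM,
distance-decay and the βNTI-environment correlation all use label
permutations with an explicit seed and the add-one convention
p = (1 + exceedances)/(1 + n_perm), so p is never 0 and never smaller than
1/(n_perm+1). Mantel-type p-values are two-sided on |r|. Geographic
distances are great-circle with Earth radius 6371.0088 km. Spearman
environment correlations use tie-corrected ranks with the t approximation
for n ≥ 21 and a permutation null below that.

These routines are implemented in-package (scikit-bio's equivalents do not
take a random seed, and end-to-end reproducibility is a hard requirement
here); scikit-bio serves as an independent cross-check in the test suite.

## Maximal information coefficient

Classic MIC: over all grid resolutions (nx, ny) with nx·ny ≤ n^0.6, the
y-axis is equipartitioned into ny rows (ties kept together) and the x-axis
partition is optimized by dynamic programming over clump boundaries, with
at most c·nx superclumps (c = 15). The DP maximizes the column-additive
statistic Σ m_pq log2(m_pq/m_p) = −n·H(Y|X); adding H(Y) gives I, and the
characteristic value is I/log2(min(nx, ny)). Both orientations are
computed and the maximum taken, making the score symmetric; it lies in
[0, 1] and is invariant to strictly monotone transforms. On noiseless
functional data at n = 100 it saturates at 1; on independent uniforms its
null distribution concentrates near 0.24.

Significance for the pair matrix uses a shared permutation null: each draw
permutes the sample order of one member of a (cycled) pair, and every
observed MIC is ranked against the same null sample; Benjamini-Hochberg
adjusts across pairs. This is a deliberately self-contained error-control
construction standing in for TIC-based pipelines; the FDR intent is the
same and the divergence is documented here. Note the attainable p floor is
1/(n_perm+1): an adjusted-p threshold of 0.001 needs permutation counts
well above 1000 unless many pairs tie at the floor.

## Co-occurrence network

Edges require MIC ≥ 0.5 and adjusted p below the cutoff; the sign is the
sign of the pair's Spearman ρ (MIC itself is nonnegative; a zero ρ is
logged and counted positive). Isolated taxa are not added as nodes; a
zero-edge result is a warned-about empty network, not an error. Topology:
degree; unnormalized Brandes betweenness; classic closeness within each
connected component; diameter and average path length on the largest
component (the published networks this mirrors are disconnected, so the
convention must be pinned); Louvain modules at resolution 1.0 with a fixed
seed, module ids ranked by descending size. Keystoneness is the mean of
min-max-scaled degree, (1 − scaled betweenness), and scaled closeness —
a constant centrality scales to 0 — with ties in the ranking broken by OTU
id.

## Synthetic survey generator

The generator emulates a latitudinal sediment survey: 7 named locations
(FT carries 7 sites, the others 6, ≈129 samples; a uniform 6 sites gives
the 126-sample design used in the determinism tests), 3 depth layers, and
per-sample read depths uniform on 19,206–43,750, with rarefaction to the
minimum as the default downstream.

- **Phylogeny:** pure-birth (Yule, rate 1) forward simulation with
  exponential waiting times; ultrametric, all branch lengths positive.
- **Traits:** Brownian motion from a root value of 0; a tip optimum has
  variance σ²·(root-to-tip length), giving the phylogenetically conserved
  optima that make selection detectable by βNTI.
- **Pool abundances:** lognormal(0, 1) by default (log-series available);
  ranked abundances are shuffled across tips so the pool itself carries no
  phylogenetic signal in abundance — without this decoupling, neutral data
  would show spurious βNTI signal because tip labels follow tree traversal
  order.
- **Neutral regime:** each sample's local abundances are Beta draws around
  the pool (Sloan stationary distribution at immigration m), followed by a
  multinomial read draw; columns sum exactly to their depth.
- **Selection:** the pool is multiplied by a Gaussian filter
  exp(−(optimum − env)²/(2·s²)) and renormalized before the neutral draw;
  s → ∞ reduces byte-for-byte to the neutral regime at the same seed.
- **Dispersal limitation:** the immigration rate decays as
  exp(−distance/scale) with great-circle distance from the abundance
  centroid of all sites (the regional-pool assumption of the downstream
  null models).
- **Environment:** the selection axis is expressed on the trait scale:
  tied to standardized latitude plus a depth-layer offset ("latitude"
  mode), constant at a chosen trait quantile ("constant"), or split into
  two latitudinal blocks at opposite quantiles ("two_block"). Metadata
  additionally carries survey covariates (MAT, MAP, salinity, pH, TOC, TN)
  as linear functions of latitude with Gaussian noise, and records the true
  regime per sample for test oracles.

**What the generator does not emulate:** sequencing error, chimeras and
primer bias (counts are sampled directly, not reads); temporal dynamics;
taxon-specific read-length or copy-number effects; spatial autocorrelation
of covariates beyond the latitude trend. Tests that pass on these data
therefore validate the statistical machinery and its calibration, not the
preprocessing of real amplicon data.

**Detectability of homogeneous selection.** With abundance-weighted βMNTD,
a selection signature needs (i) per-sample communities restricted to a
trait band that is phylogenetically clustered and (ii) substantial
compositional turnover among samples within that band. In the generator
this regime is reached with a large pool relative to per-sample richness
(2,000 taxa), strong drift (m ≈ 0.003), a filter width ≈ 0.3 of the
trait sd, and a constant environment at an upper trait quantile (0.8);
these are the documented study conditions for the selection checks. Small
pools at survey read depths put nearly every taxon in every sample, which
compresses βNTI toward 0 — a real limitation of nearest-taxon statistics,
not an implementation artifact.

## Numerical choices and degenerate inputs

- All randomness flows through numpy Generators seeded explicitly; child
  seeds derive from `SeedSequence.spawn`. Identical seeds reproduce outputs
  byte-for-byte, including pipeline TSV/JSON files (floats printed at %.10g).
- Rarefaction uses multivariate hypergeometric draws (uniform subsampling
  without replacement); samples below depth are dropped with a warning (or
  raise, by flag), and all-zero OTU rows are removed.
- Chao1 uses the bias-corrected form S + F1(F1−1)/(2(F2+1)) by default;
  the classic form is a flag. Shannon is in nats; evenness J = H′/ln S is
  missing for S = 1. Absence counts as below the rare-abundance cutoff; an
  OTU reaching 1% anywhere is dominant even if it dips below 0.01%
  elsewhere (dominant precedence on the overlapping definitions).
- Degenerate Beta parameters in the neutral sampler are floored at 1e-12;
  a pathological all-zero local draw falls back to the pool itself.
- The pipeline reruns distances and null models per abundance-class subset
  on the pruned taxon set when `per_class` is enabled, and per location
  under `group_by`, mirroring how per-stratum analyses recompute their
  nulls within each stratum.

## Problem sizes

Default test and acceptance scales: 500-taxon pools and 100 samples for
neutral-model recovery; 200 taxa × 30 samples × 999 nulls for βNTI and
RC_bray calibration; 2,000 taxa × 42 samples × 199–299 nulls for the
selection checks; 150 taxa × 126 samples for the end-to-end pipeline runs;
n = 100 for MIC diagnostics. These sizes were chosen so each check runs in
seconds to a couple of minutes on a single core while keeping the relevant
statistics (pair counts, null quantiles) well resolved.
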