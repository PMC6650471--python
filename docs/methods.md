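# Methods

`cryodiv` implements the statistical toolbox used to characterise microbial
communities of glacial and periglacial habitats: within-sample (alpha) and
between-sample (beta) diversity, OTU definition and rarefaction, a
threshold-rule endemicity classifier, and an isolation-by-distance (IBD)
analysis built on Mantel statistics. This note documents the models, the
parameter conventions, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## OTU definition and rarefaction

**Average-neighbor clustering.** Sequences are binned into OTUs by
agglomerative group-average clustering of a pairwise distance matrix:
clusters merge while the minimum *average* between-cluster distance
(arithmetic mean over all cross-cluster pairs of the original matrix) is at
or below the cutoff, default 0.03 (97% identity). Ties in the merge
criterion are broken by the lexicographically lowest label pair, so the
partition is deterministic; OTUs are numbered by their smallest member. The
implementation recomputes averages directly from the original matrix (an
O(n³) strategy appropriate for the clade sizes involved, ~10²); the test
suite checks it against scipy's Lance–Williams average linkage on generic
matrices.

**Rarefaction.** Samples are subsampled *without replacement*
(multivariate hypergeometric draws from a seeded generator), not
multinomially, because the expected-richness curve used alongside is the
hypergeometric closed form

E[S_d] = Σ_i [1 − C(N−N_i, d) / C(N, d)],

evaluated in log-Γ space to avoid overflow. Rarefaction is a single seeded
draw by default; the analytic curve is what should be plotted or compared
across samples. The default depth is the minimum sample total.

## Alpha diversity

Per sample, from the count vector (and, for PD, a rooted tree):

- Shannon H = −Σ p_i ln p_i, natural log by default (a `base` argument is
  provided for bits/Hartley conventions);
- bias-corrected Chao1 = S_obs + F1(F1−1)/(2(F2+1)), defined even when no
  doubletons exist (F1, F2 = singleton/doubleton counts);
- Berger–Parker dominance d = N_max/N;
- Good's coverage C = 1 − F1/N;
- Faith's PD = total branch length of the minimal subtree connecting the
  present tips. The default is the *rooted* variant (the path to the root is
  included, so a single tip has positive PD); `rooted=False` restricts to
  branches between present tips. Group summaries are unweighted arithmetic
  means of per-sample values.

## Beta diversity

**Weighted UniFrac.** For samples A and B, raw weighted UniFrac is
Σ_b l_b |p_Ab − p_Bb| over all branches, with p_Ab the fraction of A's
reads descending from branch b. The *raw* form is the package default: it
is the form whose values can exceed 1 (a reported dissimilarity of 1.49 is
only possible unnormalized), which makes it the right default for
reproducing published tables from this literature. The normalized form
divides by Σ_j d_j (p_Aj + p_Bj) over tips (d_j = root-to-tip distance) and
lies in [0, 1]. OTUs with zero counts everywhere may be absent from the
tree; any OTU with a positive count must be a tip.

**ANOSIM.** All n(n−1)/2 distances are ranked with mid-ranks for ties;
R = (mean between-group rank − mean within-group rank)/(M/2) with
M = n(n−1)/2, so R ∈ [−1, 1] and R is invariant under monotone transforms
of the distances. p comes from group-label permutation with the add-one
convention, p = (1 + #{R_perm ≥ R_obs})/(1 + n_perm). Groups of size 1 are
rejected; sizes below 5 trigger a logged warning (the permutation
distribution is then very coarse — with 2+2 samples only three distinct
relabelings exist).

**PCoA.** Classical metric scaling: B = −½ J D² J (Gower centering),
symmetric eigendecomposition, coordinates = eigenvectors × √λ for positive
eigenvalues, axes ordered by eigenvalue. Negative eigenvalues (non-Euclidean
input) are reported verbatim, never Lingoes/Cailliez-corrected; proportion
explained is computed over the positive part of the spectrum only. The
positive/zero threshold is 1e-10 relative to the spectral scale.

## Endemicity classification

OTUs with ≥ 2 sequences (default `min_seqs=2`; singletons are likely
artifacts) are classified from a match table holding, per OTU, the best
database-hit identity and the set of thermal environments ({cold,
temperate}) of all hits at ≥ 97% identity:

| best identity | environments of ≥97% hits | category | tier |
|---|---|---|---|
| ≥ 97 | all cold | cryophilic | non-endemic |
| ≥ 97 | all temperate | non-cryophilic | non-endemic |
| ≥ 97 | both | polythermal / cosmopolitan | non-endemic |
| [95.5, 97) | — | subnovel | endemic |
| [88.5, 95.5) | — | novel | endemic |
| < 88.5 | — | unclassified (warned) | — |

Boundary closure is a design choice the verbal rule (">97%" vs "<97%")
leaves open: each threshold belongs to the upper interval, so the rules
partition the identity line and raising an identity can never create
endemism. "Polythermal" and "cosmopolitan" are synonyms here and carried as
one category. The classifier consumes a precomputed match table; it never
runs a database search (results would be database-version-dependent).

## Isolation by distance

**Genetic distances** are uncorrected p-distances: mismatches over compared
sites, with *pairwise deletion* of positions where either sequence carries a
gap or ambiguity (complete deletion available); U ≡ T. A pair with zero
comparable sites is an error, not a silent zero. Model-corrected distances
(JC69 etc.) are out of scope.

**Geographic distances** are great-circle (haversine) distances between the
sites of each sequence pair; same-site pairs are 0 km. The default Earth
radius is the IUGG mean radius 6371.0088 km; the international-ellipsoid
value 6378.388 km is provided as a constant because some older
geographic-distance routines used it, and matching published kilometre
figures may require that convention.

**Mantel test.** r is the Pearson correlation over the n(n−1)/2 unordered
pairs; the null distribution comes from simultaneous row/column permutation
of one matrix; the default tail is positive (the IBD hypothesis is
directional), with negative and two-sided tails available; the add-one
convention applies. The permutation default is 1000, the convention in this
literature.

**Mantel correlogram.** The number of distance classes follows Sturge's
rule on the pair count, k = ⌈1 + log₂ m⌉ — e.g. 96 sequences → m = 4560 →
k = 14. Classes are equal-width over (0, max distance]; zero-distance
(same-site) pairs are placed in class 1 so the classes partition all pairs.
Each class is a Mantel test of the genetic matrix against the binary
class-membership model matrix. The reported class statistic is the
*negated* Mantel r, so positive values mean pairs in the class are more
genetically similar than average (positive spatial autocorrelation); the
literature does not fix a sign convention, and this one makes correlograms
read like autocorrelation functions. The per-class permutation test is
one-tailed in the direction of the observed statistic; the Bonferroni
correction is global (p × k, capped at 1, for every class — not
progressive), and significance means corrected p ≤ 0.05. Empty classes are
retained with n_pairs = 0 and NaN statistics rather than dropped. No
half-maximum-distance truncation is applied. Note that the ceil convention
is taken at face value: for m = 1326 it yields 12 classes, even though a
published correlogram of that size shows 11; whatever pruning produced the
printed count is undocumented and deliberately not guessed.

## Synthetic data

The generators are pure functions of (config, seed) and emulate the study
designs this toolbox targets:

- **Community tables**: lognormal(μ=0, σ=1.5) base abundances across 200
  OTUs; an "ice" habitat effect multiplies a random 25% of OTUs by
  exp(group_effect) (default 2.0); 6 samples per group of 1000 multinomial
  reads each. This plants a compositional difference detectable by
  UniFrac + ANOSIM while keeping the lognormal rank-abundance shape typical
  of amplicon surveys.
- **Trees**: random coalescent-style topologies with Exponential(0.1)
  branch lengths, tip labels matching the community generator.
- **IBD alignments**: sites evenly spaced along a meridian transect
  (spacing 500 km, 24 sites, 4 sequences/site ≈ the ~100-sequence clade
  scale); a master sequence accumulates Poisson(β·d·L) mutations per leg
  (stepping-stone scheme), plus per-sequence Poisson(noise·L) private
  mutations. The expected p-distance between sites D km apart is
  1 − exp(−βD) to first order, giving a closed-form curve to validate the
  Mantel machinery against; defaults β = 10⁻⁶ /site/km and noise = 0.005
  /site place the global Mantel r in the weak-but-detectable regime
  observed for cryosphere clades. Divergence expected to exceed 0.75 raises
  a saturation error, since an uncorrected distance cannot express it.
- **Match tables**: categories drawn from a mix patterned on a periglacial
  bacterial survey (46:7:7:3:3 cosmopolitan : cryophilic : non-cryophilic :
  subnovel : novel over 66 OTUs); identities uniform inside each category's
  interval and strictly off the 97/95.5/88.5 boundaries, so classifier
  recovery of planted classes is exact and boundary behaviour is exercised
  by dedicated unit cases instead.

What the generators do **not** emulate: read-level error profiles and
chimeras, taxonomic structure, coalescent genealogies with migration,
uneven site occupancy, or real spatial configurations of glaciers. Passing
parameter-recovery tests therefore demonstrates the statistics are computed
correctly and calibrated (type-I error at nominal rate, power increasing
with planted effect), not that any biological conclusion transfers to real
surveys.

## Problem sizes in the test suite

Calibration tests use 500 replicates (Mantel and ANOSIM type-I error,
99 permutations each, n = 10–12 objects); power and null-correlogram
checks use 100 replicates of a 16-sequence, 8-site transect with 199
permutations per test; the classifier recovery test uses 1000 OTUs. These
sizes give binomial confidence intervals tight enough for the stated
acceptance bounds while keeping the whole suite around a quarter minute.

## Known limitations

- The average-neighbor implementation is quadratic in memory and cubic in
  time; it targets long-read clade analyses (hundreds of sequences), not
  OTU picking over millions of reads.
- ANOSIM and Mantel p-values are permutation estimates; with tiny designs
  (2+2) the attainable p floor is coarse and results should be read
  accordingly.
- The correlogram's equal-width binning follows the Sturge's-rule
  convention; quantile (equal-frequency) binning is not offered.
- Weighted UniFrac assumes the tree's tip set covers all observed OTUs;
  there is no fallback insertion of missing taxa.
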