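# Methods

## Statistical model

A disease pair (i, j) on a roster of N patients is summarized by the 2×2
presence/absence table with cells a (neither), b (j only), c (i only),
d (both); the margins are the per-disease patient counts n₁ = c + d and
n₂ = b + d. The roster total N must count *all* patients in the source
system, including those with no mapped disease: cell a is derived from it,
and omitting the disease-free population would inflate every expected count.
Under independence E[d] = n₁n₂/N; the reported effect size is the ratio
d / E[d], and the direction call (over/under) is simply d versus E[d].

Significance is the classical two-sided Fisher exact test: the sum of
hypergeometric probabilities of all tables with the observed margins that
are no more probable than the observed table. The engine works entirely in
log space (log-gamma differences), so million-patient rosters neither
overflow nor lose the extreme tails; a relative tie tolerance of 1e-7 on the
probability comparison keeps the observed table inside its own two-sided sum
despite floating-point rounding. Degenerate margins (an empty row or column)
give p = 1. The same engine, with a one-sided upper-tail alternative, serves
the gene-overlap test. The test suite checks the engine against exact
integer enumeration for every table with N ≤ 60 and against an independent
library implementation on random tables.

p-values are reported raw; multiplicity is handled by comparing the raw p
with α/m (α = 0.05 throughout). For the EMR tests m is, by default, the
number of diseases in the pair's age-incidence cluster; the conventional
alternative m = k(k−1)/2 (pairs per cluster) is available as
`bonferroni_mode="pairs"`. Both are recorded in the result metadata. Pairs
with any observed or expected cell below 5 are excluded before testing, but
m is determined by cluster membership, not by how many pairs survive the
cell filter.

## Age-incidence clustering

EMR observation windows generate spurious inverse comorbidity between
diseases whose onset ages are far apart (a childhood-onset and an old-age
disease rarely co-occur in the same chart even when they co-occur in the
same life). The correction is to compare diseases only when their
incidence-by-age shapes are similar:

* Each disease is the 91-vector of earliest-onset counts at integer ages
  0..90 (ages above 90 censored to 90), scaled to unit Euclidean length so
  shape, not caseload, drives distances. A disease with no onsets is an
  error, not a silent zero vector.
* Candidate solutions come from Ward-linkage hierarchical clustering (always
  included; it yields compact clusters of similar size and is deterministic),
  k-means with seeded restarts, and average-linkage hierarchical clustering,
  over k = 2..10 by default. Partitioning-around-medoids would be a natural
  further member but no installed implementation exists, so the default set
  stops at these three; the method list is configurable.
* Each (method, k) labeling is scored with six internal validity indices:
  mean silhouette width, Calinski–Harabasz, Dunn, Davies–Bouldin (negated),
  Handl connectivity with 10 nearest neighbours (negated), and the gap
  statistic with 10 uniform reference draws. All are aligned so larger is
  better; an index that cannot be computed for a labeling is recorded as a
  failure (NaN), never silently dropped. The gap statistic clusters its
  reference draws with k-means at the same k regardless of the method under
  scoring — a deliberate simplification that keeps the reference dispersion
  comparable across methods.
* An index that is *strictly* monotone in k for every method is removed:
  it would always point at an end of the search range. Non-strict
  monotonicity is not enough — a plateaued index still carries peak
  information.
* Each surviving index is z-standardized (zero mean, unit variance, ddof 0)
  across all (method, k) cells jointly, then averaged over methods and
  indices into one composite per k. Joint standardization is the simplest
  reading of "standardize each measure"; a per-method variant would weight
  methods differently and was not adopted.
* The chosen k is a local maximum of the composite (strictly above both
  neighbours; a boundary k qualifies against its single neighbour). Among
  several local maxima the highest wins and ties break toward smaller k
  (larger clusters admit more testable pairs). If no strict local maximum
  exists the global maximum is used; a flat composite is an error.
* Final labels always come from the Ward dendrogram cut at the chosen k.

Cluster naming (e.g. "adulthood", "aged") is a human act and out of scope;
the API carries an optional id→name map for reporting only.

## Ingestion

Encounter extracts (patient id, ICD9 code, age at visit, visit year) are
filtered to visits from a configurable rollout year (default 2008) onward,
ages censored at a configurable cap (default 90), malformed rows dropped
with their line numbers logged. Codes are mapped many-to-one to disease
names through a catalog; codes outside the catalog are counted and ignored
(the study vocabulary is deliberately a subset). Per (patient, disease) the
earliest age across all mapped encounters is kept; marginal counts, pair
counts (one boolean incidence-matrix product, verified against brute-force
patient-set intersection in tests) and onset histograms follow. Diseases
with fewer than 50 patients (strict) are removed together with their pairs.

Aggregate-only sources (per-disease and per-pair count files plus a roster
total) bypass onset histograms — their age clustering must borrow the
labels derived from a patient-level source. The roster total may carry a
downward adjustment for rostered populations that cannot contribute disease
codes (e.g. healthy-employee blocks); the adjustment applies to N only,
never to the loaded counts, since nothing is known about how such patients
would have contributed to pairs.

Roster frequencies are reported as percents rounded half-even to two
decimals.

## Gene sets and overlap

Variant-association rows (disease, gene, optional p-value and provenance)
are filtered to p < 10⁻⁶ (strict) when p-values are present; tables without
a p column are assumed pre-filtered. When one variant maps to several genes
the symbols are joined with colons into a canonical group (unique symbols,
sorted); the group is the default unit of overlap, so `GLT8D1` and
`GLT8D1:GNL3` are distinct units — this reproduces published shared-gene
lists verbatim. An `explode_groups` flag splits groups into individual
symbols for sensitivity analyses.

Overlap between two diseases' sets is tested one-sided (enrichment: overlap
at least as large as observed) against a gene universe. The universe
defaults to the number of distinct units present anywhere in the loaded
table — a database-relative convention, always recorded in the output,
overridable by an explicit integer. No universe convention can be backed out
of published odds ratios (they are mutually inconsistent across rows), so
none is asserted as canonical. The odds ratio is
(shared × neither) / (only₁ × only₂), defined as 0 with no overlap and
flagged infinite when one set contains the other. Zero-overlap pairs are
reported, not dropped: the integration stage needs them as explicit
negatives.

## Integration

A pair significant-and-concordant in both EMRs and significant in the
variant overlap is "clinical and genetic"; concordant but not genetically
significant, "clinical without observed genetic effect"; genetically
significant but not concordant in the EMRs, "genetic without observed
clinical effect". The last category is gated on same-cluster membership
(a cross-cluster pair was never clinically testable, so its clinical
silence is uninformative) and records which single EMR, if any, reached
significance. Discordant pairs (opposite directions in the two sources) are
logged and excluded from concordance. Report tables separate over- and
underrepresented pairs, print raw p-values in scientific notation with a
two-decimal mantissa, and sort by cluster then disease names — a
deterministic order chosen over effect-size sorting. The concordant-pair
network exports as GraphML plus a TSV edge list, nodes attributed with a
reference source's disease frequency and cluster id, edges with the
reference observed/expected ratio.

## Synthetic data

The generators define the conditions under which the pipeline is validated:

* **EMR sources.** Each disease has a baseline lifetime prevalence and a
  parametric onset-age density (a mixture of one or two Gaussian bumps on
  ages 0..90, discretized and normalized). Pairwise dependence is planted as
  a relative-risk multiplier ρ on the joint: P(both) = ρ P(a) P(b), realised
  by sequential conditional sampling — exact for any forest of planted
  pairs, with cyclic constraints rejected. Onset age is drawn independently
  of co-disease status: the age correction targets marginal incidence shape,
  and nothing is asserted about the joint age structure of comorbid pairs.
  Each (patient, disease) yields one encounter at onset (one of two ICD9
  codes per disease, exercising many-to-one mapping) and, for about a third
  of events, a later repeat encounter, so earliest-onset reduction is
  non-trivial. Two sources are two independent draws from the same
  configuration with seeds derived from one parent seed.
* **Variant tables.** Pairwise overlaps are planted exactly by dedicating
  shared genes to each pair and filling the remainder with private genes;
  feasibility requires each disease's planted overlaps to fit inside its set
  size and the universe to hold all distinct genes. Three-way overlaps are
  therefore always zero — sufficient for testing a pairwise statistic.

What the generators do **not** emulate: visit-level longitudinal structure
(repeat utilization, death censoring), coding error, gender/ethnicity
structure, correlated onset ages within comorbid pairs, SNP-level genotypes,
or linkage disequilibrium. Passing tests demonstrate that the statistics
recover planted marginal and pairwise structure under clean conditions, not
that real EMR biases beyond the modelled age confounding are handled.

## Problem sizes and numerical choices

The validation suite uses: null false-positive control with 20 diseases at
2% prevalence, 50,000 patients per source, 100 seeds; power/recovery with a
planted pair at ρ = 3 and ρ = 0.3 (2% marginals, 100,000 patients per
source, 100 seeds each); cluster-count recovery with 40 diseases over four
well-separated life-stage profiles (onset bumps at ages 5/30/55/80, width 6,
400 onsets per disease), k searched over 2..8, 50 seeds; Fisher oracle
equivalence enumerated for all tables with N ≤ 60. The end-to-end script
uses 24 diseases, 60,000 patients per source, three planted pair effects and
three planted gene overlaps. These sizes make every planted effect
comfortably detectable while keeping a full run in minutes on one core.

Other numerical choices: half-even rounding for printed percents; a 1e-7
relative tie tolerance inside the two-sided Fisher sum; Fisher margins
canonicalized (n₁ ≤ n₂) so the p-value is exactly invariant to swapping the
diseases; unit-vector norms validated to 1e-9; k-means restarted (n_init 10,
then 50) until exactly k nonempty clusters emerge.

## Known limitations

* The Bonferroni denominator "diseases per cluster" is unusual (the
  conventional count is pairs); both modes are implemented and the choice is
  surfaced in results metadata rather than hidden.
* The gene universe convention materially changes overlap p-values and odds
  ratios; results should always be read together with the recorded universe
  size.
* Sequential conditional sampling cannot plant cyclic pairwise constraints
  (it raises); chains and disjoint pairs are exact.
* Aggregate-only sources inherit another source's age clusters; if the two
  populations' age structures differ, that borrowing is an approximation.
* The local-optimum rule for k falls back to the global maximum when the
  composite has no strict interior peak; with very few candidate k values
  the distinction between "local" and "global" optimum is weak.
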