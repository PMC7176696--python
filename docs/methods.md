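# Methods

## Scope and data model

The package analyses lists of IBD segments — stretches of genome two
individuals co-inherited from a recent common ancestor — as produced by
haplotype-based detectors. A segment records the two individuals, the
haplotype index the shared stretch sits on in each (1 or 2; 0 = unknown),
chromosome, physical coordinates, genetic length in cM and a detector
confidence score. Coordinates are 1-based inclusive throughout; BED input
(0-based half-open) is converted on read, and overlap is always the test
`max(starts) <= min(ends)`. Chromosome labels are normalised by stripping a
leading `chr`. The segment column layout is a declared dialect (default:
the 9-column detector layout `sample1 hap1 sample2 hap2 chrom start end
score lengthcM`), never sniffed — a silently transposed haplotype column
would corrupt the triangulation typologies downstream.

Genetic maps are per-chromosome anchor lists (bp, cM) with linear
interpolation. Queries outside the anchored range clamp to the terminal cM
value rather than extrapolate, so segments running into telomeres cannot
acquire negative or inflated genetic lengths.

## Quality control

Filters are applied as independent, idempotent stages, each returning the
retained segments plus a count-conserving report entry
(input = retained + removed, asserted):

* **Length** — keep segments *strictly* longer than `min_cM` (default
  6 cM for dense modern panels, 2 cM for a sparse focal genome). The strict
  reading matches the usual "longer than X cM" phrasing; a flag switches to
  ≥ for sensitivity analyses.
* **Score** — keep `score >= min_score` (default 4.8 in the focal
  pipeline): removal targets scores *below* the threshold, so a segment at
  exactly the threshold survives.
* **Exclusion regions** — drop segments overlapping user-supplied
  centromere/telomere BED intervals by ≥1 bp. No built-in coordinate set is
  shipped; these regions are assembly-dependent and must be supplied.
* **Score–length outliers** — fit OLS of score on length and flag segments
  whose residual falls below −k robust standard deviations (MAD × 1.4826,
  default k = 3). In manual workflows this cut is a visual call; the
  automated rule is an explicit approximation, and therefore *advisory*:
  flagged segments are only removed on request, never silently.

The focal diagnostic regression (score on per-segment SNP count) uses
`scipy.stats.linregress` with adjusted R² = 1 − (1−R²)(n−1)/(n−2); it
errors cleanly when SNP counts are absent or constant.

## Co-ancestry network and sharing statistics

Individuals are nodes; an undirected edge joins every pair sharing ≥1
segment. A pair with k segments contributes k to segment counts but one
edge, with k and the summed cM kept as edge weights — segment-count
statistics and binary-link network views need different units. Haplotype
indices are ignored at network level: the unit is the unordered pair of
individuals. By default only individuals appearing in ≥1 segment become
nodes ("isolated pairs not represented"); a flag adds the rest as degree-0
nodes. "Disconnected" individuals are those outside the largest connected
component (ties broken by lexicographically smallest member). Regional
sub-networks are induced subgraphs on a focal population's members plus
their direct neighbours — one hop only.

Sharing rates divide intra/inter segment counts by the corresponding
possible-pair counts; the intra/inter ratio is computed from unrounded
rates. The population-pair matrix holds mean segments per possible pair,
with diagonal entries undefined (NaN) for populations of size < 2.

## Triangulation audit

Two calls are linked when they share ≥1 individual, lie on the same
chromosome and overlap by ≥1 bp; clusters are connected components of this
relation. For every linked pair sharing exactly one pivot individual B
(pairs sharing both individuals are duplicate calls, counted separately),
the audit classifies, in order:

1. **transitive** — a segment joining the two outer individuals overlaps
   the intersection interval by ≥1 bp. The search is confined to the
   cluster: a qualifying third segment overlaps both members and shares an
   individual with each, so it provably belongs to the same cluster.
2. **explained_short_overlap** — the intersection, measured in cM via the
   genetic map, is shorter than the detector's minimum reportable length
   (`min_reportable_cM`, default 1 cM — this must be set to the threshold
   the detector was actually run with, or short third segments will be
   misread as missing).
3. **explained_haplotype** — B carries the two segments on different,
   known haplotypes; no single ancestral stretch is implied.
4. **unexplained** — a candidate artifact call.

The four-way scheme is this package's explicit reconstruction of the
typology idea: each case is mechanically decidable from detector output
columns, which is what makes the audit reproducible. On error-free
pedigree-simulated data the unexplained count is exactly zero (transitivity
holds by construction of inheritance), and planted artifact pairs — calls
with a shared pivot haplotype, a wide overlap and no third segment — are
recovered exactly.

## Focal-individual enrichment

Counts of focal-shared segments per population are tested against
Binomial(n_i, p) with p = T/N (T total focal-shared segments, N panel
size), one-sided upper tail — the enrichment direction; a two-sided option
(doubled smaller tail) sits behind a flag. Expected counts n_i·p sum to T
exactly. The binomial tail is `scipy.stats.binom.sf`, verified in tests
against brute-force pmf summation to 1e-12. Trials are segments by
default; an alternative mode counts distinct sharing partners, for use
when single partners contribute many segments. An observed count above the
binomial support n_i is capped at n_i with a loud warning rather than
hidden.

TSBH adjustment: stage 1 runs BH at α′ = α/(1+α) giving r₁ rejections;
m̂₀ = m − r₁ (r₁ = 0 → reject nothing; r₁ = m → reject all); stage 2
re-runs BH at α′·m/m̂₀. Adjusted p-values are the standard BH step-up
values scaled by m̂₀/m, clipped to [0,1] and monotone in the sorted order,
so rejection reads p_adj ≤ α/(1+α). Published implementations differ by
the constant factor (1+α) (rescaling so rejection reads p_adj ≤ α); the
rejection sets are identical, and the test suite checks ours against
statsmodels' two-stage routine on both conventions. Dependence between the
per-population tests (one population's count constrains the others through
T) is handled only through TSBH's robustness under block-positive
dependence; no permutation null is attempted.

## Synthetic data

Two generators, both fully determined by their config seed (identical
config ⇒ byte-identical output):

* **Segment-level** — per-pair segment counts are Poisson(λ_intra) within
  and Poisson(λ_inter) between populations; lengths exponential; positions
  uniform on the map; scores linear in length plus Gaussian noise (so
  outlier tests can plant violations). Defaults: 4 populations × 25,
  λ_intra = 0.19 and λ_inter = 0.0027 — the per-pair sharing rates
  observed in dense European panels, whose ~70× intra/inter contrast is
  the regime the network statistics are meant for — mean length 10 cM.
* **Pedigree** — founders carry globally unique haplotype labels; each
  transmission draws Poisson(L Morgans) crossovers placed uniformly in cM
  (Haldane model, no interference — sufficient for the statistics tested)
  and splices a mosaic. True IBD between two haplotypes is the set of
  maximal intervals with identical labels, computed on the continuous
  interval representation (exact cM endpoints), not the marker grid.
  Defaults: 2 populations × 12, 5 generations, 400 markers per chromosome.
  Mean true segment length shrinks as depth grows, emulating progressive
  fragmentation of ancestral haplotypes.

The default genome is three chromosomes (120 + 100 + 80 cM at a uniform
1 cM/Mb), a desk-scale stand-in for a human autosomal map: large enough
for hundreds of segments and thousands of audited trios, small enough that
the full suite runs in seconds. The focal-study generator gives each panel
member a Bernoulli(base_rate × factor) chance of sharing one segment with
the focal individual (base rate 0.072 ≈ a realistic focal sharing fraction;
factor applied to one designated population), which matches the binomial
null the test assumes.

What the simulators do *not* emulate: coalescent demography, mutation,
phasing or genotyping error, marker ascertainment, and realistic LOD
scores (detector and truth scores are labelled proxies). Passing tests
therefore validate the *statistical machinery* — filters, counts,
networks, the audit, error control — not the behaviour of any particular
IBD caller on noisy real data.

## Naive detector

The detector reports maximal runs of marker-wise label identity between
haplotypes of different individuals, with cM span ≥ `min_cM` and marker
count ≥ `min_markers`. It is intentionally simple — exact identity, no
error model (an allowed-mismatch parameter exists but defaults to 0) — so
that its output is verifiable against ground truth: boundaries differ from
the truth by at most one inter-marker gap, giving interval Jaccard ≈ 0.998
on the default panels. It does not reimplement probabilistic HMM-based
callers and its scores are an arbitrary-scale proxy (markers × log₁₀ 2).

## Numerical and design choices

* Filters before statistics; filter order defaults to
  length → score → exclusion → outlier, each stage recorded.
* Ratio and rate calculations use unrounded intermediates; rounding only
  at presentation.
* Components/cluster tie-breaks are deterministic (size, then smallest
  member; stable sorts throughout), so reports are order-independent —
  property-tested by permuting inputs.
* Pipeline runs write a manifest (sha256 per artifact, seed, effective
  config, package version); reruns with the same config and seed reproduce
  the hashes exactly.
* Problem sizes in tests and the acceptance script (panels of ~16–430
  individuals, 200-replicate Monte Carlo, 2,000-marker chromosomes) were
  chosen as the smallest sizes at which the Monte Carlo assertions have
  comfortable margins (3 standard errors).

## Known limitations

* The binomial null treats segments as independent trials; per-partner
  clustering is only addressed by the alternative "individuals" mode.
* The outlier rule approximates a judgment call; its k has no calibrated
  false-positive rate.
* The triangulation audit assumes the supplied `min_reportable_cM` equals
  the detector's true reporting floor; a mismatch inflates the unexplained
  count.
* Community structure beyond connected components is exposed only as an
  exploratory greedy-modularity grouping with no statistical guarantee;
  visible "modules" of real panels are normally a judgment call on a
  layout, which no automatic grouping reproduces exactly.
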