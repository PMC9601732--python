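# Methods

This note documents the statistical model, the algorithms, the simulator,
and the design decisions behind `radmap`, in the order the pipeline runs.

## Population model and marker classes

The data are genotypes of two outbred heterozygous parents and N progeny
of their F1 cross at biallelic SNPs. A marker's segregation type is a pure
function of the parental genotypes: *ab*×*aa* (female heterozygous, male
homozygous), *aa*×*ab* (the reverse), *ab*×*ab* (both heterozygous), or
uninformative. Only the two 1:1 classes are mapped: their progeny show two
observable classes (homozygous = the shared parental allele, heterozygous
= carries the informative parent's second allele), which this package
codes 0/1 with −1 for missing. *ab*×*ab* markers are classified but
excluded from mapping — the strategy deliberately avoids needing them.

**Filters.** Each 1:1 marker is tested against the Mendelian 1:1 ratio
with chi-square = (n_HOM − n_HET)²/(n_HOM + n_HET) on non-missing calls
(1 df, no continuity correction — the convention of the standard mapping
packages). Markers with p < α (default 0.01) or with a missing-call
fraction ≥ 20% of all progeny (inclusive bound) are removed. When both
rules fail the reported reason is the missingness one (data quality takes
precedence); the keep/remove decision is the same either way. The missing
fraction uses total progeny as denominator; the chi-square uses the
non-missing count.

## RAD-tag selection

A tag pairs one *ab*×*aa* SNP (the anchor; its position is the tag's map
coordinate — the intra-tag span of < 1 kb is far below genetic resolution)
with one *aa*×*ab* SNP within `intra_max` = 1000 bp. Selection is a greedy
left-to-right scan per chromosome: each anchor takes the partner with the
smallest span (ties: lower missing fraction, then lower position), and a
tag is accepted only if its anchor is ≥ `inter_min` = 100 kb beyond the
previous accepted anchor. Greedy keep-first spacing was chosen over
optimal tag packing: it is deterministic, linear, and matches the
adjacent-tag phrasing of the protocol. Tag ids are "RT" + a serial that
increases along the genome (chromosomes in natural sort order).

## Two-point analysis

r̂ = min(R, n−R)/n on pairwise-complete calls, phase coupling iff
R ≤ n−R (an exact tie is an arbitrary labelling and is reported as
coupling). The LOD compares the binomial likelihood at r̂ against free
recombination. The combined (both-meiosis) fraction for a tag interval
pools gametes: r = (R_f + R_m)/(n_f + n_m), which equals the two-point
estimate on the merged matrix when data are complete. Pooling (rather
than averaging the two r̂ values) was chosen because the merged dataset is
literally a stack of gametes; the two rules coincide at equal sample
sizes.

## Grouping

Single-linkage transitive closure: two markers are co-grouped iff
connected by a chain of pairs with LOD ≥ threshold **and** r̂ ≤ `r_max`
(default 0.45). The r̂ guard exists because at large N a pair can reach a
high LOD at r̂ near 0.5; it is standard practice. `scan_thresholds`
evaluates a threshold ladder (default 5..17) and, given a target count
(e.g. the karyotype), returns the smallest threshold achieving it. The
"count" compared against the target is the number of connected components
(multi-marker groups plus singletons) — identical to the number of groups
in the normal no-singleton regime, and monotone in the threshold, which
makes the scan well-defined. Without a target the pipeline uses the
smallest threshold: raising the threshold can only fragment true
chromosomes, so the most inclusive grouping at the minimum stringency is
the right default, with the scan available when the chromosome number is
known.

## Phase harmonization and merging

Along a given marker order, the phase of each marker is called against its
immediately preceding (already harmonized) neighbour; a repulsion call
flips the column (0 ↔ 1, missing untouched) and records the FLIPPED flag.
Sequential propagation against the nearest neighbour was preferred to
anchoring on the first marker because adjacent pairs carry the most
linkage information. Flipping is a pure relabelling: every pairwise
(r̂, LOD) is exactly (bit-for-bit) unchanged, harmonization is idempotent,
and a double flip restores the original column. A pair with r̂ ≥ 0.49 has
an essentially arbitrary phase call; the package warns and keeps the
original coding rather than guessing. Merging stacks the N female rows and
N male rows of the same individuals over the same tag list; phase flags
are carried per component.

The pipeline harmonizes both meioses along the female-map order and merges;
the male map itself is built on the male matrix along its own estimated
order (the two codings are equivalent up to column flips, which the
statistics ignore).

## Multipoint likelihood and interval estimation

Each matrix row is one meiosis. The hidden state at marker i is the
transmitted parental homolog (prior ½/½); the chain switches between
adjacent markers with probability r_i (Markov — i.e. no crossover
interference); an observed call identifies the state and a missing call
emits 1 for both states. The log10-likelihood is computed by the scaled
forward algorithm; an all-missing row contributes exactly 0, and an
obligate recombinant across an interval with r = 0 yields −inf, reported
as such.

Optionally the emission models a symmetric miscall rate ε (a 0/1 call is
wrong with probability ε): P(obs | state) = 1−ε or ε. This matters
quantitatively: with a per-call miscall rate of 0.005, each interval's
apparent r̂ is inflated by ≈ 2ε(1−ε) ≈ 0.01, which at r ≈ 0.05 inflates
the Kosambi map length by 15–20%. Error-aware multipoint mapping is the
classical remedy, and the pipeline estimates one ε per linkage group by
EM (started at 0.005, clamped to [1e−6, 0.2]). The default for the
low-level functions is ε = 0, the exact error-free model.

Interval r values are fitted by EM (forward–backward E-step; M-step
r_i = expected switch count / rows), initialized from pairwise-complete
adjacent two-point estimates, iterated until |Δlog10L| < 1e−6 (≤ 200
iterations; non-convergence warns and returns the last iterate). During
iteration r is clamped to [1e−9, 0.49999]; converged values below 1e−8
are snapped to 0. With complete data and ε = 0 the starting values are
already the exact MLE (the likelihood factorizes over intervals) and are
returned unchanged, so the estimates equal the two-point values exactly.

## Marker ordering

The search objective is the adjacent-pair profile log10-likelihood
Σ S[o_k, o_{k+1}] with S[i,j] = R′·log10 r̂ + (n−R′)·log10(1−r̂) from
pairwise-complete counts. On complete data this *is* the multipoint
profile likelihood (exact factorization); with missing data it is the
standard fast surrogate — evaluating the full EM-profiled HMM likelihood
for every candidate during local search would be numerically equivalent on
complete data and computationally prohibitive otherwise. The search:
greedy chaining from the highest-LOD pair (appending the nearest unplaced
marker to either end), then alternating sweeps of window-ripple
(exhaustive permutations of every sliding window of size ≤ 5) and 2-opt
segment reversals until a full sweep finds no improvement, plus two
seeded random restarts. The final order is canonically oriented (first
tag id < last tag id), and the reported order log10-likelihood and
distances always come from the full multipoint EM fit. Exhaustive-search
oracle tests on 8-marker groups bound the heuristic's optimality gap.

Order comparison (`compare_orders`) re-estimates interval r (and ε, if
enabled) per candidate order on the merged data — profile-likelihood
"compare" semantics — so each order is judged at its own best distances.
One engine builds all three map flavors; a mixed toolchain (different
engines for parental and integrated maps) would make the likelihood
comparison across flavors incoherent.

## Genome concordance

"Discordant region" is not formally defined in the protocol this package
follows; the definition adopted here — the package's loudest open
interpretation — is: the *backbone* is the longest strictly monotone
(increasing or decreasing) subsequence of genome positions along the map
order, and DRs are the maximal runs of consecutive non-backbone markers.
This is deterministic, orientation-agnostic, and reproduces the intended
qualitative reading (local blocks breaking collinearity). Among
equal-length backbones the one keeping the earliest map markers is chosen
(first excluded marker as late as possible); on a direction tie the same
rule picks between increasing and decreasing. Markers aligned to a
chromosome other than the group's majority chromosome are excluded and
reported separately, not counted inside DRs. Note that the count of
markers inside DRs (M − backbone length) is exactly invariant under map
reversal, while the number of DRs is invariant in practice but could in
principle differ between tied maximum backbones; also note that for a
strict in-place inversion of k markers the backbone retains one block
member (k−1 markers are discordant), whereas a displaced inverted block
loses all k.

## Simulator

`simulate_f1` lays `tags_per_chromosome` tags per chromosome with anchor
spacing ≥ 100 kb (uniform jitter up to 50 kb), partner SNPs 50–999 bp
away. Parental phases follow a Markov flip chain with `repulsion_fraction`
(default 0.5 — phases are unknown a priori). Female and male gametes are
independent two-state Markov chains over the intervals with their own r
values; there is **no crossover interference**, so the Kosambi function is
a reporting transform (as in the mapping workflow), not a generative
assumption — simulated and mapped lengths are compared through the same
transform. Genotyping error (symmetric HOM↔HET swap, default 0.005) is
applied before missingness (default 0.10), independently per call — error
models miscalls of observed genotypes. All randomness comes from one
counter-based (Philox) stream keyed by the seed: identical configurations
give byte-identical outputs.

Defaults are the reference study design: 257 progeny, 19 chromosomes, 60
tags per chromosome, per-interval r drawn uniformly from (0.03, 0.08) for
the female and (0.02, 0.06) for the male meiosis. These ranges give
female > male recombination on essentially every chromosome and total map
lengths (≈ 6200/4500/5300 cM female/male/integrated at 60-tag resolution)
of the magnitude typical of dense outbred tree maps, with a mean adjacent
spacing near 5 cM.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: crossover interference, segregation-distortion
loci, locus dropout correlated with coverage, clustered or genotype-biased
missingness, mis-assembled reference coordinates (so concordance on
simulated data measures only ordering errors), and *ab*×*ab* / *ab*×*cd*
markers. Real RAD data also violate the symmetric-error assumption
(allele dropout makes HET→HOM miscalls more likely than the reverse).

## Numerical and interface conventions

All genomic coordinates are 1-based (VCF convention); map positions are
reported in cM with 2 decimals. VCF input is parsed with cyvcf2 (phased
separators accepted, phase ignored — phase is inferred, never trusted);
a simple TSV genotype dialect (a/h/−) is the text alternative. The merged
matrix, tag table, group table, maps, summaries and the JoinMap-style
.loc export are TSV with stable column orders; the merged-matrix writer
round-trips bit-exactly. Every stochastic step (ordering restarts,
simulation) takes an explicit seed; the pipeline writes a run log
(versions, seed, thresholds, filter funnel counts) and a MANIFEST marking
incomplete runs when a stage fails.

## Known limitations

- Sequential phase propagation can, in principle, lock in a wrong flip
  after an extremely weak adjacent pair; a global phase optimization is
  out of scope.
- The ordering search is a local heuristic; optimality is bounded by
  oracle tests only up to 8 markers.
- One ε per linkage group; real error rates vary per marker and per
  individual.
- Likelihoods assume independent meioses and no interference; distances
  are interference-adjusted only through the Kosambi transform.
- Grouping compares component counts, so a chromosome fragmented by a
  filtered-out tag run can only be healed by lowering the threshold, not
  by merging components post hoc.
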