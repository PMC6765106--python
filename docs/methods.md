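# Methods

`ampdenoise` reconstructs the true sequence variants ("templates") and
their frequencies from long-read circular consensus (CCS) amplicon data.
Two denoisers cover the two sequencing regimes, a population-comparison
metric scores reconstructions, and a read simulator provides controlled
test beds. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic benchmarks do and do not show.

## Error model and quality filtering

Per-base Phred scores are converted to error probabilities
`p_i = 10^(-Q_i/10)`; their sum is the read's *expected errors* E. Reads
are filtered on the expected error **rate** E/L (default cutoff 0.01).
The probability that a read is error free is taken as the Poisson
zero-count probability `exp(-E)` rather than the exact product
`prod(1 - p_i)`; the two agree to second order in the `p_i`, and the
Poisson form is the same assumption the abundance significance test makes,
keeping the model internally consistent.

The error-free fraction of a dataset — the mean of `exp(-E)` over reads —
is the regime diagnostic: when it is appreciable (tens of percent), the
true templates are literally present as repeated identical reads and
read selection (FAD) applies; when it is near zero, templates must be
reconstructed by clustering and averaging (RAD).

## Kmer representation and distances

Sequences are represented as integer count vectors over all `4^k` kmers
(default `k = 6`; 2-bit encoding, A=0 C=1 G=2 T=3, big-endian). Windows
containing `N` are skipped. The corrected kmer distance

    D(A, B) = (1 / 2k) * sum_i (A_i - B_i)^2

approximates edit distance at low divergence: one substitution in a
non-repetitive context changes `k` windows, i.e. `2k` counts by ±1, and
contributes exactly 1. Homopolymer length changes — the dominant CCS
error — perturb far fewer counts and are systematically down-weighted,
which is desirable when indels dominate the noise. Dividing by the mean
of the two sequence lengths (a single "sequence length" is ambiguous for
unequal-length sequences; the mean keeps the operation symmetric) yields
a per-base scaled distance comparable to an error rate. The corrected
distance is a squared quantity and violates the triangle inequality; the
plain Euclidean distance between count vectors, with
`D = euclidean^2 / 2k`, is the true metric used wherever triangle bounds
are needed.

## FAD — read selection

FAD dereplicates the quality-filtered reads, orders unique sequences by
abundance (ties broken lexicographically), and accepts a candidate with
dereplicated count ≥ `min_count` (default 2) when either

1. its corrected kmer distance to every accepted template exceeds
   `neighbor_radius` (default 1.0 base-equivalent), or
2. it is too abundant to be a one-base error copy of the most abundant
   accepted template within that radius, judged by the Poisson test below
   at level `alpha` (default 0.01).

A candidate at distance exactly 1.0 — the typical signature of a
single-substitution artifact — is *tested*, not waved through; the test
exists precisely for that case. Finally every input read is assigned to
the nearest accepted template (ties to the template with the larger
pre-assignment count, then the lower index) and frequencies are
recomputed. Accepted templates are verbatim input reads; FAD never
averages.

### The offspring abundance test

Under the null, an "offspring" sequence is a pile of reads of a parent
template that all suffered an error at the same single site. The
observed (dereplicated, hence error-free) parent count is corrected to
total molecules by dividing by the error-free fraction `f0`; with errors
uniform over sites the expected number of error copies at one specific
site is

    mu = (parent_count / f0) * mean_errors / mean_length

and the p-value is the Poisson upper tail `P(X >= offspring_count)`,
Bonferroni-multiplied by `mean_length` (the number of sites at which the
offspring could have arisen), capped at 1. `mean_errors` and
`mean_length` are means over the filtered input reads.

## RAD — cluster and average

### Coarse clustering

DP-means — the small-variance deterministic limit of a Dirichlet-process
Gaussian mixture — sweeps through the reads' kmer vectors: an element
joins the nearest centroid closer than the radius λ, otherwise it seeds a
new cluster; centroids are recomputed after each pass until assignments
are stable (cap 100 passes, empty clusters dropped). λ defaults to 0.01
on the scaled distance, matching the expected-error-rate filtering
cutoff: reads further apart than twice the error rate cannot come from
one template.

DP-means is order dependent, and an element that seeds a cluster can
never leave it (its own centroid is at distance zero). The sweep order is
therefore chosen deliberately: reads are processed in order of increasing
expected errors, so centroids are founded by near-noiseless reads and the
noisy tail falls into the template clusters it belongs to. (Processing in
arbitrary order instead freezes the high-error tail into singleton
clusters — hundreds of them at realistic error rates.)

The pruned variant produces the *identical* clustering while skipping
most distance computations: first-pass centroids are clustered into
meta-centroids (radius 4λ — coarse super-clusters keep the bounds tight;
exactness does not depend on this choice), read-to-meta Euclidean
distances are computed once, and the triangle bound
`d(read, centroid) >= |d(read, meta) - d(centroid, meta)|` rules out
centroids provably beyond λ. The scaled distance is monotone in the
Euclidean distance for fixed lengths, so pruning is conservative and
exact; this is asserted against the naive implementation in the tests.

### Fine splitting

Clusters at radius λ cannot separate variants differing by a few bases,
so each cluster is recursively tested for heterogeneity in a
low-dimensional kmer projection:

1. Take the `M = 20` kmer coordinates with the largest count variance
   across the cluster's reads (population variance of raw counts, ties to
   the lower index). Two classes of coordinate are excluded from
   selection outright: *multi-copy* kmers (mean count > 1.5), because
   several loci feed one coordinate and pool noise from all of them while
   diluting any between-variant signal; and the four pure-homopolymer
   kmers, which count nothing but run length — the dominant error mode.
2. Discard coordinates participating in a homopolymer length-edit pair,
   so heavily shared homopolymer indel errors cannot drive a split. A
   pair is flagged by a constructive string test (deleting a run
   character of one kmer yields a prefix/suffix of the other), with the
   candidate's full partner set enumerated constructively — a few tens of
   strings per kmer — rather than searched for within a variance ranking,
   since a partner's variance can be diluted far below any ranking cutoff
   when it is multi-copy or when the candidate aggregates extra noise.
   The string relation alone cannot distinguish a true edit pair from two
   consecutive windows of one and the same haplotype; the decisive signal
   is the Pearson correlation of the pair's counts across reads. A real
   ±1 edit *trades* counts — every loss of one kmer is a gain of the
   other, correlation near −1 — while partners varying through unrelated
   noise (even noise correlated with haplotype structure) sit near zero
   and same-haplotype window pairs correlate positively. A candidate is
   discarded when any partner correlates below −0.35.
3. Project reads onto the `N = 6` highest-variance survivors and run
   DP-means with Euclidean distance and radius 1.2. Projected
   coordinates are integer counts: reads from one template sit at
   distance 0 or 1 (one perturbed kmer) from their pattern, reads
   differing at two or more selected kmers sit at ≥ sqrt(2) ≈ 1.41. The
   radius is placed strictly between those lattice values so a single
   noisy kmer never separates a read, two template-level differences
   always do, and fractional centroid drift cannot flip either decision.
   Reads are fed to DP-means in descending projected-pattern abundance so
   dense patterns seed the centroids (a rare multi-kmer deviant processed
   first would otherwise attract single-kmer deviants lying half-way
   between it and the dominant pattern).
4. Judge each non-largest candidate sub-cluster with the same Poisson
   machinery as FAD, with the parent abundance set to the whole cluster
   being split (under the null all its reads are one template; cluster
   sizes already count all molecules, so no `f0` correction applies).
   Sub-clusters passing at `alpha` become new clusters; failing shards
   are folded back into the nearest passing sub-cluster. If nothing
   passes the cluster is final. Recursion continues per sub-cluster to a
   depth cap of 20.

### Consensus

Each final cluster is collapsed to a template: the member read whose kmer
vector is nearest the cluster mean serves as a draft; every member is
aligned to it with 30-mer anchor seeding (anchors unique in both
sequences, chained by longest increasing subsequence, gaps filled by
exact edit-distance alignment via edlib; zero anchors fall back to a full
exact alignment). Unanchored end segments are aligned globally — the
pipeline's reads span the full amplicon — and trailing read-only
alignment tails are folded into the final block so voting can extend a
truncated draft end. The draft is then scanned in non-overlapping
15-column blocks; where the reads' modal aligned subsequence (strict
plurality among reads spanning the block; ties keep the draft) differs
from the draft block, the draft is rewritten, and the sweep repeats with
re-alignment up to 3 rounds or a fixed point. Block width, round count
and the plurality rule are this package's choices; non-overlapping blocks
make the sweep deterministic, and re-alignment between rounds lets indel
corrections propagate.

Identical consensus sequences are merged (sizes summed). With
`min_cluster > 1`, clusters below the threshold are not reported; their
reads are assigned to the nearest surviving template so frequencies still
describe the whole read population rather than a filtered subset.

## SMD — comparing weighted populations

For truth A and inference B with frequencies summing to 1, SMD is the
earth mover's distance under the pairwise Levenshtein matrix D:

    SMD = min_F sum_ij F_ij D_ij
    s.t. row sums of F = freq(A), column sums = freq(B), F >= 0

solved as a dense transportation LP (scipy HiGHS; inputs must already be
normalized within 1e-6, and both marginals are rescaled to sum exactly 1
for solver conditioning). SMD reads as the average number of nucleotide
changes per sequence separating the populations; computed between
templates and their raw reads it estimates the mean per-read error count,
biased slightly low because co-occurring errors can partially cancel in
edit distance. The one-sided relaxations decompose into nearest-neighbour
sums: `SMD_FP = sum_j freq(B_j) min_i D_ij` (grows with spurious
inferences) and `SMD_FN = sum_i freq(A_i) min_j D_ij` (grows with missed
truths). The flow minimizer is generally non-unique; only the objective
is meaningful, and tests assert on it alone.

## Simulator

The generator emulates the dominant CCS error structure: independent
per-base substitutions at `sub_rate`, plus at each homopolymer run of
length r one candidate ±1-unit length change with probability
`min(1, indel_base_rate * r)` — indels live in runs and their rate grows
linearly with run length. Every base belongs to exactly one run, so the
expected indel count per read is close to `indel_base_rate * L` and the
total per-base error rate is approximately `sub_rate + indel_base_rate`.
`rate_spread` draws a per-read rate multiplier uniformly from
`[1 - spread, 1]`, emulating the read-to-read accuracy variation that
pass-number differences produce in CCS data; a spread of zero instead
puts every read exactly at the nominal rate. Quality strings are
constant-Phred per read, derived from that read's realized rate, so
quality-predicted and realized expected errors agree in distribution —
the denoisers consume only aggregate expected errors, so per-base quality
variation is deliberately not modelled.

Canned mock communities (`mvc_fixture`) use a fixed pseudo-random 2600-bp
seed sequence and exact per-template coverage (so metric scores reflect
reconstruction error, not multinomial sampling noise):

- `low_error`: 20 templates (pairwise ≥ 3 edits; 10 substitutions and 3
  indels each relative to the seed), 100 reads each, total error
  3.75e-4/base split 20% substitutions / 80% homopolymer indels. This
  puts the error-free fraction at `exp(-0.975) ≈ 0.38`, the value
  reported for real 2.6-kb CCS data filtered at the 1% threshold.
- `high_error`: 10 templates, 200 reads each, nominal 1%/base indel-heavy
  error with spread 0.75 — a population *filtered at* the 1% cutoff.
- `single_base_pair`: two templates differing by exactly one
  substitution, 500 reads each, low-error profile.

What passing these benchmarks does **not** show: the simulator has no
chimeras, no read-length variation or fragments, no per-base quality
structure, no context-specific substitution spectrum, and its indel model
allows at most one length change per run per read. Real datasets add all
of those, plus primer/barcode artifacts that must be trimmed upstream.

## Numerical and degenerate-input choices

- Dereplication is exact full-length string identity; ordering is count
  descending, ties lexicographic, making every downstream walk
  deterministic.
- DP-means stops when an assignment pass changes nothing (cap 100
  passes); empty clusters are dropped and labels compacted in order of
  first appearance.
- Nearest-template assignment breaks distance ties toward the template
  with the larger pre-assignment count, then the lower index.
- `offspring_pvalue` with an expected rate of zero returns 0 for any
  non-empty offspring (any observation contradicts a zero-rate null) and
  1 for an empty one.
- Quality encoding is fixed Phred+33; malformed FASTQ records raise an
  error naming the record. `N` bases are allowed and simply contribute no
  kmer windows.
- Benchmark problem sizes (2.6-kb templates, 1000–2000-read communities,
  10 high-error replicates, 100 consensus clusters) were chosen as the
  smallest sizes at which the statistical claims are meaningful at their
  stated thresholds.

## Known limitations

- FAD requires duplicated (error-free) reads; it refuses datasets without
  them and recommends RAD.
- The fine splitter cannot separate variants whose only difference is a
  homopolymer run length — by design, since such differences are
  indistinguishable from the dominant error mode at the kmer level.
- RAD's coarse stage can leave reads whose realized error rate pushes
  their kmer deviation beyond λ as singleton clusters; `min_cluster=2`
  re-homes them but a heavily contaminated dataset would deserve stricter
  upstream filtering.
- In the low-error regime a handful of reads sharing the same indel
  occasionally survive splitting as a small (few-read) cluster when the
  shared coordinates fall just outside the homopolymer-pair exclusion,
  yielding a low-abundance false-positive template one edit from a true
  one (roughly one fixture seed in ten). Abundance-aware downstream
  filtering removes these.
- SMD solves a dense LP; populations beyond a few thousand sequences per
  side become slow and memory-hungry.
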