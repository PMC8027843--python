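# Methods

## Genome-graph model

A genome graph stores one record per reverse-complement pair: segments
(each usable forward, `+s`, or reverse-complement, `-s`) and undirected
edges between segment *sides* (`L` facing lower coordinates, `R`
higher). Edge kinds are reference (genome adjacency), variant
(junction; a fold-back is a self-loop on one side, contributing two
copies to that side's balance sum per edge copy), and loose
(single-sided). Chromosome ends are telomeric termini. Because the
quotient is stored, the symmetry constraints κ(v)=κ(v̄), κ(e)=κ(ē) hold
by construction and `reverse_complement` is the involution that swaps
each edge's traversal direction.

Junction balance is enforced at **every non-telomeric side**, including
the inner sides of terminal segments: each copy of a segment must have
a neighbor on each side except across a telomere. A vertex-level
statement restricted to fully-interior segments would leave edges
attached to terminal segments unconstrained and makes simple supported
events (a deletion between the two outermost segments) unrecoverable;
the side-level form is the stoichiometry the model intends.

A loose edge is attached to every non-telomeric side when the prototype
is built. Loose ends are the model's slack: without them, any
copy-number step lacking a junction (arm loss, a dropped-out junction)
would make the program infeasible. The penalties keep them at zero
wherever the data can be explained without them.

The prototype graph is the disjoint refinement of all clones'
breakpoints plus the breakends of the deduplicated union of junction
calls; clone graphs are replicas, so the projection p is the identity
on element ids. Junction deduplication is exact by breakend
coordinates and strands by default; a ±N bp merge window is available
but off (0), since no positional tolerance is inherent to the model.

## Joint copy-number inference

The objective is λ·R + Σᵢ Vᵢ with

* Vᵢ = Σ_v w_v (x̄_v − κ(v))², the bin-count-weighted squared error
  between each segment's mean bin depth (already in copy-number units)
  and its integer copy number;
* R = number of unique prototype loose edges whose total copy across
  clones is nonzero (ℓ0), encoded with one binary z_e per prototype
  loose edge and a big-M row Σᵢ κⁱ(ê) ≤ n·cn_cap·z_e.

Single-sample mode replaces λ·R with a per-copy slack penalty on loose
ends (default 500; 100 is the documented alternative for noisier
material). The joint weight defaults to λ = 100.

The quadratic residual is linearized **exactly** by one-hot encoding
κ(v) over {0..cn_cap}; the whole program is then a MILP solved by HiGHS
(`scipy.optimize.milp`) to proven optimality (`mip_rel_gap = 0`).
`cn_cap` defaults to ⌈max segment mean⌉+2 and errors if below the
observed rounded depth. Among equal-objective optima, a tiny uniform
per-copy cost (1e-7 per edge copy and per vertex copy unit) prefers the
assignment with minimal total copy; together with HiGHS's determinism
this makes solutions reproducible. (A strict lexicographic tie-break
is not implementable with bounded MILP coefficients; the minimal-total
rule is this package's deterministic substitute.)

Edge upper bounds u are {0, ∞}: reference and loose edges are always
unbounded, a variant edge is open in a clone iff its junction has at
least `min_support` supporting read pairs there (default 1). A
junction reaching support nowhere is treated as never called and
excluded from the prototype.

An exhaustive reference solver (`crisisgraph.exhaustive`) enumerates
every feasible integer assignment on small instances, exploiting the
fact that, given vertex and variant-edge copies, each reference edge's
optimal value is the minimum of its two sides' residual demands (which
yields the inclusion-minimal nonzero-loose set, optimal for both ℓ0 and
slack objectives). It validates the MILP on random toys in the test
suite and acceptance script.

## Walk decomposition and haplotypes

Minimal walks are **oriented-vertex-simple**: no signed vertex `±s` is
revisited within one walk. Plain segment-simplicity would make
fold-back graphs undecomposable (any traversal of a fold-back self-loop
visits its segment in both orientations), which is exactly the
structure BFB creates. Correspondingly δ(x, h) is an element
multiplicity (an edge can be traversed once per direction) rather than
a 0/1 indicator; conservation Σ_h φ(h)·δ(x,h) = κ(x) is unchanged.
Paths run between end sides — telomeric termini, loose ends carrying
copy, or the boundary of a restricted region — and cycles are closed;
every walk is stored in canonical orientation (lexicographically
smaller of the two reverse-complement readings; cycles additionally
minimized over rotations), which is also the prototype identity for
the joint objective.

The copy assignment minimizes the number of unique prototype walks used
across the compendium (binary indicator per prototype walk, big-M
coupling) subject to exact conservation for every segment — terminal
segments included, so haplotypes account for full dosage — and every
edge, loose ends included. When walks were enumerated under a region
restriction, conservation is required only of in-region elements.

`combine_walks` splices cycles into paths at an explicit anchor
occurrence — an ordered, user-supplied record of the manual curation
step that turns a parsimonious decomposition into BFB haplotypes;
each splice consumes one cycle traversal per path copy.
`search_merge_recipe` is a bounded breadth-first search used in
validation to confirm a planted allele is reachable by splicing; the
pipeline itself never infers merges.

Enumeration is capped (`max_walks`, default 10,000) and raises with
guidance to restrict the region; the analyses here restrict to the
rearranged arm (12p in the default scenario).

## Depth operations

Bin collapse takes the median within tiles (robust to single-bin
outliers; trailing partial tiles use available bins). Noisy-region
masking flags a 100-kbp window in a clone when the population standard
deviation (divisor n, for determinism) of bin values over the window
mean exceeds 0.3, and masks bins recurrent in >10% of the cohort; an
external low-quality BED and a separate reference cohort for mask
derivation are both supported. Clustering is Ward on Euclidean
distances over unmasked bins — scipy's `ward` on observation rows,
which matches R's `ward.D2` (squared-distance update on non-squared
Euclidean input). k is a parameter (no automatic selection), mirroring
choice-by-dendrogram-inspection.

Copy-number change points for graph segmentation are detected where
flanking 5-bin median windows differ by ≥ 0.6 CN, with the exact
boundary placed at the largest single-bin jump within a candidate run;
detections within 3 bins of a junction breakend are suppressed as
duplicates.

## SNV phylogeny

Sites are hard-filtered (mapping-quality and caller-score flags carried
as input booleans, total ALT count strictly > 4). Presence is a
two-component binomial mixture: prior π = aggregated ALT fraction
across clones (clamped to [1e-6, 1−1e-6]), likelihoods Binom(alt;
depth, p_present=0.5) vs Binom(alt; depth, p_absent=0.001) — the VAF of
a clonal heterozygous variant in a pure near-diploid clone vs
sequencing error; the source analysis does not state the
under-absence likelihood, and this mixture is the declared reading.
Zero-depth entries fall back to the prior; calls binarize at 0.5.

The tree is classical neighbor joining (scikit-bio) on
symmetric-difference counts between binary presence rows — the natural
additive distance under a no-recurrence model; negative branch lengths
are clamped to zero. Each unrooted branch defines a clone-incidence
vector (both orientations considered); an SNV links to the
argmin-Jaccard branch iff its distance is strictly below 0.1, ties
broken by branch id. Rainfall clusters are maximal runs of ≥2 SNVs
with successive gaps strictly below 2 kbp, annotated with their G/C
reference-base count.

## Allelic phasing

Heterozygous parental sites have VAF strictly inside (0.3, 0.7) at
depth ≥ 10 (the depth floor stabilizes the VAF estimate; the source
used curated germline loci without a stated cut). Phasing uses a clone
with single-allele loss of the region: the zero-count allele is L
(lost), the other R (retained); sites with neither or both alleles zero
remain unphased and flagged. Absolute allelic copy number divides L/R
counts by the per-clone mean heterozygous allele count over sites
**outside** the region of interest — excluding the event region from
the normalizer avoids circularity and is this package's documented
deviation from a plain genome-wide mean.

## Telomere-motif screen

The 12-bp repeat TTAGGGTTAGGG has period 6, so its distinct cyclic
rotations number 6 (12 with reverse complements) — a count of "11
permutations" cannot be reproduced from that motif and the set is
config-driven with the 12-string default. Counting is overlapping
window membership; N never matches. A loose end is a neo-telomere
candidate iff ≥ `min_reads` (default 3) mate sequences each contain ≥
`min_count` (default 1) motif hits, else repetitive/unresolved.
Assembly and realignment of mates are outside this package; it consumes
extracted sequences.

## Synthetic crisis compendia

The generator's defaults define the study conditions used throughout
the tests and the acceptance script:

* Genome: a 120-Mbp "12"-like chromosome (p-arm distal to 35 Mbp) and a
  45-Mbp acrocentric "21"-like partner; 10-kbp depth bins; all event
  coordinates snapped to bin width so truth copy number is piecewise
  constant on bins.
* BFB is truncate-and-mirror on the L-allele walk ordered from its
  stable telomere: a break interior to the terminal span discards the
  distal part and appends the reverse complement of the retained walk
  (sister fusion), so the region proximal to the fold-back focus
  carries 2ᵏ allele copies after k cycles. A stabilizing fusion
  truncates once more and captures an intact partner-arm walk
  (breakpoint 6 Mbp into the partner, so the acquired arm is a
  substantial, detectable gain).
* Default 13-clone compendium on a fully binary lineage (binary so the
  planted topology is NJ-identifiable): 2 unrearranged, 2 arm-loss
  (the phasing loss clones), 1 chromothripsis (12 fragments over
  5–20 Mbp, retain 0.5, shuffled and re-oriented), 3 early-BFB (one
  fold-back at 8.0 Mbp then fusion), 5 late-BFB (fold-backs at 8.0,
  8.7, 9.4 Mbp then the same fusion — allele staircase 8/4/2).
* Depth = true total copy + Gaussian noise (sd 0.15 CN by default),
  truncated at 0 — emulating corrected, normalized coverage, the
  pipeline's actual input, not raw Poisson counts. Junction support ~
  Poisson(15 × junction copy), zeroed with dropout probability (or
  forced for named junctions), creating loose ends. 200 SNVs per
  branch at ~60× depth, VAF 0.5, per-entry presence-error 0.5%,
  sequencing-error ALT rate 0.001; a 3-SNV G/C cluster is planted
  within 2 kbp of the first fold-back locus. Parental het SNPs every
  4 kbp on the "12" chromosome at 40× per haplotype (the q arm
  provides an abundant balanced normalizer); the lost allele of the
  arm-loss clone has Poisson mean 0, so its counts are exactly zero.
* A 118-clone depth-only cohort spans six archetypes (unrearranged,
  21q gain, arm loss, early BFB, extended BFB, chromothripsis) for
  clustering.

What the simulator does **not** emulate — and hence what passing tests
do not establish about real data: GC/mappability structure and wave
artifacts in coverage, mapping ambiguity near repeats (junction
breakends are exact), subclonality and contamination (clones are 100%
pure), replication timing, SV-caller breakend jitter, and
sequence-level context (no reads; loose-end mates are random strings
unless telomeric content is requested).

## Problem sizes and numerics

Acceptance-scale runs use the 13-clone default scenario (~60–80
prototype segments after refinement, cn_cap 12: roughly 10⁴ binaries
per joint fit), 50 random toy compendia (≤6 segments, ≤3 variant edges,
≤3 clones, cap 4) checked against exhaustive enumeration, and the
118-clone cohort for clustering — sizes chosen so the full suite
resolves to proven optimality in minutes on one core while preserving
every structural feature of the method (shared fold-backs, staircases,
dropout-induced loose ends, polyclonal lineages). Floating-point
comparisons in tests use absolute tolerances ≤ 1e-4 against exact
oracle values; the MILP gap is 0 and all reported objectives are
recomputed from the returned integer assignment rather than read off
the solver.

## Known limitations

* True lexicographic tie-breaking among equal optima is approximated by
  a minimal-total-copy preference (see above).
* The exhaustive enumerator assumes prototype-shaped graphs (one
  reference edge per interior boundary, ≤1 loose edge per side); it is
  a validation tool, not a general solver.
* Region-restricted walk decomposition treats region-boundary sides as
  walk ends; alleles extending beyond the region are reconstructed only
  within it.
* The presence model assumes a diploid-clonal VAF of 0.5 everywhere; in
  highly amplified regions the true VAF departs from 0.5 and posterior
  calibration degrades (the hard ALT-count filter absorbs most of
  this at tested depths).
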