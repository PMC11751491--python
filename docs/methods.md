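# Methods

## Sparsification model

A diet pattern *P* ∈ {0,1}^p with weight *x* ≥ 1 is treated as the shortest
repeating unit of an infinite mask. Applying *P* at shift *s* to a sequence
keeps base *i* iff `P[(i + s) mod p] = 1`; the kept bases form the patterned
sequence together with a strictly increasing map back to original
coordinates. The reduction ratio β = p/x is exact over whole periods, so an
index built over the patterned sequence holds ≈ x/p of the entries of an
unpatterned one — this is the quantity the acceptance script measures.

The rotation convention ("shift by *s* means the mask at original position
*i* is `bits[(i+s) mod p]`") is used identically for reference masking
(always *s* = 0) and for the read-side shift search, so a read sampled at
reference offset *o* phases correctly exactly when its shift satisfies
*a* ≡ *o* (mod *p*).

## Seeding

Sequences are 2-bit encoded (A=0, C=1, G=2, T=3); N positions are recorded
separately and their code slot is never read. Each k-mer is packed into a
64-bit word (k ≤ 28, upper bits reserved), canonicalized to the smaller of
its forward and reverse-complement packing, and hashed with Thomas Wang's
invertible 64-bit finalizer masked to 2k bits. Within every window of *w*
consecutive k-mers the k-mer(s) of minimal hash are emitted — ties keep all
tied k-mers, preserving the scheme's window guarantee; palindromic k-mers
are skipped as strand-ambiguous; any window overlapping an N emits nothing
and scanning restarts after it. On random sequence the expected density is
2/(w+1) minimizers per *patterned* base.

Seed positions are always original coordinates of the seed's first included
base, and each seed also records its original-coordinate span (k·β bases for
regular patterns), which the reverse-strand geometry needs.

## Index

All (hash, reference, position, strand, span) records are appended to flat
arrays, sorted once by (hash, reference, position), grouped, and wrapped
with an O(1) hash → slice lookup. References are processed in batches of at
most `batch_bases` original bases; longer references are split on
pattern-period boundaries with a (k+w)·p overlap so every minimizer window
of the unsplit sequence lies wholly inside some chunk, and boundary
duplicates are dropped. Hashes with more than `max_occ` (default 500)
locations are masked at query time and contribute 0 to occurrence sums.
The saved index is a versioned container (params JSON + arrays); the magic
and version are checked on load, and indexes built with `--idx-no-seq` drop
the sequences, making later base-level alignment unavailable by design.

## Pattern alignment and voting

For each shift *s* the read is sparsified, at most *t* = 10 minimizers are
taken from its prefix, and their index occurrences are summed per occurrence
(hyper-frequent seeds count 0 so they cannot dominate). The argmax shift
wins; ties break to the smallest shift, and an all-zero sum yields 0. The
shift is chosen on the forward read only: seeds are canonical, so both
strands contribute to the sums. For symmetric patterns such as "10" the
reverse strand phases onto one of the same p shifts, which the search covers.

Matches are adjusted to Δ = ref_pos − read_pos, with reverse-strand read
positions measured from the reverse-complemented read
(`read_len − pos − span`), keeping Δ additive on both strands. Per-seed
location lists arrive sorted, are k-way merged per strand (equivalent by
construction to a comparison sort of the concatenation, which the tests
assert), and deduplicated. Greedy left-to-right clustering then anchors a
cluster at the first delta and absorbs every later delta within *D* on the
same reference; clusters with ≥ *V* votes win, ranked by votes (ties to the
smaller anchor) and capped at 50. When nothing reaches *V*, the single
best-voted cluster is rescued so the read is not lost; a read with no hits
at all is reported unmapped.

Mode presets: short reads use whole-read voting with D = 0.1·len + 50 and
V = 2 followed by global alignment; HiFi/ONT use subsequence pairs with
D = 500/1000 and V = 3 followed by local alignment per pair. Ultra-long
reads are processed in 30 kb segments whose candidates are lifted back to
whole-read coordinates; segment-local pair padding is clamped to the segment
so adjacent segments merge by gap bridging rather than overlapping.

## Alignment

Both kernels are affine-gap banded DP (default scoring match 2, mismatch 4,
gap open 4, extend 2) with cells restricted to |j − i| ≤ band + |n − m|, so
the terminal cell is always reachable and a band ≥ len(a)+len(b) reproduces
the unbanded optimum (asserted against a full-matrix oracle). The band is
the cluster's voting spread plus a margin of 2·⌈0.01·len⌉ + 16, since
consecutive indels are what separate matching seeds' deltas. Equal-length
candidate segments are compared directly first; identical ones get a perfect
`<len>M` record with no DP. Boundary deletions are trimmed from CIGARs into
the mapping position; local alignments soft-clip unaligned read ends. For
long reads, per-pair alignments on the same reference and strand whose
reference gap is ≤ 50 kb are concatenated: small double-sided gaps
(≤ 2·band each) are bridged by a global sub-alignment, anything else becomes
pure I/D runs; more distant pairs stay separate records. The best-scoring
record is primary; others are supplementary when shorter than 80% of the
primary's aligned read length, else secondary.

MAPQ is a deterministic surrogate (flagged in the SAM header):
`clamp(round(40·(1 − second/best)·min(1, votes/10) + 20·identity), 0, 60)`.
It preserves the usual semantics — 60 for unique near-perfect hits, ≤ 20
when two candidates tie — without claiming calibration against any
empirical table.

## Containment and profiling

Containment disables alignment entirely: a read tallies to the reference of
its top vote cluster iff that cluster reaches *V* (ties on votes go to the
smallest reference id), or to its best cluster unconditionally in recovery
mode. Coverage is mapped-base sum / reference length — a deliberate, simple
estimator. Desk-scale acceptance thresholds default to ≥ 50 mapped reads
and ≥ 0.05 coverage (the production-scale analogues, 100 000 reads and 1×,
are a flag away). Relative abundance is the mapped-read proportion over
accepted references; profile quality is presence/absence F1 (standard
precision/recall harmonic mean) and L1 = Σ|truth − predicted| over the
taxon union.

## Seeding benchmark

Pairs are a random sequence and a copy with exactly *n* substitutions
(*n* uniform on [0, max_subs]; the uniform choice is ours — the original
"random number of substitutions" distribution is unspecified, so reported
acceptance percentages are run-specific and not comparable). Edit distance
is unit-cost NW (edlib). Rates use set membership of canonical hashes: the
fraction of the mutated copy's seeds present among the original's. Spaced
masks for weights 13/18/21 are literature presets; other weights derive a
mask by repeating the diet pattern until it holds k ones. The acceptance
threshold at an edit-distance cutoff is the minimum rate among qualifying
pairs, which makes false negatives impossible by construction — the tests
assert this per run, alongside the diagnostic that diet-seed rates fall
monotonically with edit distance (Spearman ρ < −0.5 at pattern "10", k=8).

## Synthetic data

`simulate_genome` draws i.i.d. bases at a stated GC; `simulate_reads` draws
uniform origins (multi-genome sets weighted by length), 50/50 strand,
i.i.d. substitutions, and indel events at a per-base rate with
geometric(0.5) lengths, truth encoded in read names. This emulates the
error *geometry* of short/HiFi reads but none of the structure of real
data — no repeats, no coverage or GC bias, no quality-correlated errors, no
homopolymer artifacts — so passing recovery tests demonstrates algorithmic
correctness on homogeneous sequence, not performance on real genomes, where
repetitive structure would raise multi-mapping rates.

Problem sizes used by the tests and the acceptance script — 1 Mb for index
scaling, 500 kb genomes with 2 500-read sets per condition for mapping
recovery, 500 benchmark pairs, a 5+5-genome community of 200 kb genomes at
10× with 1 kb reads (0.2% substitutions) for containment — are chosen so
the statistics of interest stabilise (binomial CIs well inside the asserted
margins) while the whole suite stays desk-sized.

## Known limitations

Asymmetric patterns degrade reverse-strand phasing (the reversed mask need
not be a shift of itself); pattern "10" — also the best performer in the
underlying mechanism — avoids this. Vote counting quantifies seed count,
not within-seed base agreement, so highly diverged regions can attract
spurious candidates that alignment must filter. MAPQ is uncalibrated. The
implementation is single-threaded Python/numpy with numba DP kernels;
semantics, not raw speed, are the target.
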