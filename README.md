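# dietmap

Sparsified-genomics sequence analysis: read mapping, containment search, and
seeding benchmarks over *diet-pattern* sparsified sequences.

## The idea

Indexing and seeding dominate the cost of many genomics pipelines, and every
standard approach (minimizers, spaced seeds, syncmers, …) first touches
*every* base of both the reference and the reads. `dietmap` instead applies a
short repeating binary pattern *P* — the **diet pattern** — to the sequence
itself: wherever the repetition of *P* holds a 1 the base is kept, wherever
it holds a 0 the base is dropped. A pattern of length *p* and weight *x*
(count of 1s) shrinks a sequence by the reduction ratio

    β = p / x            (e.g. "10" → β = 2: half the bases survive)

Double-strand (*w*, *k*)-minimizers are then extracted from the *patterned*
sequence, but every seed is stored at its **original** coordinate, so mapping
positions never need translating back.

Reads are sampled at unknown offsets, so the read's mask must be phased
against the reference's: for each shift *s* ∈ [0, *p*) the read is sparsified
at that shift and a capped number of minimizers is looked up in the index;
the shift with the highest summed occurrence — the **alignment index**
*a* — wins. Matching locations are clustered by **location voting**: each
seed match votes with its position difference Δ = ref_pos − read_pos, deltas
within a distance *D* of a cluster anchor pool their votes, and clusters with
at least *V* votes become candidate mappings (no seed chaining anywhere).
Winners are aligned base-level with banded affine-gap DP — the cluster's
voting spread sets the band — and reported as SAM or PAF with
primary/secondary/supplementary classification.

The same voting machinery powers an alignment-free **containment search**
(which references does a read set cover, with read counts, coverage and
relative abundances) and a four-way **seeding benchmark** comparing all
overlapping seeds, minimizers, spaced seeds, and diet seeds by their seed
matching rate versus Levenshtein distance.

## Worked example

```sh
# a 100 kb random genome and 1,000 error-free 150 b reads with known truth
dietmap simulate --length 100000 --n-reads 1000 --read-length 150 --out-prefix toy
# [dietmap] wrote toy.fa (100000 bases) and toy.reads.fa (1000 reads)

# index it with the half-diet pattern "10" (k=19, w=16) and map the reads
dietmap index toy.fa -o toy.gdi --pattern 10
# [dietmap] indexed 1 reference(s): 5867 distinct seeds, 5867 locations, density 0.0587
# [dietmap] wrote toy.gdi
dietmap map toy.gdi toy.reads.fa --out toy.sam
# [dietmap] 1000 reads, 1000 mapped (primary), 1000 records
```

The density line says the patterned index holds ≈0.059 seeds per original
base — half the ≈0.118 = 2/(w+1) expected of an unpatterned minimizer index,
exactly the β = 2 saving of pattern "10". The first SAM line reads:

```
sim0|ref=ref|pos=75404|strand=+|ed=0  0  ref  75405  48  150M  *  0  0  <seq>  *  NM:i:0  AS:i:300
```

The read simulated from position 75404 maps exactly there (SAM is 1-based),
with a perfect 150M CIGAR and zero mismatches; MAPQ 48 reflects that a 150 b
read contributes only ~7 sparsified seed votes (the confidence term saturates
at 10 votes — see `docs/methods.md`).

Programmatic use mirrors the CLI:

```python
import dietmap as dm

genome = dm.simulate_genome(100_000, seed=1)
idx = dm.build_index([genome], dm.parse_pattern("10"), k=19, w=16)
mapper = dm.ReadMapper(idx, mode="sr")
records = mapper.map_read("r1", genome[1][5000:5150])
print(records[0].pos, records[0].cigar)   # 5001 150M
```

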