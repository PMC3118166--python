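# pyromap

FM-index seed-and-extend mapping of 454 / GS FLX pyrosequencing reads to
a reference genome, plus a homopolymer-aware read simulator and a
truth-based evaluation harness.

Pyrosequencing reads one homopolymer per flow, so its dominant errors are
small insertions and deletions of repeated bases; substitutions are rare.
In a re-sequencing project the correct alignment of a read is therefore
mostly long exact matches interrupted by short divergent spots.
`pyromap` indexes the reference with a Burrows–Wheeler/FM-index, greedily
decomposes each read `r = s₁a₁s₂a₂⋯sₖaₖ` into maximal exact-match seeds
`sᵢ` with homopolymer-aware skip rules, groups seed occurrences
`p₁ ≤ p₂ ≤ …` into *coherent* chains (reference distances matching read
distances within slack ε), and finishes the largest candidates with a
banded Needleman–Wunsch / Gotoh affine-gap DP: global between anchors,
semi-global at the read ends.  A mapping is accepted when its identity
(matches / alignment columns) reaches a threshold *t*, or when its error
count (mismatches + gap bases) stays within a budget *e*.

The scientific details — skip rules, the rarest-informative-prefix
anchoring that keeps true loci reachable at high error rates, slack and
band policies, the simulator's per-homopolymer error model — are in
[docs/methods.md](docs/methods.md).

## Worked example

The package ships a small constructed instance: a 15-base read
`AAAAGCCCTAGGGTT` derived from a template planted at reference position
101 (1-based) with one inserted base at read position 5 and one
substituted base at read position 9, plus a decoy occurrence of the
second seed at position 201.

```python
import pyromap as pm
from pyromap.fixtures import fig2b, fig2b_config

ex = fig2b()
bundle = pm.IndexBundle.build(pm.encode_reference(ex.records))
cfg = fig2b_config()

seeds = pm.extract_seeds(ex.read, bundle.searcher, cfg.seeding)
print([(s.read_start, s.length) for s in seeds.seeds])
# [(0, 4), (5, 4), (10, 5)]            seeds AAAA, CCCT, GGGTT

occs = pm.collect_occurrences(seeds, bundle, cfg.seeding.max_occ)
chains = pm.chain_occurrences(occs, seeds, cfg.chaining)
print([( [o.seed_index for o in c.occurrences], c.span) for c in chains])
# [([0, 2], 9), ([1], 4)]              s1+s3 cohere (9 bases); s2 is the decoy

m = pm.map_read(ex.read, bundle, cfg)[0]
print(m.ref_start + 1, m.cigar_string, round(m.identity, 3))
# 101 4=1I3=1X6= 0.867
```

The first and third seeds form a coherent chain spanning 9 seed bases,
beating the decoy; extension fills the gap and recovers position 101
with one insertion and one mismatch (identity 13/15 ≈ 86.7%).

## Command line

```bash
pyromap index ref.fasta -o ref.idx
pyromap map ref.idx reads.fastq -t 50 --report best -o out.sam
pyromap simulate ref.fasta --n 2000 --psub 0.05 --pins 0.05 --pdel 0.05 \
        --seed 7 -o reads.fasta --truth truth.tsv
pyromap evaluate out.sam truth.tsv --tolerance 10
pyromap fixture fig2b -o fixtures/
```

SAM output uses `=`/`X`/`I`/`D` CIGAR operators and an `NM` tag; the
truth table is tab-separated text (read id, record, start, length,
strand, error tallies).

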