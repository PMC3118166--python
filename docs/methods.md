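# Methods

`pyromap` maps GS FLX / 454 pyrosequencing reads to a reference sequence
for re-sequencing applications, and ships the synthetic read generator
used to evaluate it.  This note documents the model, the numerical
choices, the parameters that matter, and the limits of what the tests
demonstrate.

## The mapping model

Pyrosequencing reads one maximal homopolymer (run of identical bases) per
flow.  Its characteristic errors are homopolymer length over- and
under-calls — small insertions and deletions of repeated bases — with
substitutions comparatively rare.  At the error rates typical of
re-sequencing projects, a correct alignment is therefore mostly long
exact-match stretches separated by short, possibly gapped, divergent
spots.  The mapper exploits this shape in four stages.

**Indexing.**  The reference records are uppercased and concatenated into
one sentinel-terminated text.  Runs of non-ACGT symbols are replaced by
separator symbols that split records into *segments*; separators sort
below every base and never match a read symbol, so no alignment can cross
an ambiguity run or a record boundary, and no sequence is fabricated in
place of `N`s.  The suffix array is built by prefix doubling (numpy
`lexsort` rounds, O(n log² n)), the BWT via `bwt[i] = text[sa[i] − 1]`,
and the FM-index stores per-symbol cumulative counts, checkpointed
occurrence counts for rank (stride 128), and a text-position-sampled
suffix array (stride 32) for locate.  A second FM-index over the reversed
text turns forward longest-prefix matching into plain backward search
(an occurrence of `p` at `i` in the body equals an occurrence of
`reverse(p)` at `n − |p| − i` in the reversed body).  The strides trade
space for time and are configurable; the defaults are conventional.

**Seeding.**  From a cursor, the longest read prefix that occurs exactly
in the reference becomes a seed.  The symbol that blocked the extension
is skipped: if it differs from the last matched symbol the cursor moves
one position past it (a putative substitution), and if it repeats the
last matched symbol the mismatch sits inside a homopolymer (a putative
length miscall), so the cursor jumps to the next homopolymer start.  A
zero-length match advances the cursor by one; a homopolymer that runs to
the read end terminates seeding.

A maximal match, however, can *overshoot* the error that ends the true
exact stretch whenever the slightly-too-long string happens to occur
somewhere else in the genome — in which case the seed's occurrence list
no longer contains the read's true locus at all.  For a 2 Mbp reference
the overshoot probability is near 1 for stretches under ~10 bp, which is
the common case at high error rates.  Each seed therefore also records
its **rarest informative prefix**: the shortest prefix, at least
`min_seed_len` (default 5) long, whose occurrence count is at most
`max_occ` (default 200).  Chains are anchored on the occurrences of that
prefix, with positions where the full maximal match occurs credited at
full length.  Seeds that never become that rare are flagged truncated and
excluded; their read span is recovered by the gap-filling DP.

**Chaining.**  All anchor occurrences are sorted by reference position
and scanned once left to right.  An occurrence extends a chain when the
seed order is respected, both positions lie in the same segment, and the
reference-side gap matches the read-side gap within slack
`ε = max(eps_min, ⌈ρ · gap⌉)` (defaults 8 and 0.25).  The slack grows
with the gap because homopolymer indels make the distance between two
anchors drift like a random walk: at a 10% per-homopolymer indel rate the
drift standard deviation is ≈ √(0.33 · gap), and the defaults cover
roughly three standard deviations.  The scan is linear in the number of
occurrences — never the product of per-seed occurrence counts.

The library exposes the textbook single-pass partition
(`chain_occurrences`: close the chain whenever the next occurrence is
incoherent with its tail), and the mapper's internal path adds two
robustness refinements:

* *bounded lookback* (default 4): an occurrence is appended to the most
  recently active of the last few chains it is coherent with, so one
  chance occurrence that happens to land inside another chain's window
  starts its own singleton without cutting that chain;
* *dense rescue anchoring*: when no chain covers at least
  max(16, len/8) read bases on either strand — heavily corrupted reads
  whose seed cursors all start near errors — anchors are re-derived from
  every homopolymer start of the read (the natural cursor set for
  flow-based sequencing), and chaining is repeated.  The rescue pass
  costs a few milliseconds and fires on a small minority of reads.

Candidates are the `top` chains (default 10) ranked by the number of read
bases their anchors cover, leftmost first on ties.  Extending several
near-ties matters: a short true-locus chain can trail a chance occurrence
by a few bases of span, and the extension error count is the reliable
tie-breaker (a wrong locus costs roughly half the read in errors).

**Extension and acceptance.**  Anchors become all-match runs (anchors
overlapping the previous one on read or reference are dropped greedily).
Between anchors, read and reference gaps are aligned by banded
Needleman–Wunsch with Gotoh's affine-gap recurrences; at the two read
ends the alignment is semi-global — reference overhang beyond the read is
free — against windows of `len + end_slack + 0.25·len` reference bases.
Costs are edit-distance-like: match 0, mismatch 1, gap open 1, gap extend
1 per base, so a length-k gap costs 1 + k.  The band spans the
length-difference corridor padded by `band_pad + 0.125·min(la, lb)`
cells; both the end-window and the band padding grow with segment length
for the same random-walk drift reason as the chain slack.  Tie-breaks are
deterministic: match/mismatch over insertion over deletion.

The stitched edit path consumes the entire read.  Identity is matches
divided by alignment columns (matches + mismatches + inserted + deleted
bases); errors are mismatches plus gap *bases*.  A mapping is accepted if
identity·100 ≥ t (default t = 50) or, alternatively, if errors ≤ e.
Both orientations are always tried (reverse complement mapped against
the forward index); `report=best` keeps the minimum-error mappings
ordered by (errors, leftmost, forward-first), `report=all` keeps every
accepted one.  SAM output uses `=`/`X`/`I`/`D` CIGAR operators so
matches and mismatches are auditable from the record alone, and an
`NM` tag with the error count.

## The read simulator

`generate_read_set` extracts `n_reads` templates from a source sequence:
lengths are Normal(μ_l, σ_l) (defaults 250, 50), rounded and clamped to
[30, source length]; starts are uniform.  Each homopolymer run of the
template then experiences one mutually exclusive event: substitution with
probability `p_sub` (one uniformly chosen base of the run, replaced
according to a 4×4 substitution matrix, uniform 1/3 off-diagonal by
default), insertion with `p_ins` (the run gains k copies of its base),
deletion with `p_del` (the run loses min(k, run length) bases), or
nothing.  Indel lengths follow the truncated power law
P(k) = k^(−γ) / Σ_{j=1..ω} j^(−γ) on {1..ω} (defaults ω = 10, γ = 3 for
both operations).  Reads are forward-strand by default (a flag samples
strands uniformly); every read carries an edit log whose replay against
the template must reproduce it byte for byte.

What the generator deliberately does *not* model: position-dependent
quality decay (real 454 quality drops toward the 3' end), error rates
that grow with homopolymer length, chimeras, or adapter sequence.  Errors
here are uniform along the read and independent of run length.  Passing
the synthetic benchmarks therefore shows robustness to the *rate and
spectrum* of pyrosequencing errors, not to their real positional
structure, and a uniform-random reference is less repetitive than a real
genome, so decoy competition is understated relative to, say, a human
chromosome.

Evaluation counts a read as correctly mapped when its best mapping hits
the true source record and strand within 10 bases of the true origin
(indels shift reported starts; 10 bases absorbs that at these settings).
`matches_per_error` reports pooled base-pair matches per error base
across accepted mappings, with the denominator floored at 1.

## Problem sizes used

The accuracy study in `tests/test_acceptance.py` and
`scripts/acceptance.py` uses a 2 Mbp uniform-random reference and 2,000
reads per error setting (5% and 10% per homopolymer per error type),
mapped at identity threshold 50 — the same generator settings as the
published synthetic benchmark, at a reference scale a single CPU handles
in a couple of minutes.  The banded-vs-unbanded DP comparison uses 100
reads at the 1% setting against a pure-Python unbanded Gotoh oracle.

## Degenerate inputs and edge rules

Empty pattern → full suffix-array interval.  Non-ACGT read symbols never
match and terminate seeds; a read of all `N` yields an empty seed set and
maps nowhere.  A reference record with no ACGT at all is dropped with a
warning; an empty reference is an error.  Reads shorter than the minimum
anchor length can only map through the dense rescue path or not at all.
Windows truncated by a segment boundary penalize the unplaced read bases
as insertions.  All internal coordinates are 0-based half-open; SAM
emission is 1-based.

## Known limitations

* The greedy seed decomposition is heuristic: reads whose every exact
  stretch is shorter than the minimum anchor length go unmapped even if
  a low-identity alignment exists.
* Banded extension is optimal only when the true path stays inside the
  band; the drift-proportional padding makes escapes rare at ≤ 10%
  per-homopolymer error but cannot exclude them.
* Chaining is greedy, not optimal DP; pathological repeat structures can
  split a true chain.  The lookback and rescue mechanisms reduce, not
  eliminate, this.
* Single-threaded by design; paired reads, split/chimeric alignments and
  base-quality-aware scoring are out of scope.
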