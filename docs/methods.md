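# Methods

## Coverage model

A sample that can carry at most `m` distinct variants and yields `n`
sequences is modelled as `n` independent draws over the `m` variants with
equal probability `1/m` — the neutral null in which every template amplifies
and sequences equally well. The genotype-completeness probability

    f(r, m, n) = P(every variant drawn at least r times)

is computed exactly: the number of the `m^n` equally likely outcome strings
giving every category at least `r` draws is accumulated by a big-integer
convolution over categories (`ways[t] = Σ_k C(t, k)·ways_prev[t−k]`,
`k ≥ r`), and the probability is the integer ratio. Threshold solving
(`T1 = min n : 1 − f ≤ α`) compares exact `Fraction`s, so no boundary is
ever decided by floating-point rounding; `f` is nondecreasing in `n`, so a
linear scan from `r·m` terminates. With the defaults `r = 3`, `α = 10⁻³`:
T1 = 19 (m = 2), 46 (m = 4), 104 (m = 8).

`r = 3` is the conventional validation count for this kind of locus (a
variant observed three times is accepted as real); `α = 10⁻³` is the default
tolerated probability of an incomplete genotype. Both are parameters, not
constants. `optimal_multiplex` divides a run's guaranteed read count
(optionally discounted by an expected demultiplexing efficiency) by T1 and
floors — the run-design rule of thumb.

Unequal allele yields (PCR competition) are deliberately not modelled: the
equal-probability multinomial is the null expectation, and the simulator
exposes per-allele weights for studying departures from it.

## Read structure and demultiplexing

A read is `key + forward tag + forward primer + insert + rc(reverse primer)
+ rc(reverse tag)`; reads started from the opposite adaptor show the
mirrored layout with the reverse tag and primer first. The parser tries
both layouts on the read and on its reverse complement; a read matching
more than one distinct interpretation is rejected as `ambiguous` (safety
over yield). Primer matching is full-length and IUPAC-exact by default
(degenerate codes match their degeneracy sets; an `N` in a read matches
nothing narrower than `N`); a relaxed mode requires only the 5′-most `k`
bases (default 10) of each primer, trading stringency for yield. Tag
matching is exact — 3 bp tags admit no error correction, and the resulting
misassignment risk is a documented property of short tags, not of the
parser. Reads shorter than key + both tags + both primers + 1 are
`too_short`. Quality scores are carried but never filtered on; the
procedure filters on structure only.

### Key-homopolymer tag collapse

A tag whose first base equals the key's last base (TCAG + G…) forms a
homopolymer that the basecaller strips together with the key, truncating
the tag by one base and shifting the whole read frame. The parser therefore
treats the 5′ tag position as having two candidate interpretations — a
full-length known tag, or a one-base-short collapsed tag — each validated
by the primer sitting in its frame (a collapsed read can masquerade as a
different full-length tag, so the tag lookup alone is not trusted).
Recovery compares the observation against the hazard-flagged subset of the
tag set on the final two tag bases only (the corrupted read's tail is the
trustworthy part) and succeeds only when exactly one hazard tag agrees;
ties are `homopolymer_unrecoverable`. With 3 bp tags the final two bases
are the whole observed region, so two distinct hazard tags can never
collide; collisions become possible for longer tags.

The simulator emits collapse-affected reads from the opposite adaptor
(`key + rtag[1:] + reverse primer + rc(insert) + …`), which is where the
artifact physically arises; the collapse probability defaults to 0 and is
switched on explicitly where the recovery path is under test.

## Four-step validation

Fixed order, each step consuming the previous step's output, each emitting
an input = removed + retained accounting report:

1. **Pool cleaning.** Variants seen exactly once in the whole pool
   (singletons, scope = pool, matching how pools are processed
   independently) and sequences whose length differs from the expected
   insert by a non-multiple of 3 (reading-frame shifts) are removed. Both
   sub-filters are individually toggleable; length-mod-3 is used as the
   observable proxy for frameshift indels, so legitimate 3 bp indels pass.
2. **Depth filter.** Samples with `N_i < T1(r, m, α)` are removed whole;
   `m` comes from the sample sheet per sample.
3. **Frequency filter.** Within each sample, variants with `F_ij < T2`
   (default 4%) are removed. Frequencies are computed once on the step-2
   counts and removals are simultaneous, not iterative (reproducible and
   order-independent); the comparison is strict (`F_ij` exactly equal to T2
   is retained) and done on exact rationals.
4. **Artifact screen.** Each variant is tested as a single-crossover
   composite `P[:k] + Q[k:]` of the sample's strictly more abundant
   retained variants (chimeras arise between true variants of the same
   sample); the maximal interval of equivalent breakpoints is reported,
   since crossovers between the same flanking differences are
   indistinguishable. If non-target reference sequences are supplied
   (pseudogenes/paralogs known to co-amplify), a variant whose edit
   distance to the closest reference is smaller than to every co-retained
   variant is removed as `other_gene` — a local, offline stand-in for
   database matching. Samples whose depth falls below T1 after removals
   are eliminated (`removed_post_screen`).

Chimera detection uses the equal-length fast path only; variants of this
locus are length-matched once the frameshift filter has run, so
unequal-length candidates yield no call. Multi-breakpoint chimeras are out
of scope.

Surviving samples become genotypes with confidence `f(r, m, N_i)`. Samples
retaining more than `m` variants are flagged, never truncated — excess
variants can be real (unmodelled gene duplication). Artifact classification
for rejected variants applies a fixed precedence: chimera → substitution
(same length, Hamming ≤ 2) → insertion/deletion (1–2 bp net length change,
total edit distance ≤ 2) → other_gene → unknown.

Replicate concordance counts pairs in which both members were genotyped;
discordant pairs where one variant set strictly contains the other are
classed as allelic dropout. The percentage is rounded to the nearest
integer (63 of 66 prints 95%).

## Simulator

The generator emulates the study conditions end to end:

* **Allele pools** — per species, `allele_pool_size` variants (default 30)
  of 171 bp, each 10 substitutions from a species ancestral sequence.
  Mutual similarity of alleles is essential realism: the chimera and
  paralog screens exploit exactly that structure. Off-target sequences
  (default 3) are 60 substitutions from the ancestor, emulating diverged
  pseudogenes/paralogs.
* **Genotypes** — each sample draws `m` alleles uniformly *with
  replacement*; duplicate draws yield homozygotes at rate ≈ 1/pool size.
* **Depth** — negative binomial (gamma–Poisson) with mean 80 and shape 5
  by default, matching the wide per-sample spread seen on real runs
  (per-pool means around 66–83 with minima near 0); a fixed depth and a
  lower truncation are available.
* **Artifact spectrum** — each read draws a class from the normalised
  84/6/2/4/6/1 spectrum (true, 1–2 bp substitutions, 1–2 bp insertions,
  1–2 bp deletions, single-crossover chimeras, off-target). Per-sample
  variability around those means is produced by depth dispersion and
  per-read sampling rather than modelled separately. A chimera drawn for a
  single-allele sample is re-drawn as true and counted.
* **Heterozygote balance** — 50:50 in expectation; optional per-allele
  weights expose PCR-competition skew.

What the simulator does *not* model: flowgram-level homopolymer run-length
noise (beyond the tag collapse), quality-score realism, per-base error
hotspots, tag-specific amplification bias, spatial/region effects.
Passing tests on simulated data therefore demonstrate the pipeline's logic
and thresholds under the documented artifact spectrum, not performance on
any particular instrument run.

## Problem sizes and numerical choices

The end-to-end stochastic check runs 200 diploid single-copy samples at
negative-binomial depth (mean 80, truncated at T1 = 19) with the default
spectrum — about 17,000 reads — and requires ≥ 95% of samples to receive
exactly their true genotype; property suites run on 40-sample runs. These
sizes keep the whole suite interactive while leaving the class fractions
and depth spread at their realistic values.

Determinism: all randomness flows from one integer seed through
`numpy.random.Generator`; read emission derives a child stream from
`(seed, 1)`. Ties in variant ordering are broken by count then sequence;
chimera parent pairs are scanned in sorted order and the widest breakpoint
interval wins. Degenerate inputs (empty read files, unknown pools, empty
tag sets, T2 outside (0, 1)) raise named errors rather than producing
partial output.

## Known limitations

* 3 bp tags admit no mismatch tolerance; a sequencing error inside a tag
  silently misassigns or rejects the read.
* The paralog screen needs user-supplied non-target references; without
  them only chimeras are screened in step 4.
* The equal-probability multinomial understates required depth when allele
  amplification is skewed; choose a conservative α (the 10⁻³ default) or
  model skew explicitly with the simulator's allele weights.
* Pool-wide singleton removal can discard a real variant present in a
  single sequence of a shallow pool; the sub-filter is toggleable for
  small datasets.
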