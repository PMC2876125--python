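"""Four-step validation of demultiplexed amplicon variants.

Step 1 cleans the pool (pool-wide singletons, frameshift-length sequences),
step 2 drops samples sequenced below the depth threshold T1 = T1(r, m, α)
from the coverage model, step 3 drops within-sample variants below the
frequency threshold T2 (default 4%), and step 4 screens the survivors for
PCR chimeras and non-target loci (pseudogenes/paralogs), re-checking depth
afterwards.  Surviving samples are assembled into genotypes carrying the
model confidence f(r, m, N_i).

Notation follows the field's bookkeeping: for pool-level data R raw reads,
N retained sequences, A distinct variants, N_j sequences per variant j; per
sample i, N_i sequences, A_i variants, N_ij per-variant counts and
frequencies F_ij = N_ij / N_i.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import pandas as pd

from ._seq import hamming
from .coverage import coverage_probability, threshold_T1
from .design import AmpliconDesign

ARTIFACT_CLASSES = ("substitution", "insertion", "deletion", "chimera", "other_gene", "unknown")


@dataclass
class SampleObservations:
    """Per-sample variant table after demultiplexing."""

    sample: str
    species: str
    m: int
    counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"sample {self.sample!r}: m must be >= 1")
        bad = [v for v, c in self.counts.items() if c < 1]
        if bad:
            raise ValueError(f"sample {self.sample!r}: zero/negative counts for {bad[:3]}")

    @property
    def n_i(self) -> int:
        return sum(self.counts.values())

    @property
    def a_i(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> dict[str, float]:
        n = self.n_i
        return {v: c / n for v, c in self.counts.items()} if n else {}


@dataclass
class PoolDataset:
    """One pool's worth of demultiplexed observations."""

    pool: str
    raw_read_count: int
    samples: list[SampleObservations]

    @property
    def N(self) -> int:
        return sum(s.n_i for s in self.samples)

    @property
    def variant_counts(self) -> Counter:
        """Pool-wide N_j per variant."""
        total: Counter = Counter()
        for s in self.samples:
            total.update(s.counts)
        return total

    @property
    def A(self) -> int:
        return len(self.variant_counts)

    def sample(self, sample_id: str) -> SampleObservations:
        for s in self.samples:
            if s.sample == sample_id:
                return s
        raise KeyError(f"unknown sample {sample_id!r}")

    @classmethod
    def from_demux(cls, result, sheet) -> "PoolDataset":
        """Build from a DemuxResult and the sample sheet (for species/m)."""
        meta = {e.sample: e for e in sheet.pool_entries(result.pool)}
        samples = [
            SampleObservations(sid, meta[sid].species, meta[sid].m, dict(table))
            for sid, table in sorted(result.sample_tables.items())
            if table
        ]
        return cls(result.pool, len(result.assignments), samples)


@dataclass
class FilterReport:
    """Accounting for one step: input = removed + retained, in sequences,
    plus per-item removal reasons."""

    step: str
    input_sequences: int
    removed_sequences: int
    removals: list[tuple[str, str, str]] = field(default_factory=list)
    # (sample or "<pool>", variant or "<sample>", reason)

    @property
    def retained_sequences(self) -> int:
        return self.input_sequences - self.removed_sequences


@dataclass(frozen=True)
class ArtifactCall:
    variant: str
    artifact_class: str
    parents: tuple[str, ...] = ()
    breakpoints: tuple[int, int] | None = None  # chimeras: [lo, hi] equivalent crossovers

    def __post_init__(self) -> None:
        if self.artifact_class not in ARTIFACT_CLASSES:
            raise ValueError(f"invalid artifact class {self.artifact_class!r}")
        if self.artifact_class == "chimera":
            if len(self.parents) != 2 or self.parents[0] == self.parents[1]:
                raise ValueError("a chimera call needs exactly two distinct parents")
            if self.breakpoints is None:
                raise ValueError("a chimera call needs a breakpoint interval")


@dataclass(frozen=True)
class Genotype:
    sample: str
    species: str
    m: int
    variants: frozenset[str]
    n_i: int
    confidence: float
    status: str  # genotyped | insufficient_depth | removed_post_screen
    flagged_excess_variants: bool = False

    @property
    def zygosity(self) -> str:
        return "homozygous-like" if len(self.variants) == 1 else "heterozygous/multi"


# ---------------------------------------------------------------- step 1

def step1_filter(
    pool: PoolDataset,
    design: AmpliconDesign,
    drop_singletons: bool = True,
    drop_frameshift: bool = True,
) -> tuple[PoolDataset, FilterReport]:
    """Pool-level cleaning: variants seen once in the whole pool are likely
    sequencing errors; sequences whose length differs from the expected
    insert by a non-multiple of 3 would shift the reading frame."""
    report = FilterReport("step1", pool.N, 0)
    pool_counts = pool.variant_counts
    expected = design.expected_insert_length
    new_samples = []
    for s in pool.samples:
        kept: dict[str, int] = {}
        for v, c in s.counts.items():
            if drop_frameshift and (len(v) - expected) % 3 != 0:
                report.removed_sequences += c
                report.removals.append((s.sample, v, "frameshift"))
            elif drop_singletons and pool_counts[v] == 1:
                report.removed_sequences += c
                report.removals.append((s.sample, v, "pool_singleton"))
            else:
                kept[v] = c
        if kept:
            new_samples.append(replace(s, counts=kept))
    return PoolDataset(pool.pool, pool.raw_read_count, new_samples), report


# ---------------------------------------------------------------- step 2

def step2_depth_filter(
    pool: PoolDataset, r: int = 3, alpha: float = 1e-3
) -> tuple[PoolDataset, FilterReport]:
    """Drop whole samples with N_i below T1(r, m, alpha): too few sequences
    for a reliable complete genotype."""
    report = FilterReport("step2", pool.N, 0)
    t1_cache: dict[int, int] = {}
    kept = []
    for s in pool.samples:
        t1 = t1_cache.setdefault(s.m, threshold_T1(r, s.m, alpha))
        if s.n_i < t1:
            report.removed_sequences += s.n_i
            report.removals.append((s.sample, "<sample>", f"depth {s.n_i} < T1={t1}"))
        else:
            kept.append(s)
    return PoolDataset(pool.pool, pool.raw_read_count, kept), report


# ---------------------------------------------------------------- step 3

def step3_frequency_filter(
    pool: PoolDataset, t2: float = 0.04
) -> tuple[PoolDataset, FilterReport]:
    """Drop within-sample variants with F_ij < T2.

    Frequencies are computed once on the incoming counts and all removals in
    a sample are simultaneous; the comparison is strict (F_ij exactly equal
    to T2 is retained) and done in exact rational arithmetic so the 4%
    boundary never depends on float rounding.
    """
    if not 0.0 < t2 < 1.0:
        raise ValueError(f"T2 must be in (0, 1), got {t2}")
    t2_frac = Fraction(str(t2))
    report = FilterReport("step3", pool.N, 0)
    new_samples = []
    for s in pool.samples:
        n = s.n_i
        kept = {}
        for v, c in s.counts.items():
            if Fraction(c, n) < t2_frac:
                report.removed_sequences += c
                report.removals.append((s.sample, v, f"F_ij={c}/{n} < T2"))
            else:
                kept[v] = c
        if kept:
            new_samples.append(replace(s, counts=kept))
    return PoolDataset(pool.pool, pool.raw_read_count, new_samples), report


# ---------------------------------------------------------------- step 4

def _affix_lengths(candidate: str, parent: str) -> tuple[int, int]:
    lp = 0
    for a, b in zip(candidate, parent):
        if a != b:
            break
        lp += 1
    ls = 0
    for a, b in zip(reversed(candidate), reversed(parent)):
        if a != b:
            break
        ls += 1
    return lp, ls


def detect_chimera(candidate: str, parents: Iterable[str]) -> ArtifactCall | None:
    """Report a single-crossover PCR chimera.

    A candidate is chimeric iff two distinct parents P, Q and a breakpoint
    k (1 <= k < L) exist with candidate = P[:k] + Q[k:].  Breakpoints between
    the same flanking differences are indistinguishable, so the maximal
    interval of equivalent k is reported.  Candidates equal to any parent
    are never chimeras; parents must share the candidate's length (variants
    here are length-matched after the frameshift filter — unequal lengths
    yield no call).
    """
    parents = sorted(set(parents))
    parents = [p for p in parents if len(p) == len(candidate)]
    if candidate in parents:
        return None
    if len(parents) < 2:
        return None
    L = len(candidate)
    best: tuple[int, int, str, str] | None = None
    lp = {p: _affix_lengths(candidate, p)[0] for p in parents}
    ls = {p: _affix_lengths(candidate, p)[1] for p in parents}
    for p in parents:
        for q in parents:
            if p == q:
                continue
            lo = max(1, L - ls[q])
            hi = min(L - 1, lp[p])
            if lo <= hi and (best is None or (hi - lo) > (best[1] - best[0])):
                best = (lo, hi, p, q)
    if best is None:
        return None
    lo, hi, p, q = best
    return ArtifactCall(candidate, "chimera", parents=(p, q), breakpoints=(lo, hi))


def _edit_distance(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def step4_artifact_screen(
    pool: PoolDataset,
    nontarget_refs: Sequence[str] | None = None,
    r: int = 3,
    alpha: float = 1e-3,
) -> tuple[PoolDataset, FilterReport, list[ArtifactCall]]:
    """Screen retained variants for chimeras and non-target loci.

    Within each sample, variants are tested (least abundant first) as
    single-crossover composites of the sample's strictly more abundant
    variants; a variant closer in edit distance to a supplied non-target
    reference than to every co-retained variant is removed as other_gene.
    Samples whose depth falls below T1 after removals are eliminated.
    """
    report = FilterReport("step4", pool.N, 0)
    calls: list[ArtifactCall] = []
    t1_cache: dict[int, int] = {}
    new_samples = []
    for s in pool.samples:
        # abundance-descending, ties broken lexicographically for determinism
        order = sorted(s.counts, key=lambda v: (-s.counts[v], v))
        kept = dict(s.counts)
        for v in reversed(order):
            more_abundant = [p for p in kept if kept[p] > kept[v] and p != v]
            call = detect_chimera(v, more_abundant)
            if call is not None:
                report.removed_sequences += kept[v]
                report.removals.append((s.sample, v, "chimera"))
                calls.append(call)
                del kept[v]
        if nontarget_refs:
            for v in sorted(kept):
                others = [p for p in kept if p != v]
                if not others:
                    continue
                d_ref = min(_edit_distance(v, ref) for ref in nontarget_refs)
                d_target = min(_edit_distance(v, p) for p in others)
                if d_ref < d_target:
                    report.removed_sequences += kept[v]
                    report.removals.append((s.sample, v, "other_gene"))
                    calls.append(ArtifactCall(v, "other_gene"))
                    del kept[v]
        if not kept:
            report.removals.append((s.sample, "<sample>", "emptied_post_screen"))
            continue
        survivor = replace(s, counts=kept)
        t1 = t1_cache.setdefault(s.m, threshold_T1(r, s.m, alpha))
        if survivor.n_i < t1:
            report.removed_sequences += survivor.n_i
            report.removals.append((s.sample, "<sample>", f"post-screen depth {survivor.n_i} < T1={t1}"))
        else:
            new_samples.append(survivor)
    return PoolDataset(pool.pool, pool.raw_read_count, new_samples), report, calls


# ---------------------------------------------------------------- genotypes

def assemble_genotypes(pool: PoolDataset, r: int = 3, alpha: float = 1e-3) -> list[Genotype]:
    """Turn surviving samples into genotypes with model confidence
    f(r, m, N_i).  Samples retaining more than m variants are flagged, not
    truncated — excess variants can be real (unmodelled duplication)."""
    genotypes = []
    for s in pool.samples:
        genotypes.append(
            Genotype(
                sample=s.sample, species=s.species, m=s.m,
                variants=frozenset(s.counts), n_i=s.n_i,
                confidence=coverage_probability(r, s.m, s.n_i),
                status="genotyped",
                flagged_excess_variants=len(s.counts) > s.m,
            )
        )
    return genotypes


@dataclass
class ValidationResult:
    pool: PoolDataset  # final, post-step-4
    genotypes: list[Genotype]
    reports: list[FilterReport]
    artifact_calls: list[ArtifactCall]


def validate_pool(
    pool: PoolDataset,
    design: AmpliconDesign,
    r: int = 3,
    alpha: float = 1e-3,
    t2: float = 0.04,
    drop_singletons: bool = True,
    drop_frameshift: bool = True,
    nontarget_refs: Sequence[str] | None = None,
) -> ValidationResult:
    """Run steps 1-4 and genotype assembly in the fixed order, recording
    non-genotyped samples with their elimination stage."""
    p1, rep1 = step1_filter(pool, design, drop_singletons, drop_frameshift)
    p2, rep2 = step2_depth_filter(p1, r, alpha)
    removed_depth = {s.sample for s in p1.samples} - {s.sample for s in p2.samples}
    p3, rep3 = step3_frequency_filter(p2, t2)
    p4, rep4, calls = step4_artifact_screen(p3, nontarget_refs, r, alpha)
    removed_screen = {s.sample for s in p3.samples} - {s.sample for s in p4.samples}

    genotypes = assemble_genotypes(p4, r, alpha)
    meta = {s.sample: s for s in pool.samples}
    for sid in sorted(removed_depth):
        s = meta[sid]
        genotypes.append(Genotype(s.sample, s.species, s.m, frozenset(), 0, 0.0, "insufficient_depth"))
    for sid in sorted(removed_screen):
        s = meta[sid]
        genotypes.append(Genotype(s.sample, s.species, s.m, frozenset(), 0, 0.0, "removed_post_screen"))
    genotypes.sort(key=lambda g: g.sample)
    return ValidationResult(p4, genotypes, [rep1, rep2, rep3, rep4], calls)


# ---------------------------------------------------------------- artifacts

def classify_artifact(
    rejected: str,
    accepted: Iterable[str],
    nontarget_refs: Sequence[str] | None = None,
) -> ArtifactCall:
    """Classify a rejected variant against the accepted set.

    Precedence: chimera, then substitution (same length, Hamming <= 2),
    then insertion/deletion (1-2 bp net length change with no other edits
    beyond 2), then other_gene (closer to a non-target reference than to
    any accepted variant), else unknown.
    """
    accepted = sorted(set(accepted))
    if not accepted:
        raise ValueError("classify_artifact requires a non-empty accepted set")
    chim = detect_chimera(rejected, accepted)
    if chim is not None:
        return chim
    for a in accepted:
        if len(a) == len(rejected) and hamming(rejected, a) <= 2:
            return ArtifactCall(rejected, "substitution", parents=(a,))
    for a in accepted:
        delta = len(rejected) - len(a)
        if 1 <= abs(delta) <= 2 and _edit_distance(rejected, a) <= 2:
            cls = "insertion" if delta > 0 else "deletion"
            return ArtifactCall(rejected, cls, parents=(a,))
    if nontarget_refs:
        d_ref = min(_edit_distance(rejected, ref) for ref in nontarget_refs)
        d_acc = min(_edit_distance(rejected, a) for a in accepted)
        if d_ref < d_acc:
            return ArtifactCall(rejected, "other_gene")
    return ArtifactCall(rejected, "unknown")


# ---------------------------------------------------------------- statistics

def pool_statistics(pool: PoolDataset) -> dict:
    """Descriptive summary: R, N, A, the N_j distribution and per-sample
    N_i / A_i / F_ij tables.  Pure function of the dataset."""
    variant_counts = pool.variant_counts
    per_sample = pd.DataFrame(
        [(s.sample, s.species, s.m, s.n_i, s.a_i) for s in pool.samples],
        columns=["sample", "species", "m", "N_i", "A_i"],
    )
    freq_rows = [
        (s.sample, v, c, c / s.n_i)
        for s in pool.samples
        for v, c in sorted(s.counts.items())
    ]
    frequencies = pd.DataFrame(freq_rows, columns=["sample", "variant", "N_ij", "F_ij"])
    return {
        "pool": pool.pool,
        "R": pool.raw_read_count,
        "N": pool.N,
        "A": pool.A,
        "N_j": dict(sorted(variant_counts.items())),
        "per_sample": per_sample,
        "frequencies": frequencies,
    }


# ---------------------------------------------------------------- replicates

@dataclass
class ConcordanceReport:
    pairs_total: int
    pairs_genotyped: int
    concordant: int
    discordant: list[tuple[str, str, str]]  # (sample_a, sample_b, class)

    @property
    def percent(self) -> int:
        """Concordance over doubly-genotyped pairs, rounded to the nearest
        integer (63/66 prints 95)."""
        if not self.pairs_genotyped:
            return 0
        return round(100 * self.concordant / self.pairs_genotyped)


def replicate_concordance(
    genotypes: Iterable[Genotype],
    pairs: Sequence[tuple[str, str]],
) -> ConcordanceReport:
    """Compare genotypes of replicate sample pairs.

    Only pairs with both members genotyped are scored.  Discordant pairs
    where one variant set is a strict subset of the other are classed as
    allelic_dropout; the rest as other.
    """
    by_sample = {g.sample: g for g in genotypes}
    for a, b in pairs:
        for sid in (a, b):
            if sid not in by_sample:
                raise ValueError(f"unknown sample id {sid!r} in replicate pairs")
    genotyped = [
        (a, b)
        for a, b in pairs
        if by_sample[a].status == "genotyped" and by_sample[b].status == "genotyped"
    ]
    concordant = 0
    discordant = []
    for a, b in genotyped:
        va, vb = by_sample[a].variants, by_sample[b].variants
        if va == vb:
            concordant += 1
        elif va < vb or vb < va:
            discordant.append((a, b, "allelic_dropout"))
        else:
            discordant.append((a, b, "other"))
    return ConcordanceReport(len(pairs), len(genotyped), concordant, discordant)


# ---------------------------------------------------------------- outputs

def write_validation_outputs(result: ValidationResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = [
        (g.sample, g.species, g.m, ";".join(sorted(g.variants)), g.n_i,
         f"{g.confidence:.6g}", g.zygosity if g.variants else "", g.status,
         int(g.flagged_excess_variants))
        for g in result.genotypes
    ]
    pd.DataFrame(
        rows,
        columns=["sample", "species", "m", "variants", "N_i", "confidence",
                 "zygosity", "status", "flagged_excess_variants"],
    ).to_csv(outdir / "genotypes.tsv", sep="\t", index=False)

    variant_counts = result.pool.variant_counts
    with open(outdir / "validated_variants.fasta", "w") as fh:
        for i, (v, c) in enumerate(sorted(variant_counts.items()), start=1):
            fh.write(f">variant_{i:04d} N_j={c}\n{v}\n")

    step_rows = [
        (r.step, r.input_sequences, r.removed_sequences, r.retained_sequences)
        for r in result.reports
    ]
    pd.DataFrame(step_rows, columns=["step", "input", "removed", "retained"]).to_csv(
        outdir / "filter_report.tsv", sep="\t", index=False
    )
    detail = [
        (r.step, s, v, why) for r in result.reports for (s, v, why) in r.removals
    ]
    pd.DataFrame(detail, columns=["step", "sample", "variant", "reason"]).to_csv(
        outdir / "filter_removals.tsv", sep="\t", index=False
    )
    calls = [
        (c.variant, c.artifact_class, ";".join(c.parents),
         "" if c.breakpoints is None else f"{c.breakpoints[0]}-{c.breakpoints[1]}")
        for c in result.artifact_calls
    ]
    pd.DataFrame(calls, columns=["variant", "class", "parents", "breakpoints"]).to_csv(
        outdir / "artifact_calls.tsv", sep="\t", index=False
    )
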