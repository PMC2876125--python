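"""Synthetic 454-style multiplex amplicon reads with ground truth.

The simulator emulates a tagged multiplex run end to end: per-species allele
pools, per-sample genotypes drawn with replacement (duplicate draws yield
homozygotes), per-sample depth from a negative-binomial model (wide
per-sample spread, as observed on real runs), and a per-read artifact class
drawn from the documented spectrum — true 84, substitutions 6, insertions 2,
deletions 4, chimeras 6, other genes 1, normalised to probabilities.  Reads
are emitted in the standard layout (key + forward tag + forward primer +
insert + rc(reverse primer) + rc(reverse tag)); reads affected by the
key-homopolymer tag collapse are emitted from the opposite adaptor with the
reverse tag's lead base absorbed into the key, which is where the artifact
physically arises.

Everything is driven by one integer seed; identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seq import IUPAC, revcomp
from .demux import Read
from .design import (
    AmpliconDesign,
    SampleSheet,
    TagSet,
    build_sample_sheet,
    default_tag_sets,
    flag_homopolymer_hazard,
)

# Per-read artifact class spectrum (within-sample sequence composition of a
# real run: 84/6/2/4/6/1), normalised at use.
DEFAULT_SPECTRUM = {
    "true": 84.0,
    "substitution": 6.0,
    "insertion": 2.0,
    "deletion": 4.0,
    "chimera": 6.0,
    "other_gene": 1.0,
}

CLASSES = tuple(DEFAULT_SPECTRUM)


@dataclass(frozen=True)
class SpeciesSpec:
    """A species' allele pool: `allele_pool_size` variants of length
    `allele_length`, each `allele_divergence` substitutions away from a
    species-specific ancestral sequence.  Variants of one highly polymorphic
    locus are mutually similar (tens of substitutions over ~171 bp at most),
    which is exactly the structure the chimera and paralog screens rely on."""

    name: str
    m: int = 2
    allele_pool_size: int = 30
    allele_length: int = 171
    allele_divergence: int = 10

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.allele_pool_size < 1:
            raise ValueError("allele pool must contain at least one allele")
        if self.allele_length < 1:
            raise ValueError("allele length must be positive")
        if not 0 < self.allele_divergence <= self.allele_length:
            raise ValueError("allele_divergence must be in (0, allele_length]")


@dataclass(frozen=True)
class DepthModel:
    """Per-sample depth: negative binomial with the given mean and shape
    (gamma-Poisson; larger shape = tighter spread), optionally truncated
    below by redrawing.  fixed_depth overrides the draw entirely."""

    mean: float = 80.0
    shape: float = 5.0
    fixed_depth: int | None = None
    min_depth: int = 0

    def draw(self, rng: np.random.Generator) -> int:
        if self.fixed_depth is not None:
            return self.fixed_depth
        p = self.shape / (self.shape + self.mean)
        while True:
            d = int(rng.negative_binomial(self.shape, p))
            if d >= self.min_depth:
                return d


@dataclass
class SimConfig:
    seed: int
    species: Sequence[SpeciesSpec] = (SpeciesSpec("species_1", m=2),)
    samples_per_species: int = 50
    depth: DepthModel = field(default_factory=DepthModel)
    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    hazard_collapse_rate: float = 0.0
    allele_weights: Sequence[float] | None = None  # optional PCR-competition skew
    off_target_pool_size: int = 3
    n_forward_tags: int = 36
    n_reverse_tags: int = 24
    tag_length: int = 3
    design: AmpliconDesign = field(default_factory=AmpliconDesign)
    pool: str = "A"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        missing = [c for c in CLASSES if c not in self.spectrum]
        if missing:
            raise ValueError(f"spectrum missing classes: {missing}")
        if any(v < 0 for v in self.spectrum.values()) or sum(self.spectrum.values()) <= 0:
            raise ValueError("spectrum weights must be non-negative with positive sum")
        if not 0.0 <= self.hazard_collapse_rate <= 1.0:
            raise ValueError("hazard_collapse_rate must be in [0, 1]")

    @property
    def class_probabilities(self) -> dict[str, float]:
        total = sum(self.spectrum[c] for c in CLASSES)
        return {c: self.spectrum[c] / total for c in CLASSES}


@dataclass
class SampleTruth:
    sample: str
    species: str
    m: int
    alleles: tuple[str, ...]  # distinct alleles actually carried

    @property
    def genotype(self) -> frozenset[str]:
        return frozenset(self.alleles)


@dataclass
class SimTruth:
    config: SimConfig
    samples: list[SampleTruth]
    allele_pools: dict[str, list[str]]
    off_target_pool: list[str]
    sheet: SampleSheet
    forward_tags: TagSet
    reverse_tags: TagSet
    reads: list[Read] = field(default_factory=list)
    provenance: list[dict] = field(default_factory=list)
    chimera_redraws: int = 0


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """`n_subs` substitutions at distinct random positions."""
    positions = rng.choice(len(seq), size=n_subs, replace=False)
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(out)


# Pseudogenes/paralogs co-amplified by the primers are far more diverged
# from the target alleles than the alleles are from each other.
OFF_TARGET_DIVERGENCE = 60


def simulate_genotypes(config: SimConfig) -> SimTruth:
    """Draw allele pools and per-sample genotypes (the truth skeleton).

    Each sample draws m alleles uniformly *with replacement* from its
    species pool, so duplicate draws yield fewer distinct alleles —
    homozygosity arises naturally.
    """
    rng = np.random.default_rng(config.seed)
    pools: dict[str, list[str]] = {}
    ancestors: dict[str, str] = {}
    for sp in config.species:
        ancestor = _random_seq(rng, sp.allele_length)
        ancestors[sp.name] = ancestor
        pool: list[str] = []
        while len(pool) < sp.allele_pool_size:
            allele = _mutate(rng, ancestor, sp.allele_divergence)
            if allele not in pool:
                pool.append(allele)
        pools[sp.name] = pool
    first = config.species[0]
    off_target = [
        _mutate(rng, ancestors[first.name], min(OFF_TARGET_DIVERGENCE, first.allele_length))
        for _ in range(config.off_target_pool_size)
    ]

    samples: list[SampleTruth] = []
    descriptors: list[tuple[str, str, int]] = []
    idx = 0
    for sp in config.species:
        for _ in range(config.samples_per_species):
            idx += 1
            sid = f"S{idx:04d}"
            draws = rng.integers(0, sp.allele_pool_size, size=sp.m)
            alleles = tuple(sorted({pools[sp.name][i] for i in draws}))
            samples.append(SampleTruth(sid, sp.name, sp.m, alleles))
            descriptors.append((sid, sp.name, sp.m))

    fwd, rev = default_tag_sets(config.n_forward_tags, config.n_reverse_tags, config.tag_length)
    n = len(descriptors)
    cols = 12
    rows = 8
    n_plates = -(-n // (rows * cols))
    sheet = build_sample_sheet(descriptors, fwd, rev, (rows, cols, n_plates), pool=config.pool)
    return SimTruth(config, samples, pools, off_target, sheet, fwd, rev)


def _corrupt_substitution(rng: np.random.Generator, seq: str) -> tuple[str, list[int]]:
    k = int(rng.integers(1, 3))  # 1 or 2 changes
    positions = sorted(rng.choice(len(seq), size=k, replace=False).tolist())
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != seq[p]])
    return "".join(out), positions


def _corrupt_indel(rng: np.random.Generator, seq: str, kind: str) -> tuple[str, list[int]]:
    k = int(rng.integers(1, 3))  # 1 or 2 bp
    if kind == "insertion":
        p = int(rng.integers(0, len(seq) + 1))
        ins = _random_seq(rng, k)
        return seq[:p] + ins + seq[p:], [p]
    p = int(rng.integers(0, len(seq) - k + 1))
    return seq[:p] + seq[p + k:], [p]


def _instantiate_iupac(rng: np.random.Generator, primer: str) -> str:
    return "".join(b if b in "ACGT" else rng.choice(list(IUPAC[b])) for b in primer)


def simulate_reads(truth: SimTruth) -> SimTruth:
    """Emit tagged reads for every sample and complete the truth record."""
    config = truth.config
    rng = np.random.default_rng((config.seed, 1))
    design = config.design
    barcode = {
        e.sample: (truth.forward_tags.by_label(e.ftag), truth.reverse_tags.by_label(e.rtag))
        for e in truth.sheet.pool_entries(config.pool)
    }
    hazard = flag_homopolymer_hazard(design.key, truth.reverse_tags)
    probs = config.class_probabilities
    p_vec = np.array([probs[c] for c in CLASSES])

    read_no = 0
    for st in truth.samples:
        ftag, rtag = barcode[st.sample]
        depth = config.depth.draw(rng)
        if config.allele_weights is not None and len(st.alleles) > 1:
            w = np.asarray(config.allele_weights[: len(st.alleles)], dtype=float)
            allele_p = w / w.sum()
        else:
            allele_p = None
        classes = rng.choice(len(CLASSES), size=depth, p=p_vec)
        for cls_i in classes:
            cls = CLASSES[cls_i]
            src = st.alleles[rng.choice(len(st.alleles), p=allele_p)] if st.alleles else ""
            detail: list[int] = []
            sources = [src]
            if cls == "chimera" and len(st.alleles) < 2:
                cls = "true"  # logged: chimeras need two distinct alleles
                truth.chimera_redraws += 1
            if cls == "true":
                insert = src
            elif cls == "substitution":
                insert, detail = _corrupt_substitution(rng, src)
            elif cls in ("insertion", "deletion"):
                insert, detail = _corrupt_indel(rng, src, cls)
            elif cls == "chimera":
                others = [a for a in st.alleles if a != src]
                other = others[rng.choice(len(others))]
                k = int(rng.integers(1, len(src)))
                insert = src[:k] + other[k:]
                detail = [k]
                sources = [src, other]
            else:  # other_gene
                insert = truth.off_target_pool[rng.choice(len(truth.off_target_pool))]
                sources = []

            read_no += 1
            rid = f"read{read_no:07d}"
            fp = _instantiate_iupac(rng, design.forward_primer)
            rp = _instantiate_iupac(rng, design.reverse_primer)
            collapsed = False
            if (
                rtag in hazard
                and config.hazard_collapse_rate > 0
                and rng.random() < config.hazard_collapse_rate
            ):
                # B-adaptor read: the basecaller strips the key homopolymer
                # together with the reverse tag's lead base.
                bases = (
                    design.key + rtag.sequence[1:] + rp
                    + revcomp(insert) + revcomp(fp) + revcomp(ftag.sequence)
                )
                collapsed = True
            else:
                bases = (
                    design.key + ftag.sequence + fp
                    + insert + revcomp(rp) + revcomp(rtag.sequence)
                )
            truth.reads.append(Read(rid, bases))
            truth.provenance.append(
                {
                    "read": rid,
                    "sample": st.sample,
                    "class": cls,
                    "sources": ";".join(sources),
                    "detail": ";".join(map(str, detail)),
                    "collapsed_tag": collapsed,
                    "insert": insert,
                }
            )
    return truth


def simulate(config: SimConfig) -> SimTruth:
    """Genotype skeleton + reads in one call."""
    return simulate_reads(simulate_genotypes(config))


def write_simulation(truth: SimTruth, outdir: str | Path) -> None:
    """reads.fasta, truth tables, sample sheet, tag sets and design —
    everything a pipeline run needs, as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "reads.fasta", "w") as fh:
        for read in truth.reads:
            fh.write(f">{read.id}\n{read.bases}\n")
    pd.DataFrame(
        [
            (st.sample, st.species, st.m, ";".join(st.alleles))
            for st in truth.samples
        ],
        columns=["sample", "species", "m", "alleles"],
    ).to_csv(outdir / "truth_genotypes.tsv", sep="\t", index=False)
    pd.DataFrame(truth.provenance).to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)
    truth.sheet.write(outdir / "sample_sheet.tsv")
    truth.forward_tags.write(outdir / "forward_tags.tsv")
    truth.reverse_tags.write(outdir / "reverse_tags.tsv")
    truth.config.design.to_yaml(outdir / "design.yaml")
    with open(outdir / "off_target.fasta", "w") as fh:
        for i, seq in enumerate(truth.off_target_pool, start=1):
            fh.write(f">off_target_{i} synthetic non-target locus\n{seq}\n")
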