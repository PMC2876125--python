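"""Combinatorial tag-barcoding design.

A sample is identified not by its own oligo but by the *pair* of short tags
carried by its forward and reverse primers, so n forward and k reverse tags
encode n*k samples.  This module holds the tag sets, the amplicon design
record (454 adaptors, TCAG key, target-specific primers), barcode
enumeration, the key-homopolymer hazard check, plate layout / sample-sheet
construction and the plain-text interchange formats for all of them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
import yaml

from ._seq import hamming, is_iupac_dna, is_strict_dna

# Tagged-primer design used for DRB exon 2 genotyping on the GS FLX:
# 19 bp emPCR adaptors A/B ending in the TCAG basecaller key, the JS1/JS2
# target-specific primers, and a 171 bp insert between them.
ADAPTOR_A = "GCCTCCCTCGCGCCATCAG"
ADAPTOR_B = "GCCTTGCCAGCCCGCTCAG"
KEY = "TCAG"
PRIMER_JS1 = "GAGTGTCATTTCTACAACGGGACG"
PRIMER_JS2 = "GATCCCGTAGTTGTGTYTGCA"
EXPECTED_INSERT_LENGTH = 171

SHEET_COLUMNS = ["pool", "plate", "row", "col", "sample", "ftag", "rtag", "species", "m"]


@dataclass(frozen=True)
class Tag:
    """A short barcode appended to the 5' end of a primer."""

    label: str
    sequence: str
    role: str = "forward"  # "forward" or "reverse"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("tag label must be non-empty")
        if not is_strict_dna(self.sequence):
            raise ValueError(
                f"tag {self.label!r}: sequence must be non-empty uppercase ACGT, "
                f"got {self.sequence!r}"
            )
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"tag role must be 'forward' or 'reverse', got {self.role!r}")


class TagSet:
    """An ordered set of same-length, unique tags sharing one role."""

    def __init__(self, tags: Iterable[Tag]):
        tags = list(tags)
        if not tags:
            raise ValueError("a tag set must contain at least one tag")
        lengths = {len(t.sequence) for t in tags}
        if len(lengths) != 1:
            raise ValueError(f"all tags in a set must have equal length, got lengths {sorted(lengths)}")
        seen: dict[str, Tag] = {}
        for t in tags:
            if t.sequence in seen:
                raise ValueError(
                    f"duplicate tag sequence {t.sequence!r} "
                    f"(labels {seen[t.sequence].label!r} and {t.label!r})"
                )
            seen[t.sequence] = t
        labels = [t.label for t in tags]
        if len(set(labels)) != len(labels):
            dup = next(l for l in labels if labels.count(l) > 1)
            raise ValueError(f"duplicate tag label {dup!r}")
        roles = {t.role for t in tags}
        if len(roles) != 1:
            raise ValueError("all tags in a set must share one role")
        self._tags = tags
        self._by_seq = seen
        self._by_label = {t.label: t for t in tags}

    @property
    def tag_length(self) -> int:
        return len(self._tags[0].sequence)

    @property
    def role(self) -> str:
        return self._tags[0].role

    def __len__(self) -> int:
        return len(self._tags)

    def __iter__(self) -> Iterator[Tag]:
        return iter(self._tags)

    def __contains__(self, sequence: str) -> bool:
        return sequence in self._by_seq

    def by_sequence(self, sequence: str) -> Tag | None:
        return self._by_seq.get(sequence)

    def by_label(self, label: str) -> Tag:
        try:
            return self._by_label[label]
        except KeyError:
            raise KeyError(f"unknown tag label {label!r}") from None

    @classmethod
    def from_sequences(cls, sequences: Sequence[str], role: str, prefix: str | None = None) -> "TagSet":
        prefix = prefix if prefix is not None else ("F" if role == "forward" else "R")
        return cls(Tag(f"{prefix}{i + 1:02d}", s, role) for i, s in enumerate(sequences))

    @classmethod
    def read(cls, path: str | Path, role: str) -> "TagSet":
        """Two-column whitespace/tab text: label, sequence."""
        tags = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            label, seq = line.split()[:2]
            tags.append(Tag(label, seq, role))
        return cls(tags)

    def write(self, path: str | Path) -> None:
        Path(path).write_text("".join(f"{t.label}\t{t.sequence}\n" for t in self._tags))


@dataclass(frozen=True)
class AmpliconDesign:
    """The fixed parts of the tagged-amplicon construct.

    Reads have the layout  key + forward tag + forward primer + insert +
    revcomp(reverse primer) + revcomp(reverse tag); the adaptors are consumed
    by the instrument and never appear in the read.
    """

    adaptor_a: str = ADAPTOR_A
    adaptor_b: str = ADAPTOR_B
    key: str = KEY
    forward_primer: str = PRIMER_JS1
    reverse_primer: str = PRIMER_JS2
    expected_insert_length: int = EXPECTED_INSERT_LENGTH

    def __post_init__(self) -> None:
        for name in ("adaptor_a", "adaptor_b", "key"):
            val = getattr(self, name)
            if not is_strict_dna(val):
                raise ValueError(f"{name} must be non-empty uppercase ACGT, got {val!r}")
        if not self.adaptor_a.endswith(self.key) or not self.adaptor_b.endswith(self.key):
            raise ValueError("both adaptors must end with the key sequence")
        for name in ("forward_primer", "reverse_primer"):
            val = getattr(self, name)
            if not is_iupac_dna(val):
                raise ValueError(f"{name} must be valid IUPAC DNA, got {val!r}")
        if self.expected_insert_length <= 0:
            raise ValueError("expected_insert_length must be positive")

    def amplicon_length(self, tag_length: int = 3) -> int:
        """Tagged amplicon length excluding adaptors: insert + both primers
        + both tags (222 bp for the default design with 3 bp tags)."""
        return (
            self.expected_insert_length
            + len(self.forward_primer)
            + len(self.reverse_primer)
            + 2 * tag_length
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AmpliconDesign":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def enumerate_barcodes(forward_tags: TagSet, reverse_tags: TagSet) -> list[tuple[Tag, Tag]]:
    """All |F|*|R| ordered (forward, reverse) tag pairs, forward-major.

    TagSet construction already rejects duplicate sequences, so the output
    pairs are distinct by construction.
    """
    return [(f, r) for f in forward_tags for r in reverse_tags]


def flag_homopolymer_hazard(key: str, tags: TagSet) -> frozenset[Tag]:
    """Tags whose first base extends the key's final base into a homopolymer
    (e.g. key TCAG followed by a G-leading tag reads TCAG-G...).  The
    basecaller strips the run together with the key, truncating the tag by
    one base; such tags are hazardous and their reads need recovery."""
    if not key:
        raise ValueError("key must be non-empty")
    last = key[-1]
    return frozenset(t for t in tags if t.sequence[0] == last)


def tag_distance_report(tags: TagSet) -> pd.DataFrame:
    """Pairwise Hamming distances between tags of a set (descriptive aid for
    choosing tags differing by more than one substitution)."""
    rows = [
        (a.label, b.label, hamming(a.sequence, b.sequence))
        for a, b in itertools.combinations(list(tags), 2)
    ]
    return pd.DataFrame(rows, columns=["tag_a", "tag_b", "hamming"])


@dataclass(frozen=True)
class SampleEntry:
    pool: str
    plate: str
    row: int
    col: int
    sample: str
    ftag: str
    rtag: str
    species: str
    m: int

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"sample {self.sample!r}: copy number m must be >= 1, got {self.m}")


class SampleSheet:
    """One row per well: which sample sits behind which (pool, ftag, rtag)."""

    def __init__(self, entries: Iterable[SampleEntry]):
        self.entries = list(entries)
        seen: dict[tuple[str, str, str], str] = {}
        for e in self.entries:
            bc = (e.pool, e.ftag, e.rtag)
            if bc in seen:
                raise ValueError(
                    f"barcode ({e.ftag}, {e.rtag}) reused within pool {e.pool!r} "
                    f"(samples {seen[bc]!r} and {e.sample!r})"
                )
            seen[bc] = e.sample

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleSheet) and self.entries == other.entries

    @property
    def pools(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.pool not in out:
                out.append(e.pool)
        return out

    def pool_entries(self, pool: str) -> list[SampleEntry]:
        entries = [e for e in self.entries if e.pool == pool]
        if not entries:
            raise KeyError(f"unknown pool {pool!r}")
        return entries

    def barcode_map(self, pool: str) -> dict[tuple[str, str], SampleEntry]:
        """(forward tag label, reverse tag label) -> entry, for one pool."""
        return {(e.ftag, e.rtag): e for e in self.pool_entries(pool)}

    def validate_tags(self, forward_tags: TagSet, reverse_tags: TagSet) -> None:
        for e in self.entries:
            forward_tags.by_label(e.ftag)
            reverse_tags.by_label(e.rtag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.__dict__ for e in self.entries], columns=SHEET_COLUMNS)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "SampleSheet":
        df = pd.read_csv(path, sep="\t", dtype={c: str for c in SHEET_COLUMNS if c not in ("row", "col", "m")})
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        return cls(
            SampleEntry(
                pool=str(r.pool), plate=str(r.plate), row=int(r.row), col=int(r.col),
                sample=str(r.sample), ftag=str(r.ftag), rtag=str(r.rtag),
                species=str(r.species), m=int(r.m),
            )
            for r in df.itertuples()
        )


def build_sample_sheet(
    samples: Sequence[tuple[str, str, int]],
    forward_tags: TagSet,
    reverse_tags: TagSet,
    plate_geometry: tuple[int, int, int],
    pool: str = "A",
    barcode_assignment: Sequence[tuple[str, str]] | None = None,
) -> SampleSheet:
    """Lay samples out on plates with a unique barcode per well.

    samples: (sample id, species, copy number m) in fill order.
    plate_geometry: (rows, columns, number of plates).
    barcode_assignment: optional explicit (ftag label, rtag label) per
    sample; by default wells are filled plate-major/row-major with the
    reverse tag cycling along wells and the forward tag advancing every
    |R| wells, so reverse varies by column and forward by row block.
    """
    rows, cols, n_plates = plate_geometry
    if rows < 1 or cols < 1 or n_plates < 1:
        raise ValueError(f"invalid plate geometry {plate_geometry}")
    capacity = rows * cols * n_plates
    n_barcodes = len(forward_tags) * len(reverse_tags)
    if len(samples) > n_barcodes:
        raise ValueError(
            f"{len(samples)} samples exceed the {n_barcodes} available barcode combinations"
        )
    if len(samples) > capacity:
        raise ValueError(f"{len(samples)} samples exceed the plate capacity {capacity}")
    if barcode_assignment is not None and len(barcode_assignment) != len(samples):
        raise ValueError("barcode_assignment must give one (ftag, rtag) pair per sample")

    pairs = enumerate_barcodes(forward_tags, reverse_tags)
    entries = []
    for idx, (sample, species, m) in enumerate(samples):
        plate, well = divmod(idx, rows * cols)
        row, col = divmod(well, cols)
        if barcode_assignment is not None:
            flab, rlab = barcode_assignment[idx]
            ftag, rtag = forward_tags.by_label(flab), reverse_tags.by_label(rlab)
        else:
            ftag, rtag = pairs[idx]
        entries.append(
            SampleEntry(
                pool=pool, plate=f"P{plate + 1}", row=row + 1, col=col + 1,
                sample=sample, ftag=ftag.label, rtag=rtag.label, species=species, m=int(m),
            )
        )
    return SampleSheet(entries)


def default_tag_sets(n_forward: int = 36, n_reverse: int = 24, tag_length: int = 3) -> tuple[TagSet, TagSet]:
    """Deterministic synthetic tag sets: k-mers in lexicographic order over
    ACGT, forward tags first, then reverse tags continuing the enumeration
    (so the two sets never share a sequence).  Hazard (G-leading) tags are
    not excluded — the recovery path is part of the pipeline."""
    kmers = ["".join(p) for p in itertools.product("ACGT", repeat=tag_length)]
    if n_forward + n_reverse > len(kmers):
        raise ValueError(
            f"{n_forward}+{n_reverse} tags exceed the {len(kmers)} distinct {tag_length}-mers"
        )
    fwd = TagSet.from_sequences(kmers[:n_forward], "forward")
    rev = TagSet.from_sequences(kmers[n_forward:n_forward + n_reverse], "reverse")
    return fwd, rev
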