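"""Read parsing and sample assignment for dual-tagged amplicon reads.

A well-formed read carries, in order: the TCAG key, a forward tag, the
forward primer, the insert, the reverse-complemented reverse primer and the
reverse-complemented reverse tag.  Reads sequenced from the opposite adaptor
show the mirrored layout (key, reverse tag, reverse primer, rc(insert),
rc(forward primer), rc(forward tag)).  Both the read and its reverse
complement are tried against both layouts; a read matching more than one
distinct interpretation is rejected as ambiguous.

Tags whose first base equals the key's last base can lose that base to the
basecaller's key stripping (key-homopolymer collapse).  When the full-length
tag lookup fails, the parser attempts recovery from the remaining bases
against the hazard-flagged subset of the tag set; recovery succeeds only
when it is unambiguous.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from ._seq import iupac_match, revcomp
from .design import AmpliconDesign, SampleSheet, Tag, TagSet, flag_homopolymer_hazard

REJECTION_REASONS = (
    "no_key",
    "unknown_tag",
    "incomplete_barcode",
    "primer_mismatch",
    "too_short",
    "ambiguous",
    "homopolymer_unrecoverable",
)

# How far an attempt progressed before failing; the reported reason is the
# deepest failure over all orientation/layout attempts.
_REASON_RANK = {
    "no_key": 0,
    "too_short": 1,
    "unknown_tag": 2,
    "homopolymer_unrecoverable": 3,
    "primer_mismatch": 4,
    "incomplete_barcode": 5,
    "ambiguous": 6,
}


@dataclass(frozen=True)
class Read:
    id: str
    bases: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("read id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise ValueError(f"read {self.id!r}: qualities/bases length mismatch")


@dataclass(frozen=True)
class Assignment:
    read_id: str
    status: str  # "assigned" | "rejected"
    sample: str | None = None
    ftag: str | None = None
    rtag: str | None = None
    insert: str | None = None
    orientation: str | None = None  # "A" | "B" layout that matched
    reason: str | None = None
    recovered_tag: bool = False

    def __post_init__(self) -> None:
        if self.status == "assigned":
            if not self.sample or not self.insert:
                raise ValueError("assigned reads must carry a sample id and a non-empty insert")
        elif self.status == "rejected":
            if self.reason not in REJECTION_REASONS:
                raise ValueError(f"invalid rejection reason {self.reason!r}")
        else:
            raise ValueError(f"invalid status {self.status!r}")


@dataclass(frozen=True)
class RecoveryResult:
    tag: Tag | None
    status: str  # "recovered" | "ambiguous" | "no_match"


def recover_collapsed_tag(observed_suffix: str, key: str, tags: TagSet) -> RecoveryResult:
    """Recover a tag truncated by key-homopolymer collapse.

    The observed tag region is one base short; the missing lead base equals
    the key's last base.  Only hazard-flagged tags participate, and recovery
    succeeds iff exactly one of them agrees with the observation on the
    final two tag bases (the analysis deliberately trusts only the tail of
    the corrupted tag read; with the default 3 bp tags that is the whole
    observed region).
    """
    hazard = flag_homopolymer_hazard(key, tags)
    if len(observed_suffix) != tags.tag_length - 1:
        return RecoveryResult(None, "no_match")
    k = min(2, tags.tag_length - 1)
    hits = sorted(
        (t for t in hazard if t.sequence[-k:] == observed_suffix[-k:]),
        key=lambda t: t.label,
    )
    if len(hits) == 1:
        return RecoveryResult(hits[0], "recovered")
    if len(hits) > 1:
        return RecoveryResult(None, "ambiguous")
    return RecoveryResult(None, "no_match")


@dataclass(frozen=True)
class _Parse:
    ftag: Tag
    rtag: Tag
    insert: str
    orientation: str
    recovered: bool


def _match_primer(primer: str, window: str, prefix: int | None) -> bool:
    """Full-length IUPAC-exact match, or 5'-prefix match in relaxed mode.
    The primer still occupies its full length in the read; only the 5'-most
    `prefix` bases are required to agree."""
    if prefix is None:
        return iupac_match(primer, window)
    k = min(prefix, len(primer))
    return iupac_match(primer[:k], window[:k])


def _try_layout(
    seq: str,
    design: AmpliconDesign,
    five_tags: TagSet,
    three_tags: TagSet,
    five_primer: str,
    three_primer: str,
    orientation: str,
    primer_prefix: int | None,
) -> tuple[_Parse | None, str | None]:
    """Attempt one layout on one oriented sequence.

    five_tags/five_primer sit just after the key; three_primer/three_tags
    appear reverse-complemented at the 3' end.  Returns (parse, failure
    stage); exactly one of the two is non-None.
    """
    key = design.key
    if not seq.startswith(key):
        return None, "no_key"
    tl = five_tags.tag_length
    pos = len(key)

    # 5' tag: a full-length known tag and a collapsed (one base short) tag
    # are both candidate interpretations; each must be confirmed by the
    # primer sitting in its frame.  A collapsed read can dress up as a
    # different full-length tag (key + truncated tag + primer start), so the
    # full-length reading alone is not trusted.
    recovered = False
    ftag = None
    full_tag = five_tags.by_sequence(seq[pos:pos + tl])
    full_ok = full_tag is not None and _match_primer(
        five_primer, seq[pos + tl: pos + tl + len(five_primer)], primer_prefix
    )
    if full_ok:
        ftag = full_tag
        pos += tl
    else:
        shifted_ok = _match_primer(
            five_primer, seq[pos + tl - 1: pos + tl - 1 + len(five_primer)], primer_prefix
        )
        rec = recover_collapsed_tag(seq[pos:pos + tl - 1], key, five_tags)
        if shifted_ok and rec.status == "recovered":
            ftag = rec.tag
            pos += tl - 1
            recovered = True
        elif shifted_ok and rec.status == "ambiguous":
            return None, "homopolymer_unrecoverable"
        elif full_tag is not None:
            return None, "primer_mismatch"
        else:
            return None, "unknown_tag"

    if not _match_primer(five_primer, seq[pos:pos + len(five_primer)], primer_prefix):
        return None, "primer_mismatch"
    pos += len(five_primer)

    # 3' end: revcomp(three_tag) then, inward, revcomp(three_primer).
    ttl = three_tags.tag_length
    rtag = three_tags.by_sequence(revcomp(seq[len(seq) - ttl:]))
    if rtag is None:
        return None, "incomplete_barcode"
    tp_window = seq[len(seq) - ttl - len(three_primer): len(seq) - ttl]
    if not _match_primer(three_primer, revcomp(tp_window), primer_prefix):
        return None, "primer_mismatch"

    insert = seq[pos: len(seq) - ttl - len(three_primer)]
    if not insert:
        return None, "too_short"
    if orientation == "A":
        return _Parse(ftag, rtag, insert, "A", recovered), None
    # B layout: the 5' tag was the reverse tag and the insert is flipped.
    return _Parse(rtag, ftag, revcomp(insert), "B", recovered), None


def parse_read_structure(
    read: Read,
    design: AmpliconDesign,
    forward_tags: TagSet,
    reverse_tags: TagSet,
    strict_primers: bool = True,
    primer_prefix: int = 10,
    barcode_map: dict[tuple[str, str], "object"] | None = None,
) -> Assignment:
    """Parse one read into an Assignment.

    With strict_primers (the default) primers must match full-length and
    IUPAC-exactly; otherwise only their 5'-most `primer_prefix` bases are
    required to match.  When `barcode_map` is given, the recognised tag pair
    is resolved to a sample; without it the structural parse alone decides
    and the sample field carries the tag-pair placeholder.
    """
    prefix = None if strict_primers else primer_prefix
    min_len = (
        len(design.key)
        + forward_tags.tag_length
        + reverse_tags.tag_length
        + len(design.forward_primer)
        + len(design.reverse_primer)
        + 1
    )
    if len(read.bases) < min_len:
        return Assignment(read.id, "rejected", reason="too_short")

    fp, rp = design.forward_primer, design.reverse_primer
    attempts = []
    for seq in (read.bases, revcomp(read.bases)):
        attempts.append(_try_layout(seq, design, forward_tags, reverse_tags, fp, rp, "A", prefix))
        attempts.append(_try_layout(seq, design, reverse_tags, forward_tags, rp, fp, "B", prefix))

    parses = [p for p, _ in attempts if p is not None]
    distinct = {(p.ftag.label, p.rtag.label, p.insert) for p in parses}
    if len(distinct) > 1:
        return Assignment(read.id, "rejected", reason="ambiguous")
    if not parses:
        stages = [s for _, s in attempts if s is not None]
        reason = max(stages, key=lambda s: _REASON_RANK[s])
        return Assignment(read.id, "rejected", reason=reason)

    p = parses[0]
    if barcode_map is not None:
        entry = barcode_map.get((p.ftag.label, p.rtag.label))
        if entry is None:
            # valid tags, but the combination encodes no sample in this pool
            return Assignment(read.id, "rejected", reason="unknown_tag")
        sample = entry.sample
    else:
        sample = f"{p.ftag.label}+{p.rtag.label}"
    return Assignment(
        read.id, "assigned", sample=sample, ftag=p.ftag.label, rtag=p.rtag.label,
        insert=p.insert, orientation=p.orientation, recovered_tag=p.recovered,
    )


@dataclass
class DemuxResult:
    pool: str
    sample_tables: dict[str, Counter]
    assignments: list[Assignment]
    reason_counts: Counter
    tag_counts: pd.DataFrame | None = None

    @property
    def n_assigned(self) -> int:
        return sum(1 for a in self.assignments if a.status == "assigned")

    @property
    def n_rejected(self) -> int:
        return sum(1 for a in self.assignments if a.status == "rejected")


def demultiplex_pool(
    reads: Iterable[Read],
    sheet: SampleSheet,
    design: AmpliconDesign,
    forward_tags: TagSet,
    reverse_tags: TagSet,
    pool: str,
    strict_primers: bool = True,
    primer_prefix: int = 10,
) -> DemuxResult:
    """Assign every read of one pool to its sample (or a rejection reason).

    Every input read appears exactly once across assigned + rejected.
    Per-sample tables aggregate identical inserts with their counts; per-tag
    assignment counts are reported as a descriptive summary of tag yield.
    """
    sheet.validate_tags(forward_tags, reverse_tags)
    barcode_map = sheet.barcode_map(pool)  # raises KeyError on unknown pool
    sample_tables: dict[str, Counter] = {e.sample: Counter() for e in sheet.pool_entries(pool)}
    assignments: list[Assignment] = []
    reason_counts: Counter = Counter()
    ftag_counts: Counter = Counter()
    rtag_counts: Counter = Counter()

    for read in reads:
        a = parse_read_structure(
            read, design, forward_tags, reverse_tags,
            strict_primers=strict_primers, primer_prefix=primer_prefix,
            barcode_map=barcode_map,
        )
        assignments.append(a)
        if a.status == "assigned":
            sample_tables[a.sample][a.insert] += 1
            ftag_counts[a.ftag] += 1
            rtag_counts[a.rtag] += 1
        else:
            reason_counts[a.reason] += 1

    tag_rows = [("forward", t.label, ftag_counts.get(t.label, 0)) for t in forward_tags]
    tag_rows += [("reverse", t.label, rtag_counts.get(t.label, 0)) for t in reverse_tags]
    tag_counts = pd.DataFrame(tag_rows, columns=["role", "tag", "assigned_reads"])
    return DemuxResult(pool, sample_tables, assignments, reason_counts, tag_counts)


def read_sequences(path: str | Path) -> Iterator[Read]:
    """Stream reads from FASTA or FASTQ, plain or gzipped.

    Format is auto-detected from the (inner) extension, falling back to the
    first byte ('>' FASTA, '@' FASTQ).
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    ext = Path(stem).suffix.lower()
    if ext in (".fa", ".fasta", ".fna"):
        fmt = "fasta"
    elif ext in (".fq", ".fastq"):
        fmt = "fastq"
    else:
        with opener(path, "rt") as fh:
            first = fh.read(1)
        fmt = "fastq" if first == "@" else "fasta"
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, fmt):
            quals = rec.letter_annotations.get("phred_quality")
            yield Read(
                rec.id, str(rec.seq).upper(),
                tuple(quals) if quals is not None else None,
            )


def write_demux_outputs(result: DemuxResult, outdir: str | Path) -> None:
    """Per-sample FASTA of assigned inserts, an assignment log and a
    rejection-reason summary, all plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    per_read: dict[str, list[Assignment]] = {}
    for a in result.assignments:
        if a.status == "assigned":
            per_read.setdefault(a.sample, []).append(a)
    for sample, table in sorted(result.sample_tables.items()):
        lines = []
        for a in per_read.get(sample, []):
            lines.append(f">{a.read_id} ftag={a.ftag} rtag={a.rtag}\n{a.insert}\n")
        (outdir / f"{sample}.fasta").write_text("".join(lines))

    log = pd.DataFrame(
        [
            (a.read_id, a.status, a.sample or "", a.ftag or "", a.rtag or "",
             a.orientation or "", a.reason or "", int(a.recovered_tag))
            for a in result.assignments
        ],
        columns=["read", "status", "sample", "ftag", "rtag", "orientation", "reason", "recovered_tag"],
    )
    log.to_csv(outdir / "assignments.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        [(r, result.reason_counts.get(r, 0)) for r in REJECTION_REASONS],
        columns=["reason", "reads"],
    )
    summary.to_csv(outdir / "rejections.tsv", sep="\t", index=False)
    if result.tag_counts is not None:
        result.tag_counts.to_csv(outdir / "tag_counts.tsv", sep="\t", index=False)
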