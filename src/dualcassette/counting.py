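"""Junction-read counting from spliced alignments.

A read supports an exon–exon junction when its alignment contains an N
CIGAR operation whose gap coordinates match the junction's intron exactly
and enough aligned bases flank the gap on both sides (the *anchor* or
*overhang*).  Only uniquely mapped reads are counted ("single hits"):
multi-mappers are unreliable evidence near paralogous or repetitive exons.

The module parses SAM text (header optional, pre-decoded streams accepted),
extracts per-read junction observations from the CIGAR reference walk,
counts them against the six junctions of a dual-cassette event, and pools
per-sample count vectors into per-group vectors (pseudobulk pooling for
single-cell data, replicate pooling for bulk).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .events import JUNCTION_ORDER, CassetteEvent, Junction, enumerate_junctions

__all__ = [
    "AlignedRead",
    "JunctionObservation",
    "JunctionCountVector",
    "UniquenessPolicy",
    "SamParseError",
    "parse_alignments",
    "junctions_of_read",
    "count_junction_reads",
    "count_sam",
    "read_junction_table",
    "write_junction_table",
    "read_sj_tab",
    "read_grouping_table",
    "pool_counts",
]

logger = logging.getLogger(__name__)

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_VALID_OPS = set("MIDNSH=X")

#: distance (nt) within which a non-matching gap is flagged as a near-miss
NEAR_MISS_TOL = 2


class SamParseError(ValueError):
    """Malformed SAM record; message carries the 1-based line number."""


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read with a parsed CIGAR."""

    read_id: str
    chrom: str
    pos: int  # 1-based leftmost mapped reference base
    cigar: tuple[tuple[str, int], ...]  # (op, length)
    mapq: int
    flags: int
    nh_tag: int | None = None


@dataclass(frozen=True)
class JunctionObservation:
    """One splice gap observed in a read.

    ``donor``/``acceptor`` are the genomic last-base-before and
    first-base-after the N gap (always donor < acceptor, genomic order).
    Anchors count aligned reference-consuming bases (M/=/X/D) in the
    alignment segment on each side of the gap.
    """

    donor: int
    acceptor: int
    left_anchor: int
    right_anchor: int


@dataclass(frozen=True)
class JunctionCountVector:
    """Junction-read counts for one sample (or pooled group).

    ``counts`` follows the canonical junction order
    (C1A1, C1A2, C1C2, A1A2, A1C2, A2C2).  Diagnostic tallies do not take
    part in equality so that table round-trips compare on counts alone.
    """

    sample_id: str
    counts: tuple[int, int, int, int, int, int]
    n_discarded_nonunique: int = field(default=0, compare=False)
    n_discarded_anchor: int = field(default=0, compare=False)
    n_off_event: int = field(default=0, compare=False)
    n_non_junction: int = field(default=0, compare=False)
    n_near_miss: int = field(default=0, compare=False)
    n_reads_seen: int = field(default=0, compare=False)
    n_reads_counted: int = field(default=0, compare=False)
    n_members: int | None = field(default=None, compare=False)
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if len(self.counts) != 6:
            raise ValueError(f"counts must have 6 entries, got {len(self.counts)}")
        if any((c < 0 or int(c) != c) for c in self.counts):
            raise ValueError(f"counts must be non-negative integers: {self.counts}")

    @property
    def total(self) -> int:
        return int(sum(self.counts))

    def as_dict(self) -> dict[str, int]:
        return dict(zip(JUNCTION_ORDER, self.counts))


@dataclass(frozen=True)
class UniquenessPolicy:
    """How "unambiguously mapped" is decided.

    If the NH tag is present and ``require_nh_one`` is set, the read must
    report exactly one hit; otherwise MAPQ must reach ``min_mapq``.
    """

    require_nh_one: bool = True
    min_mapq: int = 10

    def passes(self, read: AlignedRead) -> bool:
        if self.require_nh_one and read.nh_tag is not None:
            return read.nh_tag == 1
        return read.mapq >= self.min_mapq


def _parse_cigar(text: str, lineno: int) -> tuple[tuple[str, int], ...]:
    if text == "*":
        return ()
    ops = []
    consumed = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != consumed:
            break
        consumed = m.end()
        ops.append((m.group(2), int(m.group(1))))
    if consumed != len(text) or not ops:
        raise SamParseError(f"line {lineno}: malformed CIGAR {text!r}")
    for op, _ in ops:
        if op not in _VALID_OPS:
            raise SamParseError(f"line {lineno}: unsupported CIGAR operation {op!r} in {text!r}")
    return tuple(ops)


def parse_alignments(source: str | Path | Iterable[str]) -> Iterator[AlignedRead]:
    """Parse SAM text into :class:`AlignedRead` records.

    *source* may be a file path or any iterable of SAM lines (so already
    decoded streams, e.g. from ``samtools view``, plug in directly).
    Header lines are skipped; a header is not required.  Unmapped (0x4),
    secondary (0x100) and supplementary (0x800) records are skipped.

    Raises
    ------
    SamParseError
        On a record with fewer than 11 mandatory columns or a malformed
        CIGAR; the message names the offending line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            yield from parse_alignments(fh)
        return
    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        cols = line.split("\t")
        if len(cols) < 11:
            raise SamParseError(
                f"line {lineno}: expected 11 mandatory SAM columns, got {len(cols)}"
            )
        try:
            flags = int(cols[1])
            pos = int(cols[3])
            mapq = int(cols[4])
        except ValueError as exc:
            raise SamParseError(f"line {lineno}: non-integer mandatory field: {exc}") from exc
        if flags & 0x4 or flags & 0x100 or flags & 0x800:
            continue
        nh = None
        for tag in cols[11:]:
            if tag.startswith("NH:i:"):
                nh = int(tag[5:])
                break
        yield AlignedRead(
            read_id=cols[0],
            chrom=cols[2],
            pos=pos,
            cigar=_parse_cigar(cols[5], lineno),
            mapq=mapq,
            flags=flags,
            nh_tag=nh,
        )


def junctions_of_read(read: AlignedRead) -> list[JunctionObservation]:
    """Extract one observation per N operation by walking the CIGAR.

    The anchor on each side of a gap is the number of aligned
    reference-consuming bases (M/=/X/D) in the contiguous alignment
    segment bounded by the read end or the neighbouring N; insertions and
    clips contribute no anchor.
    """
    # split the alignment into segments separated by N gaps; each segment
    # keeps its aligned reference span
    segments: list[int] = []  # aligned (M/=/X/D) length per segment
    gaps: list[tuple[int, int]] = []  # (donor, acceptor) per N
    ref = read.pos
    seg_aligned = 0
    for op, length in read.cigar:
        if op == "N":
            gaps.append((ref - 1, ref + length))
            segments.append(seg_aligned)
            seg_aligned = 0
            ref += length
        elif op in "M=XD":
            seg_aligned += length
            ref += length
        # I/S/H consume no reference and add no anchor
    segments.append(seg_aligned)
    return [
        JunctionObservation(
            donor=donor,
            acceptor=acceptor,
            left_anchor=segments[i],
            right_anchor=segments[i + 1],
        )
        for i, (donor, acceptor) in enumerate(gaps)
    ]


def count_junction_reads(
    reads: Iterable[AlignedRead],
    junctions: Sequence[Junction],
    *,
    min_overhang: int = 5,
    uniqueness: UniquenessPolicy | None = None,
    chrom: str | None = None,
    count_once: bool = False,
    sample_id: str = "sample",
) -> JunctionCountVector:
    """Count reads supporting each of the six event junctions.

    A read increments junction *j* when one of its observations matches
    *j*'s gap exactly and both anchors reach ``min_overhang`` and the read
    passes the uniqueness policy.  By default a read spanning two event
    junctions (short cassette exon, long read) increments both, matching
    how splice-junction tables are defined; ``count_once`` restricts each
    read to a single increment (its leftmost matched junction).

    Reads on a different chromosome than *chrom* (when given) are tallied
    as off-event; if no read matches the chromosome a warning is recorded.
    """
    if min_overhang < 1:
        raise ValueError("min_overhang must be >= 1")
    if uniqueness is None:
        uniqueness = UniquenessPolicy()
    key_to_idx = {j.genomic_key: i for i, j in enumerate(junctions)}
    counts = [0] * 6
    n_nonunique = n_anchor = n_off = n_nonjunc = n_near = 0
    n_seen = 0
    n_counted_reads = 0
    n_chrom_match = 0
    for read in reads:
        n_seen += 1
        if chrom is not None and read.chrom != chrom:
            n_off += 1
            continue
        n_chrom_match += 1
        obs = junctions_of_read(read)
        if not obs:
            n_nonjunc += 1
            continue
        if not uniqueness.passes(read):
            n_nonunique += 1
            continue
        matched_ok = []
        any_anchor_fail = False
        any_match_attempt = False
        for o in obs:
            idx = key_to_idx.get((o.donor, o.acceptor))
            if idx is None:
                if any(
                    abs(o.donor - k[0]) <= NEAR_MISS_TOL and abs(o.acceptor - k[1]) <= NEAR_MISS_TOL
                    for k in key_to_idx
                ):
                    n_near += 1
                continue
            any_match_attempt = True
            if o.left_anchor >= min_overhang and o.right_anchor >= min_overhang:
                matched_ok.append(idx)
            else:
                any_anchor_fail = True
        if matched_ok:
            n_counted_reads += 1
            if count_once:
                counts[min(matched_ok, key=lambda i: junctions[i].genomic_key)] += 1
            else:
                for idx in matched_ok:
                    counts[idx] += 1
        elif any_anchor_fail:
            n_anchor += 1
        elif any_match_attempt:
            pass  # unreachable: a match either counts or anchor-fails
        else:
            n_off += 1
    warnings = ()
    if chrom is not None and n_seen > 0 and n_chrom_match == 0:
        warnings = (f"no read on chromosome {chrom!r}; all counts zero",)
        logger.warning(warnings[0])
    return JunctionCountVector(
        sample_id=sample_id,
        counts=tuple(counts),
        n_discarded_nonunique=n_nonunique,
        n_discarded_anchor=n_anchor,
        n_off_event=n_off,
        n_non_junction=n_nonjunc,
        n_near_miss=n_near,
        n_reads_seen=n_seen,
        n_reads_counted=n_counted_reads,
        warnings=warnings,
    )


def count_sam(
    source: str | Path | Iterable[str],
    event: CassetteEvent,
    *,
    min_overhang: int = 5,
    uniqueness: UniquenessPolicy | None = None,
    count_once: bool = False,
    sample_id: str = "sample",
) -> JunctionCountVector:
    """Parse a SAM source and count it against *event*'s junctions."""
    return count_junction_reads(
        parse_alignments(source),
        enumerate_junctions(event),
        min_overhang=min_overhang,
        uniqueness=uniqueness,
        chrom=event.chrom,
        count_once=count_once,
        sample_id=sample_id,
    )


# ---------------------------------------------------------------------------
# tabular I/O


def write_junction_table(vectors: Sequence[JunctionCountVector], path: str | Path) -> None:
    """Write a long-format junction-count TSV (sample_id, junction_label, count)."""
    rows = [
        {"sample_id": v.sample_id, "junction_label": label, "count": c}
        for v in vectors
        for label, c in zip(JUNCTION_ORDER, v.counts)
    ]
    pd.DataFrame(rows, columns=["sample_id", "junction_label", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_junction_table(path: str | Path) -> list[JunctionCountVector]:
    """Read a junction-count TSV written by :func:`write_junction_table`.

    Missing junction rows default to 0; unknown labels and negative or
    non-integer counts raise with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"sample_id", "junction_label", "count"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: junction table needs columns {sorted(required)}")
    vectors: dict[str, list[int]] = {}
    order: list[str] = []
    for rownum, row in enumerate(df.itertuples(index=False), start=2):
        label = row.junction_label
        if label not in JUNCTION_ORDER:
            raise ValueError(f"{path} row {rownum}: unknown junction label {label!r}")
        try:
            count = int(row.count)
        except (TypeError, ValueError):
            raise ValueError(
                f"{path} row {rownum}: non-integer count {row.count!r}"
            ) from None
        if count < 0 or float(row.count) != count:
            raise ValueError(f"{path} row {rownum}: invalid count {row.count!r}")
        sid = str(row.sample_id)
        if sid not in vectors:
            vectors[sid] = [0] * 6
            order.append(sid)
        vectors[sid][JUNCTION_ORDER.index(label)] += count
    return [JunctionCountVector(sample_id=s, counts=tuple(vectors[s])) for s in order]


def read_sj_tab(
    path: str | Path,
    junctions: Sequence[Junction],
    *,
    chrom: str | None = None,
    sample_id: str = "sample",
) -> JunctionCountVector:
    """Read a splice-junction tab file (the common 9-column aligner output).

    Columns: chrom, intron first base, intron last base (both 1-based),
    strand code, motif, annotated, unique-read count, multi-read count,
    max overhang.  An intron (s, e) corresponds to the junction whose gap
    is donor = s − 1, acceptor = e + 1.  Only unique-read counts are used;
    introns not matching one of the six event junctions are ignored.
    """
    key_to_idx = {j.genomic_key: i for i, j in enumerate(junctions)}
    counts = [0] * 6
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 7:
                raise ValueError(f"{path} line {lineno}: expected >=7 columns")
            if chrom is not None and cols[0] != chrom:
                continue
            try:
                intron_start, intron_end, uniq = int(cols[1]), int(cols[2]), int(cols[6])
            except ValueError as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
            idx = key_to_idx.get((intron_start - 1, intron_end + 1))
            if idx is not None:
                counts[idx] += uniq
    return JunctionCountVector(sample_id=sample_id, counts=tuple(counts))


def read_grouping_table(path: str | Path) -> dict[str, str]:
    """Read a grouping TSV (columns sample_id, group_id) into a mapping."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"sample_id", "group_id"}.issubset(df.columns):
        raise ValueError(f"{path}: grouping table needs columns sample_id, group_id")
    mapping: dict[str, str] = {}
    for row in df.itertuples(index=False):
        sid, gid = str(row.sample_id), str(row.group_id)
        if sid in mapping and mapping[sid] != gid:
            raise ValueError(f"{path}: sample {sid!r} assigned to two groups")
        mapping[sid] = gid
    return mapping


def pool_counts(
    vectors: Sequence[JunctionCountVector],
    grouping: Mapping[str, str],
    *,
    strict: bool = True,
) -> list[JunctionCountVector]:
    """Pool per-sample count vectors into per-group vectors.

    Group counts are elementwise integer sums over member samples
    (replicate pooling in bulk, pseudobulk pooling in single-cell data).
    Groups named in *grouping* but with no sample present are retained as
    all-zero vectors with 0 members.  Under ``strict`` an unassigned
    sample raises; otherwise it is dropped and logged.
    """
    groups: dict[str, list[int]] = {g: [0] * 6 for g in dict.fromkeys(grouping.values())}
    members: dict[str, int] = {g: 0 for g in groups}
    # nonunique, anchor, off, nonjunc, near, seen, counted
    diag = {g: [0, 0, 0, 0, 0, 0, 0] for g in groups}
    n_dropped = 0
    for v in vectors:
        gid = grouping.get(v.sample_id)
        if gid is None:
            if strict:
                raise ValueError(f"sample {v.sample_id!r} has no group assignment")
            n_dropped += 1
            continue
        groups[gid] = [a + b for a, b in zip(groups[gid], v.counts)]
        members[gid] += 1
        d = diag[gid]
        d[0] += v.n_discarded_nonunique
        d[1] += v.n_discarded_anchor
        d[2] += v.n_off_event
        d[3] += v.n_non_junction
        d[4] += v.n_near_miss
        d[5] += v.n_reads_seen
        d[6] += v.n_reads_counted
    if n_dropped:
        logger.info("pool_counts: dropped %d unassigned samples", n_dropped)
    return [
        JunctionCountVector(
            sample_id=gid,
            counts=tuple(groups[gid]),
            n_discarded_nonunique=diag[gid][0],
            n_discarded_anchor=diag[gid][1],
            n_off_event=diag[gid][2],
            n_non_junction=diag[gid][3],
            n_near_miss=diag[gid][4],
            n_reads_seen=diag[gid][5],
            n_reads_counted=diag[gid][6],
            n_members=members[gid],
        )
        for gid in groups
    ]
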