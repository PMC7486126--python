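"""Dual-cassette-exon event model.

A *dual-cassette event* consists of two adjacent cassette exons (A1, A2)
flanked by two constitutive exons (C1 upstream, C2 downstream in transcript
orientation).  Four isoforms are possible — skipping both cassettes (SKIP,
often written "−A"), including only A1, only A2, or both (A1A2) — and the
event defines exactly six exon–exon junctions.  Each isoform is identified
by the subset of junctions its mature mRNA contains, which is what makes
junction-read counts informative about isoform abundance.

Coordinates are 1-based inclusive (GTF convention) throughout.  Events on
the minus strand are described in *transcript* orientation: C1 is the first
exon transcribed, so its genomic coordinates are the highest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "JUNCTION_ORDER",
    "ISOFORM_ORDER",
    "ISOFORM_JUNCTIONS",
    "CassetteEvent",
    "Junction",
    "EventValidationError",
    "EventParseError",
    "build_event",
    "event_from_dict",
    "load_event",
    "enumerate_junctions",
    "build_design_matrix",
]

#: Canonical junction order used for every count vector and matrix row.
JUNCTION_ORDER: tuple[str, ...] = ("C1A1", "C1A2", "C1C2", "A1A2", "A1C2", "A2C2")

#: Canonical isoform (column) order.
ISOFORM_ORDER: tuple[str, ...] = ("SKIP", "A1", "A2", "A1A2")

#: Junction membership of each isoform's mature mRNA.
ISOFORM_JUNCTIONS: Mapping[str, frozenset[str]] = {
    "SKIP": frozenset({"C1C2"}),
    "A1": frozenset({"C1A1", "A1C2"}),
    "A2": frozenset({"C1A2", "A2C2"}),
    "A1A2": frozenset({"C1A1", "A1A2", "A2C2"}),
}

_EXON_NAMES = ("c1", "a1", "a2", "c2")


class EventValidationError(ValueError):
    """An event specification violates the dual-cassette geometry."""


class EventParseError(ValueError):
    """An event record is missing fields or has malformed values."""


@dataclass(frozen=True)
class CassetteEvent:
    """One dual-cassette splicing event.

    Exon intervals are ``(start, end)`` 1-based inclusive genomic
    coordinates with ``start <= end``; exon names are transcript-oriented
    (C1 is transcribed first even on the minus strand).
    """

    event_id: str
    chrom: str
    strand: str
    c1: tuple[int, int]
    a1: tuple[int, int]
    a2: tuple[int, int]
    c2: tuple[int, int]

    def __post_init__(self) -> None:
        if not self.chrom:
            raise EventValidationError("chrom must be non-empty")
        if self.strand not in {"+", "-"}:
            raise EventValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        for name in _EXON_NAMES:
            start, end = getattr(self, name)
            if start < 1 or end < start:
                raise EventValidationError(
                    f"exon {name} interval ({start},{end}) is empty or not 1-based"
                )
        # genomic left-to-right exon order: transcript order on '+',
        # reversed on '-'
        genomic = list(_EXON_NAMES) if self.strand == "+" else list(reversed(_EXON_NAMES))
        for up, dn in zip(genomic, genomic[1:]):
            if getattr(self, up)[1] >= getattr(self, dn)[0]:
                raise EventValidationError(
                    f"exons {up} and {dn} overlap or are mis-ordered on strand {self.strand}: "
                    f"{getattr(self, up)} vs {getattr(self, dn)}"
                )

    def exon(self, name: str) -> tuple[int, int]:
        return getattr(self, name.lower())

    def exon_length(self, name: str) -> int:
        start, end = self.exon(name)
        return end - start + 1


@dataclass(frozen=True)
class Junction:
    """One exon–exon junction of a dual-cassette event.

    ``donor`` is the last exonic base of the upstream exon and ``acceptor``
    the first exonic base of the downstream exon, both in transcript sense.
    ``genomic_key`` is the same pair ordered left-to-right on the genome,
    which is what a spliced alignment's N gap reports regardless of strand.
    """

    label: str
    donor: int
    acceptor: int

    @property
    def genomic_key(self) -> tuple[int, int]:
        return (self.donor, self.acceptor) if self.donor < self.acceptor else (self.acceptor, self.donor)


def _transcript_boundaries(event: CassetteEvent, name: str) -> tuple[int, int]:
    """(last transcribed base, first transcribed base) of an exon."""
    start, end = event.exon(name)
    if event.strand == "+":
        return end, start
    return start, end


def enumerate_junctions(event: CassetteEvent) -> list[Junction]:
    """Enumerate the six junctions of *event* in canonical order.

    Order is ``C1A1, C1A2, C1C2, A1A2, A1C2, A2C2``.  Donor/acceptor
    coordinates follow deterministically from the exon boundaries.
    """
    pairs = {
        "C1A1": ("c1", "a1"),
        "C1A2": ("c1", "a2"),
        "C1C2": ("c1", "c2"),
        "A1A2": ("a1", "a2"),
        "A1C2": ("a1", "c2"),
        "A2C2": ("a2", "c2"),
    }
    out = []
    for label in JUNCTION_ORDER:
        up, dn = pairs[label]
        donor, _ = _transcript_boundaries(event, up)
        _, acceptor_first = _transcript_boundaries(event, dn)
        out.append(Junction(label=label, donor=donor, acceptor=acceptor_first))
    return out


def build_design_matrix(junctions: Sequence[Junction] | None = None) -> np.ndarray:
    """Build the 6×4 binary junction-by-isoform membership matrix.

    Rows follow :data:`JUNCTION_ORDER`, columns :data:`ISOFORM_ORDER`;
    entry (j, i) is 1 iff junction j is part of isoform i's mRNA.  The
    matrix depends only on the event topology, so it is identical for
    every valid event; *junctions* is accepted (and its length checked)
    so call sites can stay symmetrical with :func:`enumerate_junctions`.
    """
    if junctions is not None:
        if len(junctions) != 6:
            raise ValueError(f"expected 6 junctions, got {len(junctions)}")
        labels = [j.label for j in junctions]
        if labels != list(JUNCTION_ORDER):
            raise ValueError(f"junctions not in canonical order: {labels}")
    A = np.zeros((6, 4), dtype=float)
    for i, iso in enumerate(ISOFORM_ORDER):
        for j, jn in enumerate(JUNCTION_ORDER):
            if jn in ISOFORM_JUNCTIONS[iso]:
                A[j, i] = 1.0
    return A


def event_from_dict(spec: Mapping[str, object]) -> CassetteEvent:
    """Build a validated event from a flat record.

    Required keys: ``event_id, chrom, strand, c1_start, c1_end, a1_start,
    a1_end, a2_start, a2_end, c2_start, c2_end``.
    """
    missing = [
        k
        for k in ("event_id", "chrom", "strand")
        if k not in spec or spec[k] in (None, "")
    ]
    intervals = {}
    for name in _EXON_NAMES:
        try:
            intervals[name] = (int(spec[f"{name}_start"]), int(spec[f"{name}_end"]))
        except KeyError:
            missing.append(f"{name}_start/{name}_end")
        except (TypeError, ValueError) as exc:
            raise EventParseError(f"non-integer coordinate for exon {name}: {exc}") from exc
    if missing:
        raise EventParseError(f"event record missing fields: {', '.join(missing)}")
    strand = str(spec["strand"])
    if strand in {"−", "minus"}:  # tolerate the typographic minus
        strand = "-"
    return CassetteEvent(
        event_id=str(spec["event_id"]),
        chrom=str(spec["chrom"]),
        strand=strand,
        **intervals,
    )


# alias matching the operation name used throughout the docs
build_event = event_from_dict


def load_event(path: str) -> CassetteEvent:
    """Load an event specification from a YAML or TSV file.

    YAML: a mapping with the keys of :func:`event_from_dict`.
    TSV: a header line with those column names plus one data row.
    """
    import yaml

    with open(path) as fh:
        text = fh.read()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    if "\t" in first:
        lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
        if len(lines) < 2:
            raise EventParseError(f"{path}: TSV event spec needs a header and one row")
        header = lines[0].split("\t")
        row = lines[1].split("\t")
        if len(header) != len(row):
            raise EventParseError(f"{path}: header/row column count mismatch")
        return event_from_dict(dict(zip(header, row)))
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise EventParseError(f"{path}: YAML event spec must be a mapping")
    return event_from_dict(data)
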