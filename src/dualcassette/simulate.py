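"""Synthetic junction-count and spliced-alignment generation.

Every stage of the pipeline can be exercised without external data by
simulating from the forward model: true isoform fractions f induce
junction probabilities p = A·f / Σ(A·f), junction counts are multinomial
(or independent Poisson) draws over p at a chosen depth, and spliced reads
are placed uniformly along each isoform's mature mRNA and written as SAM
records whose CIGARs encode the introns as N gaps.  Ground truth — the
generating fractions, the exact junction counts of the emitted reads —
is recorded alongside so counting and estimation can be checked exactly.

Single-cell data are emulated by giving each cell a Poisson-distributed
read total at low mean depth (most cells contribute 0–20 junction reads)
and pooling within cell groups, which is why pooling precedes estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .counting import JunctionCountVector
from .events import (
    ISOFORM_ORDER,
    JUNCTION_ORDER,
    CassetteEvent,
    build_design_matrix,
    enumerate_junctions,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "DEFAULT_TOY_EVENT",
    "expected_junction_probs",
    "simulate_junction_counts",
    "simulate_cell_population",
    "simulate_alignments",
]

#: Exons an isoform's mature mRNA contains, in transcript order.
ISOFORM_EXONS: Mapping[str, tuple[str, ...]] = {
    "SKIP": ("c1", "c2"),
    "A1": ("c1", "a1", "c2"),
    "A2": ("c1", "a2", "c2"),
    "A1A2": ("c1", "a1", "a2", "c2"),
}


def _default_toy_event() -> CassetteEvent:
    # C1=300, A1=60, A2=60, C2=300 nt with 100-nt introns: the 60-nt
    # cassettes are shorter than a 100-nt read, so reads can span two
    # junctions at once — the geometry the counter must handle.
    return CassetteEvent(
        event_id="toy",
        chrom="chrT",
        strand="+",
        c1=(1, 300),
        a1=(401, 460),
        a2=(561, 620),
        c2=(721, 1020),
    )


DEFAULT_TOY_EVENT: CassetteEvent = _default_toy_event()


@dataclass(frozen=True)
class SimulationConfig:
    """Generating conditions for one simulated dataset.

    fractions
        True isoform fractions (SKIP, A1, A2, A1A2), summing to 1.
    depth
        Expected total junction reads (bulk) or per-cell mean (single
        cell).  Bulk junction coverage is typically 10³–10⁵ reads; single
        cells contribute 0–20.
    noise
        ``multinomial`` draws a fixed total over the junction
        probabilities; ``poisson`` draws each junction independently.
    read_length, guaranteed_anchor
        Read geometry for alignment simulation; truth only credits a
        junction observation whose anchors reach ``guaranteed_anchor``.
    """

    fractions: tuple[float, float, float, float]
    depth: float = 10_000.0
    noise: str = "multinomial"
    n_cells: int = 0
    read_length: int = 100
    guaranteed_anchor: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (4,) or np.any(f < 0):
            raise ValueError("fractions must be 4 non-negative reals")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {f.sum()!r}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.noise not in {"multinomial", "poisson"}:
            raise ValueError(f"noise must be 'multinomial' or 'poisson', got {self.noise!r}")
        if self.read_length <= 2 * self.guaranteed_anchor:
            raise ValueError("read_length must exceed 2 * guaranteed_anchor")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth bookkeeping for a simulated dataset."""

    fractions: tuple[float, float, float, float] | Mapping[str, tuple[float, ...]]
    junction_probs: tuple[float, ...] | Mapping[str, tuple[float, ...]]
    per_sample_counts: Mapping[str, tuple[int, ...]]
    seed: int
    extras: Mapping[str, object] = field(default_factory=dict)

    def pooled_counts(self, members: Sequence[str] | None = None) -> tuple[int, ...]:
        names = list(self.per_sample_counts) if members is None else list(members)
        totals = np.zeros(6, dtype=int)
        for name in names:
            totals += np.asarray(self.per_sample_counts[name], dtype=int)
        return tuple(int(v) for v in totals)


def expected_junction_probs(
    fractions: Sequence[float], design: np.ndarray | None = None
) -> np.ndarray:
    """Junction probabilities p = A·f / Σ(A·f) implied by isoform mix f."""
    f = np.asarray(fractions, dtype=float)
    if f.shape != (4,) or np.any(f < 0):
        raise ValueError("fractions must be 4 non-negative reals")
    if f.sum() <= 0:
        raise ValueError("fractions must not be all zero")
    A = build_design_matrix() if design is None else np.asarray(design, dtype=float)
    expected = A @ f
    return expected / expected.sum()


def simulate_junction_counts(
    config: SimulationConfig, *, sample_id: str = "sim"
) -> tuple[JunctionCountVector, SimulationTruth]:
    """Draw one junction-count vector from the forward model."""
    probs = expected_junction_probs(config.fractions)
    rng = np.random.default_rng(config.seed)
    if config.noise == "multinomial":
        counts = rng.multinomial(int(round(config.depth)), probs)
    else:
        counts = rng.poisson(config.depth * probs)
    vec = JunctionCountVector(sample_id=sample_id, counts=tuple(int(v) for v in counts))
    truth = SimulationTruth(
        fractions=tuple(config.fractions),
        junction_probs=tuple(float(p) for p in probs),
        per_sample_counts={sample_id: vec.counts},
        seed=config.seed,
    )
    return vec, truth


def simulate_cell_population(
    group_fractions: Mapping[str, Sequence[float]],
    *,
    n_cells: int = 200,
    depth_mean: float = 5.0,
    seed: int = 0,
) -> tuple[list[JunctionCountVector], dict[str, str], SimulationTruth]:
    """Simulate single cells in annotated groups (cell types).

    Each cell's junction-read total is Poisson(``depth_mean``) — zeros are
    common and realistic — and its counts are multinomial over its group's
    junction probabilities.  Returns per-cell count vectors, the grouping
    table, and truth with per-cell and per-group bookkeeping.
    """
    if not group_fractions:
        raise ValueError("need at least one group")
    if depth_mean < 0:
        raise ValueError("depth_mean must be >= 0")
    rng = np.random.default_rng(seed)
    vectors: list[JunctionCountVector] = []
    grouping: dict[str, str] = {}
    per_sample: dict[str, tuple[int, ...]] = {}
    probs_by_group = {
        g: tuple(float(p) for p in expected_junction_probs(f))
        for g, f in group_fractions.items()
    }
    for gid, probs in probs_by_group.items():
        p = np.asarray(probs)
        for i in range(n_cells):
            cid = f"{gid}_cell{i:04d}"
            total = int(rng.poisson(depth_mean))
            counts = rng.multinomial(total, p) if total > 0 else np.zeros(6, dtype=int)
            vec = JunctionCountVector(sample_id=cid, counts=tuple(int(v) for v in counts))
            vectors.append(vec)
            grouping[cid] = gid
            per_sample[cid] = vec.counts
    truth = SimulationTruth(
        fractions={g: tuple(float(x) for x in f) for g, f in group_fractions.items()},
        junction_probs=probs_by_group,
        per_sample_counts=per_sample,
        seed=seed,
        extras={"n_cells": n_cells, "depth_mean": depth_mean},
    )
    return vectors, grouping, truth


# ---------------------------------------------------------------------------
# spliced-read simulation


def _transcript_exons(event: CassetteEvent, isoform: str) -> list[tuple[int, int]]:
    """Genomic intervals of an isoform's exons, in transcript order."""
    return [event.exon(name) for name in ISOFORM_EXONS[isoform]]


def _read_segments(
    event: CassetteEvent, isoform: str, t_start: int, length: int
) -> list[tuple[int, int]]:
    """Genomic intervals covered by a read at 0-based transcript offset."""
    segments: list[tuple[int, int]] = []
    remaining = length
    offset = t_start
    for start, end in _transcript_exons(event, isoform):
        exon_len = end - start + 1
        if offset >= exon_len:
            offset -= exon_len
            continue
        take = min(exon_len - offset, remaining)
        if event.strand == "+":
            g_start = start + offset
            segments.append((g_start, g_start + take - 1))
        else:
            g_end = end - offset
            segments.append((g_end - take + 1, g_end))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past the transcript end")
    return sorted(segments)


def simulate_alignments(
    event: CassetteEvent,
    config: SimulationConfig,
    n_reads: int,
) -> tuple[str, SimulationTruth]:
    """Emit spliced single-end SAM reads from the isoform mixture.

    Each read draws its isoform from the true fractions and a uniform
    start along that isoform's spliced mRNA; the record's CIGAR encodes M
    segments split by N gaps at the introns, with ``NH:i:1`` (all reads
    unique).  Exon-body reads are emitted too — the counter must ignore
    them.  Truth tallies, per junction, the emitted observations whose
    anchors both reach ``config.guaranteed_anchor``; counting the SAM with
    ``min_overhang == guaranteed_anchor`` reproduces these tallies
    exactly.
    """
    L = config.read_length
    fractions = np.asarray(config.fractions, dtype=float)
    for iso, frac in zip(ISOFORM_ORDER, fractions):
        if frac > 0:
            t_len = sum(event.exon_length(n) for n in ISOFORM_EXONS[iso])
            if t_len < L:
                raise ValueError(
                    f"isoform {iso} transcript ({t_len} nt) shorter than read length {L}"
                )
    junctions = enumerate_junctions(event)
    key_to_idx = {j.genomic_key: i for i, j in enumerate(junctions)}
    rng = np.random.default_rng(config.seed)
    truth_counts = np.zeros(6, dtype=int)
    # Reads are sampled uniformly over the pooled read-placement space:
    # an isoform is drawn with probability ∝ fraction × placements
    # (T − L + 1), the standard reads ∝ molar abundance × length model.
    # Every junction then offers the same L − 1 spanning placements per
    # transcript, which is exactly the binary-design assumption of the
    # estimator.
    placements = np.array(
        [
            sum(event.exon_length(n) for n in ISOFORM_EXONS[iso]) - L + 1
            for iso in ISOFORM_ORDER
        ],
        dtype=float,
    )
    weights = fractions * placements
    weights /= weights.sum()
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        f"@SQ\tSN:{event.chrom}\tLN:{event.c2[1] + 1000 if event.strand == '+' else event.c1[1] + 1000}",
    ]
    iso_draws = rng.choice(4, size=n_reads, p=weights)
    for ridx in range(n_reads):
        iso = ISOFORM_ORDER[int(iso_draws[ridx])]
        t_len = sum(event.exon_length(n) for n in ISOFORM_EXONS[iso])
        t_start = int(rng.integers(0, t_len - L + 1))
        segments = _read_segments(event, iso, t_start, L)
        cigar_parts = []
        for i, (s, e) in enumerate(segments):
            if i > 0:
                gap = s - segments[i - 1][1] - 1
                cigar_parts.append(f"{gap}N")
            cigar_parts.append(f"{e - s + 1}M")
        for i in range(len(segments) - 1):
            donor, acceptor = segments[i][1], segments[i + 1][0]
            left = segments[i][1] - segments[i][0] + 1
            right = segments[i + 1][1] - segments[i + 1][0] + 1
            idx = key_to_idx.get((donor, acceptor))
            if idx is not None and left >= config.guaranteed_anchor and right >= config.guaranteed_anchor:
                truth_counts[idx] += 1
        lines.append(
            "\t".join(
                [
                    f"read{ridx:06d}_{iso}",
                    "0",
                    event.chrom,
                    str(segments[0][0]),
                    "255",
                    "".join(cigar_parts),
                    "*",
                    "0",
                    "0",
                    "A" * L,
                    "*",
                    "NH:i:1",
                ]
            )
        )
    truth = SimulationTruth(
        fractions=tuple(float(f) for f in fractions),
        junction_probs=tuple(float(p) for p in expected_junction_probs(fractions)),
        per_sample_counts={"sim": tuple(int(v) for v in truth_counts)},
        seed=config.seed,
        extras={"n_reads": n_reads, "read_length": L},
    )
    return "\n".join(lines) + "\n", truth
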