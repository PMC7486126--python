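"""Pipeline orchestration: count → pool → estimate → report.

Chains the stages over SAM or junction-table inputs, applies the grouping
table (pseudobulk pooling), runs the estimator per group, and writes a
stable TSV report with one row per group.  Configuration comes from a
YAML file or is built programmatically; the CLI is a thin layer over
:func:`run_pipeline`, so library and command-line runs produce
byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import counting
from .counting import JunctionCountVector, UniquenessPolicy
from .estimate import EstimatorConfig, IsoformEstimate, estimate_isoforms
from .events import JUNCTION_ORDER, CassetteEvent, load_event

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "parse_config",
    "run_pipeline",
    "report_table",
    "write_report",
    "REPORT_COLUMNS",
]

logger = logging.getLogger(__name__)

#: Frozen report column order.
REPORT_COLUMNS: tuple[str, ...] = (
    "group_id",
    "n_samples",
    *JUNCTION_ORDER,
    "total_junction_reads",
    "frac_skip",
    "frac_a1",
    "frac_a2",
    "frac_a1a2",
    "inclusion_a1",
    "inclusion_a2",
    "sse",
    "qc_flag",
)


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name in the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline settings (defaults applied)."""

    event: str
    input_mode: str = "sam"  # or "junction_table"
    inputs: dict[str, str] = field(default_factory=dict)  # sample_id -> path
    groups: str | None = None
    min_overhang: int = 5
    count_once: bool = False
    require_nh_one: bool = True
    min_mapq: int = 10
    mode: str = "ls_clamp"
    min_total: int = 10
    include_intercept: bool = False
    out: str | None = None
    log_level: str = "INFO"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_mode not in {"sam", "junction_table"}:
            raise ValueError(f"input_mode must be 'sam' or 'junction_table', got {self.input_mode!r}")
        if self.min_overhang < 1:
            raise ValueError("min_overhang must be >= 1")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        EstimatorConfig(mode=self.mode, min_total=self.min_total,
                        include_intercept=self.include_intercept)  # validates

    def resolved_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def estimator_config(self) -> EstimatorConfig:
        return EstimatorConfig(
            mode=self.mode, min_total=self.min_total, include_intercept=self.include_intercept
        )


_BOOL_FIELDS = {"count_once", "require_nh_one", "include_intercept"}
_INT_FIELDS = {"min_overhang", "min_mapq", "min_total", "seed"}


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML pipeline config, applying documented defaults.

    Unknown keys raise, naming the key; type mismatches raise with the
    expected type.  The resolved config is echoed to the log so a run is
    reproducible from its log alone.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise PipelineError("config", f"{path}: config must be a YAML mapping")
    known = {f.name for f in dc_fields(PipelineConfig)}
    for key in data:
        if key not in known:
            raise PipelineError("config", f"{path}: unknown key {key!r}")
    if "inputs" in data:
        inputs = data["inputs"]
        if isinstance(inputs, list):
            data["inputs"] = {Path(p).stem: str(p) for p in inputs}
        elif isinstance(inputs, dict):
            data["inputs"] = {str(k): str(v) for k, v in inputs.items()}
        else:
            raise PipelineError("config", f"{path}: 'inputs' must be a list or mapping")
    for key in _BOOL_FIELDS & set(data):
        if not isinstance(data[key], bool):
            raise PipelineError("config", f"{path}: {key!r} must be a boolean")
    for key in _INT_FIELDS & set(data):
        if isinstance(data[key], bool) or not isinstance(data[key], int):
            raise PipelineError("config", f"{path}: {key!r} must be an integer")
    try:
        cfg = PipelineConfig(**data)
    except TypeError as exc:
        raise PipelineError("config", f"{path}: {exc}") from exc
    except ValueError as exc:
        raise PipelineError("config", str(exc)) from exc
    logger.info("resolved config: %s", cfg.resolved_dict())
    return cfg


def _fmt(value: float | None) -> str:
    return "NA" if value is None else format(float(value), ".6g")


def report_table(estimates: Sequence[IsoformEstimate]) -> list[dict[str, str]]:
    """Flatten estimates into report rows (stable column order, NA for missing)."""
    rows = []
    for est in estimates:
        f = est.fractions
        row = {
            "group_id": est.group_id,
            "n_samples": str(est.n_members if est.n_members is not None else 1),
            **{label: str(c) for label, c in zip(JUNCTION_ORDER, est.counts)},
            "total_junction_reads": str(est.total_junction_reads),
            "frac_skip": _fmt(f[0] if f else None),
            "frac_a1": _fmt(f[1] if f else None),
            "frac_a2": _fmt(f[2] if f else None),
            "frac_a1a2": _fmt(f[3] if f else None),
            "inclusion_a1": _fmt(est.inclusion_a1),
            "inclusion_a2": _fmt(est.inclusion_a2),
            "sse": _fmt(est.sse),
            "qc_flag": est.qc_flag,
        }
        rows.append(row)
    return rows


def write_report(estimates: Sequence[IsoformEstimate], path: str | Path) -> None:
    rows = report_table(estimates)
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row[col] for col in REPORT_COLUMNS) + "\n")


def _load_vectors(config: PipelineConfig, event: CassetteEvent) -> list[JunctionCountVector]:
    vectors: list[JunctionCountVector] = []
    if config.input_mode == "sam":
        policy = UniquenessPolicy(require_nh_one=config.require_nh_one, min_mapq=config.min_mapq)
        for sample_id, path in config.inputs.items():
            if not Path(path).exists():
                raise PipelineError("count", f"SAM file not found: {path}")
            try:
                vec = counting.count_sam(
                    path,
                    event,
                    min_overhang=config.min_overhang,
                    uniqueness=policy,
                    count_once=config.count_once,
                    sample_id=sample_id,
                )
            except counting.SamParseError as exc:
                raise PipelineError("count", f"{path}: {exc}") from exc
            logger.info(
                "count[%s]: seen=%d counted=%d nonunique=%d anchor=%d nonjunction=%d off_event=%d",
                sample_id, vec.n_reads_seen, vec.n_reads_counted,
                vec.n_discarded_nonunique, vec.n_discarded_anchor,
                vec.n_non_junction, vec.n_off_event,
            )
            vectors.append(vec)
    else:
        for _, path in config.inputs.items():
            if not Path(path).exists():
                raise PipelineError("count", f"junction table not found: {path}")
            try:
                vectors.extend(counting.read_junction_table(path))
            except ValueError as exc:
                raise PipelineError("count", str(exc)) from exc
    return vectors


def run_pipeline(config: PipelineConfig) -> list[IsoformEstimate]:
    """Run count → pool → estimate and (optionally) write the report TSV.

    Deterministic given inputs and config.  Stage failures raise
    :class:`PipelineError` tagged with the stage name.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    if not Path(config.event).exists():
        raise PipelineError("event", f"event spec not found: {config.event}")
    try:
        event = load_event(config.event)
    except ValueError as exc:
        raise PipelineError("event", str(exc)) from exc
    if not config.inputs:
        raise PipelineError("count", "no inputs configured")

    vectors = _load_vectors(config, event)

    try:
        if config.groups is not None:
            if not Path(config.groups).exists():
                raise PipelineError("pool", f"grouping table not found: {config.groups}")
            grouping = counting.read_grouping_table(config.groups)
        else:
            # bulk default: every sample is its own group
            grouping = {v.sample_id: v.sample_id for v in vectors}
        pooled = counting.pool_counts(vectors, grouping)
    except PipelineError:
        raise
    except ValueError as exc:
        raise PipelineError("pool", str(exc)) from exc
    for vec in pooled:
        logger.info("pool[%s]: members=%d total=%d", vec.sample_id, vec.n_members or 0, vec.total)

    try:
        est_cfg = config.estimator_config()
        estimates = [estimate_isoforms(vec, est_cfg) for vec in pooled]
    except ValueError as exc:
        raise PipelineError("estimate", str(exc)) from exc

    if config.out is not None:
        write_report(estimates, config.out)
        logger.info("report written to %s (%d groups)", config.out, len(estimates))
    return estimates
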