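"""Isoform abundance estimation from junction-count vectors.

The linear model: let A be the 6×4 binary junction-by-isoform membership
matrix and x the vector of isoform abundances in junction-read units.
Expected junction counts are A·x, so given an observed count vector c the
abundances are estimated by least squares, min‖A·x − c‖², either
unconstrained with negatives clamped to zero afterwards (``ls_clamp``, the
default) or under the non-negativity constraint x ≥ 0 (``nnls``).  A has
full column rank — every isoform owns a junction unique to it — so the
unconstrained solution is unique.

Estimates are reported as fractions x / Σx together with the two
inclusion statistics: inclusion(A1) = f(A1) + f(A1A2) and
inclusion(A2) = f(A2) + f(A1A2), the PSI-like quantities of interest.

The core is exposed as a scikit-learn transformer,
:class:`IsoformAbundanceEstimator`, mapping an (n_groups, 6) count matrix
to an (n_groups, 4) fraction matrix; the module-level functions are thin
wrappers over it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import scipy.optimize
from sklearn.base import BaseEstimator, TransformerMixin

from .counting import JunctionCountVector
from .events import ISOFORM_ORDER, build_design_matrix

__all__ = [
    "EstimatorConfig",
    "IsoformEstimate",
    "BootstrapIntervals",
    "IsoformAbundanceEstimator",
    "solve_least_squares",
    "solve_nnls",
    "estimate_isoforms",
    "inclusion_fractions",
    "bootstrap_fractions",
]

QC_OK = "ok"
QC_LOW_COVERAGE = "low_coverage"
QC_DEGENERATE = "degenerate"


@dataclass(frozen=True)
class EstimatorConfig:
    """Estimation settings.

    mode
        ``ls_clamp``: unconstrained least squares, negatives clamped to 0
        before normalisation (default).  ``nnls``: non-negative least
        squares.
    min_total
        Minimum pooled junction reads for fractions to be reported; below
        it the 4-parameter fit is too noisy to interpret and the estimate
        is flagged ``low_coverage`` with missing fractions.
    include_intercept
        Add a constant column to the fit.  The generative model has no
        background junction-read term, so the default is off.
    """

    mode: str = "ls_clamp"
    min_total: int = 10
    include_intercept: bool = False

    def __post_init__(self) -> None:
        if self.mode not in {"ls_clamp", "nnls"}:
            raise ValueError(f"mode must be 'ls_clamp' or 'nnls', got {self.mode!r}")
        if self.min_total < 0:
            raise ValueError("min_total must be >= 0")


class LeastSquaresFit(NamedTuple):
    abundance: np.ndarray  # 4 signed reals (SKIP, A1, A2, A1A2)
    intercept: float | None
    sse: float


@dataclass(frozen=True)
class IsoformEstimate:
    """Estimation result for one sample or pooled group."""

    group_id: str
    counts: tuple[int, ...]
    raw_abundance: tuple[float, float, float, float]
    clamped_abundance: tuple[float, float, float, float]
    fractions: tuple[float, float, float, float] | None
    inclusion_a1: float | None
    inclusion_a2: float | None
    total_junction_reads: int
    sse: float
    qc_flag: str
    intercept: float | None = None
    n_members: int | None = field(default=None, compare=False)

    def fraction(self, isoform: str) -> float | None:
        if self.fractions is None:
            return None
        return self.fractions[ISOFORM_ORDER.index(isoform)]


@dataclass(frozen=True)
class BootstrapIntervals:
    """2.5–97.5 percentile intervals from multinomial read resampling."""

    fractions: Mapping[str, tuple[float, float]] | None
    inclusion_a1: tuple[float, float] | None
    inclusion_a2: tuple[float, float] | None
    n_boot: int
    seed: int


def _counts_array(counts: JunctionCountVector | Sequence[float]) -> np.ndarray:
    if isinstance(counts, JunctionCountVector):
        c = np.asarray(counts.counts, dtype=float)
    else:
        c = np.asarray(counts, dtype=float)
    if c.shape != (6,):
        raise ValueError(f"expected 6 junction counts, got shape {c.shape}")
    if np.any(c < 0):
        raise ValueError("junction counts must be non-negative")
    return c


def solve_least_squares(
    counts: JunctionCountVector | Sequence[float],
    *,
    include_intercept: bool = False,
    design: np.ndarray | None = None,
) -> LeastSquaresFit:
    """Unconstrained least-squares fit of isoform abundances.

    Returns the unique minimiser of ‖A·x − c‖² (optionally with a constant
    column appended to A) plus the residual sum of squares.
    """
    c = _counts_array(counts)
    A = build_design_matrix() if design is None else np.asarray(design, dtype=float)
    M = np.hstack([A, np.ones((A.shape[0], 1))]) if include_intercept else A
    coef, _, _, _ = np.linalg.lstsq(M, c, rcond=None)
    resid = M @ coef - c
    sse = float(resid @ resid)
    if include_intercept:
        return LeastSquaresFit(coef[:4], float(coef[4]), sse)
    return LeastSquaresFit(coef, None, sse)


def solve_nnls(
    counts: JunctionCountVector | Sequence[float],
    *,
    design: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Non-negative least squares: min ‖A·x − c‖² s.t. x ≥ 0."""
    c = _counts_array(counts)
    A = build_design_matrix() if design is None else np.asarray(design, dtype=float)
    x, rnorm = scipy.optimize.nnls(A, c)
    return x, float(rnorm**2)


class IsoformAbundanceEstimator(BaseEstimator, TransformerMixin):
    """Least-squares isoform deconvolution as a scikit-learn transformer.

    ``transform`` maps an (n_groups, 6) junction-count matrix (canonical
    junction order) to an (n_groups, 4) isoform-fraction matrix (canonical
    isoform order); rows failing coverage QC come back as NaN.

    Parameters
    ----------
    mode : {"ls_clamp", "nnls"}
        See :class:`EstimatorConfig`.
    min_total : int
        Coverage floor below which fractions are NaN.
    include_intercept : bool
        Fit a constant background term (off by default).
    """

    def __init__(self, mode: str = "ls_clamp", min_total: int = 10, include_intercept: bool = False):
        self.mode = mode
        self.min_total = min_total
        self.include_intercept = include_intercept

    def _config(self) -> EstimatorConfig:
        return EstimatorConfig(
            mode=self.mode, min_total=self.min_total, include_intercept=self.include_intercept
        )

    def fit(self, X, y=None):
        self._config()  # validates parameters
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 6:
            raise ValueError(f"X must be (n_groups, 6), got {X.shape}")
        if np.any(X < 0):
            raise ValueError("junction counts must be non-negative")
        self.design_matrix_ = build_design_matrix()
        self.isoform_labels_ = list(ISOFORM_ORDER)
        self.n_features_in_ = 6
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "design_matrix_"):
            raise RuntimeError("estimator is not fitted; call fit(X) first")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 6:
            raise ValueError(f"X must be (n_groups, 6), got {X.shape}")
        out = np.full((X.shape[0], 4), np.nan)
        for i, row in enumerate(X):
            est = self.estimate_one(row)
            if est.fractions is not None:
                out[i] = est.fractions
        return out

    def estimate_one(
        self, counts: JunctionCountVector | Sequence[float], *, group_id: str | None = None
    ) -> IsoformEstimate:
        """Full estimation record for a single count vector."""
        cfg = self._config()
        c = _counts_array(counts)
        if group_id is None:
            group_id = counts.sample_id if isinstance(counts, JunctionCountVector) else "sample"
        n_members = counts.n_members if isinstance(counts, JunctionCountVector) else None
        total = int(round(c.sum()))
        intercept: float | None = None
        if cfg.mode == "nnls":
            x, sse = solve_nnls(c)
            raw = x.copy()
            clamped = x
        else:
            fit = solve_least_squares(c, include_intercept=cfg.include_intercept)
            raw = fit.abundance
            intercept = fit.intercept
            sse = fit.sse
            clamped = np.clip(raw, 0.0, None)
        clamped_sum = float(clamped.sum())
        if total < cfg.min_total:
            qc = QC_LOW_COVERAGE
            fractions = None
        elif clamped_sum <= 0.0:
            qc = QC_DEGENERATE
            fractions = None
        else:
            qc = QC_OK
            fractions = tuple(float(v) for v in clamped / clamped_sum)
        if fractions is None:
            incl_a1 = incl_a2 = None
        else:
            incl_a1 = fractions[1] + fractions[3]
            incl_a2 = fractions[2] + fractions[3]
        return IsoformEstimate(
            group_id=group_id,
            counts=tuple(int(v) for v in c),
            raw_abundance=tuple(float(v) for v in raw),
            clamped_abundance=tuple(float(v) for v in clamped),
            fractions=fractions,
            inclusion_a1=incl_a1,
            inclusion_a2=incl_a2,
            total_junction_reads=total,
            sse=float(sse),
            qc_flag=qc,
            intercept=intercept,
            n_members=n_members,
        )


def estimate_isoforms(
    counts: JunctionCountVector | Sequence[float],
    config: EstimatorConfig | None = None,
) -> IsoformEstimate:
    """Estimate isoform fractions and inclusion statistics for one vector."""
    cfg = config or EstimatorConfig()
    est = IsoformAbundanceEstimator(
        mode=cfg.mode, min_total=cfg.min_total, include_intercept=cfg.include_intercept
    )
    est.fit(np.zeros((1, 6)))
    return est.estimate_one(counts)


def inclusion_fractions(estimate: IsoformEstimate) -> tuple[float | None, float | None]:
    """A1 and A2 inclusion: f(A1)+f(A1A2) and f(A2)+f(A1A2)."""
    return estimate.inclusion_a1, estimate.inclusion_a2


def bootstrap_fractions(
    counts: JunctionCountVector | Sequence[float],
    config: EstimatorConfig | None = None,
    *,
    n_boot: int = 1000,
    seed: int = 0,
) -> BootstrapIntervals:
    """Percentile bootstrap intervals by multinomial read resampling.

    Each replicate redraws the same total number of junction reads from
    the observed junction proportions and re-estimates; the 2.5 and 97.5
    percentiles over replicates with defined fractions are returned.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    cfg = config or EstimatorConfig()
    c = _counts_array(counts)
    total = int(round(c.sum()))
    if total == 0:
        return BootstrapIntervals(None, None, None, n_boot, seed)
    probs = c / c.sum()
    rng = np.random.default_rng(seed)
    frac_reps = []
    for _ in range(n_boot):
        resampled = rng.multinomial(total, probs)
        est = estimate_isoforms(resampled, cfg)
        if est.fractions is not None:
            frac_reps.append(est.fractions)
    if not frac_reps:
        return BootstrapIntervals(None, None, None, n_boot, seed)
    F = np.asarray(frac_reps)
    lo, hi = np.percentile(F, [2.5, 97.5], axis=0)
    incl_a1 = np.percentile(F[:, 1] + F[:, 3], [2.5, 97.5])
    incl_a2 = np.percentile(F[:, 2] + F[:, 3], [2.5, 97.5])
    return BootstrapIntervals(
        fractions={
            label: (float(lo[i]), float(hi[i])) for i, label in enumerate(ISOFORM_ORDER)
        },
        inclusion_a1=(float(incl_a1[0]), float(incl_a1[1])),
        inclusion_a2=(float(incl_a2[0]), float(incl_a2[1])),
        n_boot=n_boot,
        seed=seed,
    )
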