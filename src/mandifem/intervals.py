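"""The intervals method: summarising an FE stress field as the fractions of
structure volume occupied by fixed ranges of (log) von Mises stress, so that
whole simulations can be compared in one multivariate analysis.

Procedure, applied to the 8-simulation biting suite:

1. For each simulation, drop the 2% of elements with the highest von Mises
   stress (they are dominated by singular point-load artefacts).
2. Pool the surviving stresses of all simulations, take natural logs, and set
   a lower threshold at the pooled minimum and an upper threshold at the
   pooled 75th percentile, so the top interval holds the 25% highest values.
3. Split the log-stress axis into N-1 equal-width intervals between the
   thresholds plus one open-ended top interval, and record per simulation the
   fraction of retained mandibular volume falling in each interval.
4. Run a PCA over the simulations x intervals proportion table.
5. Choose N by repeating the analysis over a ladder of interval counts and
   regressing successive PC scores against each other; N is chosen where the
   R-squared of those regressions stops increasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import ElementField

__all__ = [
    "StressSample",
    "IntervalProfile",
    "PcaSummary",
    "ConvergenceTrace",
    "trim_top_stress",
    "build_intervals",
    "interval_volume_proportions",
    "build_profile",
    "pca_profiles",
    "convergence_select",
    "sample_from_field",
]

DEFAULT_TRIM_FRACTION = 0.02
DEFAULT_UPPER_TAIL = 0.25
DEFAULT_CANDIDATES = (5, 10, 15, 25, 50, 75)
DEFAULT_EPSILON = 0.01


@dataclass
class StressSample:
    """Per-element (von Mises stress, volume) pairs of one simulation."""

    label: str
    sigma_vm: np.ndarray
    volume: np.ndarray
    region: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma_vm = np.asarray(self.sigma_vm, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        if self.sigma_vm.shape != self.volume.shape:
            raise ValueError("stress and volume arrays differ in length")
        if np.any(self.sigma_vm < 0):
            raise ValueError("negative von Mises stress")
        if np.any(self.volume <= 0):
            raise ValueError("non-positive element volume")

    @property
    def n(self) -> int:
        return int(self.sigma_vm.size)


def sample_from_field(f: ElementField) -> StressSample:
    return StressSample(f.label, f.sigma_vm, f.volume, region=f.region)


@dataclass
class IntervalProfile:
    """Simulations x intervals table of volume proportions.

    ``edges`` holds the N interior boundaries on the natural-log stress axis:
    [FTL, e_1, ..., FTU]; the top interval is (FTU, inf).  Every row sums
    to 1.
    """

    labels: list[str]
    proportions: np.ndarray
    edges: np.ndarray

    @property
    def n_intervals(self) -> int:
        return int(self.proportions.shape[1])

    @property
    def lower_threshold(self) -> float:
        return float(self.edges[0])

    @property
    def upper_threshold(self) -> float:
        return float(self.edges[-1])


@dataclass
class PcaSummary:
    """Scores, loadings and percent variance of a standardized PCA."""

    scores: np.ndarray
    loadings: np.ndarray
    variance_pct: np.ndarray
    dropped_columns: list[int] = field(default_factory=list)


@dataclass
class ConvergenceTrace:
    """Interval-count ladder with successive-PC regression R-squared values."""

    candidates: tuple[int, ...]
    r2_pc1: list[float]
    r2_pc2: list[float]
    chosen: int

    @property
    def mean_r2(self) -> list[float]:
        return [(a + b) / 2.0 for a, b in zip(self.r2_pc1, self.r2_pc2)]


# ---------------------------------------------------------------------------


def trim_top_stress(
    sample: StressSample, fraction: float = DEFAULT_TRIM_FRACTION
) -> StressSample:
    """Remove the ceil(fraction * n) highest-stress elements of one simulation.

    Ties at the cutoff are broken by element order (stable sort), so exactly
    ceil(fraction * n) elements are removed.
    """
    if not 0 <= fraction < 1:
        raise ValueError("trim fraction must be in [0, 1)")
    if sample.n == 0:
        raise ValueError("cannot trim an empty sample")
    k = int(np.ceil(fraction * sample.n))
    if k == 0:
        return sample
    order = np.argsort(-sample.sigma_vm, kind="stable")
    keep = np.sort(order[k:])
    return StressSample(
        sample.label,
        sample.sigma_vm[keep],
        sample.volume[keep],
        region=None if sample.region is None else sample.region[keep],
    )


def _log_values(sample: StressSample) -> np.ndarray:
    """Natural-log stresses; exact zeros are floored before logging.

    Zero von Mises values can occur in synthetic fields (e.g. unloaded
    corners); they are replaced by 1e-3 times the smallest positive stress so
    they land in the lowest interval instead of breaking the transform.
    """
    vm = sample.sigma_vm
    if np.all(vm == 0):
        raise ValueError(f"sample '{sample.label}' is identically zero")
    floor = vm[vm > 0].min() * 1e-3
    return np.log(np.where(vm > 0, vm, floor))


def build_intervals(
    samples: list[StressSample],
    n_intervals: int,
    upper_tail: float = DEFAULT_UPPER_TAIL,
    pooled: bool = True,
) -> np.ndarray:
    """Interval edges on the natural-log stress axis shared by all samples.

    The lower threshold is the pooled minimum, the upper threshold the pooled
    (element-count-weighted) quantile leaving ``upper_tail`` of the values
    above it.  ``n_intervals - 1`` equal-width intervals partition the
    thresholds; the top interval is open above.  With ``pooled=False`` each
    call site may instead pass a single sample to obtain per-simulation
    ranges (a variant kept for sensitivity checks).
    """
    if n_intervals < 2:
        raise ValueError("need at least 2 intervals")
    logs = np.concatenate([_log_values(s) for s in samples])
    ftl = float(logs.min())
    ftu = float(np.quantile(logs, 1.0 - upper_tail))
    if not ftu > ftl:
        raise ValueError("degenerate pooled stress range (constant values)")
    return np.linspace(ftl, ftu, n_intervals)


def interval_volume_proportions(sample: StressSample, edges: np.ndarray) -> np.ndarray:
    """One profile row: fraction of retained volume per stress interval.

    Intervals are left-closed, right-open on the log axis; values at or above
    the upper threshold go to the open top interval, values below the lower
    threshold (possible with per-simulation ranges) to the first.
    """
    edges = np.asarray(edges, dtype=float)
    n_intervals = edges.size
    logs = _log_values(sample)
    idx = np.searchsorted(edges, logs, side="right") - 1
    # a value exactly at the upper threshold closes the last body interval
    idx[logs == edges[-1]] = n_intervals - 2
    idx = np.clip(idx, 0, n_intervals - 1)
    row = np.bincount(idx, weights=sample.volume, minlength=n_intervals)
    return row / sample.volume.sum()


def build_profile(
    samples: list[StressSample],
    n_intervals: int,
    upper_tail: float = DEFAULT_UPPER_TAIL,
) -> IntervalProfile:
    """Trimmed samples -> pooled edges -> full simulations x intervals table."""
    edges = build_intervals(samples, n_intervals, upper_tail=upper_tail)
    rows = np.vstack([interval_volume_proportions(s, edges) for s in samples])
    return IntervalProfile([s.label for s in samples], rows, edges)


# ---------------------------------------------------------------------------
# PCA


def pca_profiles(profile: IntervalProfile | np.ndarray, scale: bool = True) -> PcaSummary:
    """Standardized PCA of the proportions table via singular value
    decomposition.

    Columns with zero variance are dropped (and recorded); the rest are
    centered and, by default, scaled to unit variance so that every interval
    contributes equally regardless of its share of volume.  Percent variance
    sums to 100 over all returned components.
    """
    X = profile.proportions if isinstance(profile, IntervalProfile) else np.asarray(profile, float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 1e-14)
    dropped = [int(i) for i in np.flatnonzero(sd <= 1e-14)]
    if keep.size < 2:
        raise ValueError("fewer than 2 non-constant columns")
    Xc = X[:, keep] - mean[keep]
    if scale:
        Xc = Xc / sd[keep]
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U * S
    var = S**2
    variance_pct = 100.0 * var / var.sum()
    return PcaSummary(scores, Vt.T, variance_pct, dropped)


# ---------------------------------------------------------------------------
# interval-count convergence


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """OLS coefficient of determination of y ~ x (= squared correlation)."""
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 1.0  # both scores degenerate: nothing left to converge
    return float(((x * y).sum() / denom) ** 2)


def convergence_select(
    samples: list[StressSample],
    candidates: tuple[int, ...] = DEFAULT_CANDIDATES,
    epsilon: float = DEFAULT_EPSILON,
    upper_tail: float = DEFAULT_UPPER_TAIL,
    scale: bool = True,
) -> ConvergenceTrace:
    """Choose the interval count where successive PC scores stop changing.

    For each consecutive candidate pair the PC1 and PC2 scores of the two
    profiles are regressed against each other (R-squared is invariant to the
    sign indeterminacy of PCA axes).  The chosen N is the left member of the
    first pair whose mean R-squared fails to exceed the previous pair's mean
    by more than ``epsilon`` — the point where R-squared stops increasing —
    or the last candidate if R-squared keeps rising throughout.
    """
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate interval counts")
    if any(b <= a for a, b in zip(candidates, candidates[1:])):
        raise ValueError("candidates must be strictly ascending")
    pcas = []
    for n in candidates:
        try:
            pcas.append(pca_profiles(build_profile(samples, n, upper_tail), scale=scale))
        except ValueError as exc:
            raise ValueError(f"degenerate PCA at {n} intervals: {exc}") from exc
    r2_pc1, r2_pc2 = [], []
    for a, b in zip(pcas, pcas[1:]):
        r2_pc1.append(_r2(a.scores[:, 0], b.scores[:, 0]))
        r2_pc2.append(_r2(a.scores[:, 1], b.scores[:, 1]))
    mean_r2 = [(p1 + p2) / 2 for p1, p2 in zip(r2_pc1, r2_pc2)]
    chosen = choose_interval_count(candidates, mean_r2, epsilon)
    return ConvergenceTrace(tuple(candidates), r2_pc1, r2_pc2, int(chosen))


def choose_interval_count(
    candidates: tuple[int, ...], mean_r2: list[float], epsilon: float = DEFAULT_EPSILON
) -> int:
    """Apply the stop-of-increase rule to a sequence of pairwise mean R^2.

    ``mean_r2[k]`` belongs to the candidate pair (candidates[k],
    candidates[k+1]).  The chosen count is the left member of the first pair
    whose mean R^2 fails to exceed the previous pair's by more than
    ``epsilon``; if R^2 keeps increasing to the end, the last candidate.
    """
    if len(mean_r2) != len(candidates) - 1:
        raise ValueError("need one mean R^2 per consecutive candidate pair")
    for k in range(1, len(mean_r2)):
        if mean_r2[k] <= mean_r2[k - 1] + epsilon:
            return int(candidates[k])
    return int(candidates[-1])
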