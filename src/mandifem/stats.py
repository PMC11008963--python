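"""Nonparametric statistics for cuticle site data and FE stress samples:
tie-aware Spearman correlation matrices, Kruskal-Wallis with Dunn-Bonferroni
post-hoc pairs, and Mann-Whitney tests in the first-sample rank-sum (U1 / W)
convention.

The W convention matters: treatment contrasts on element-scale stress samples
produce W values of order n1*n2 (~1e10 for full-size meshes), which is the
scale of a U-type statistic, not of a z or H statistic.  ``mann_whitney_W``
therefore returns U1 = (rank sum of the first sample) - n1(n1+1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SiteRecord",
    "TestResult",
    "site_frame",
    "spearman_matrix",
    "kruskal_wallis",
    "dunn_bonferroni",
    "mann_whitney_W",
    "DegenerateDataError",
]

REGION_ORDER = ("MM", "BLADE", "DMA", "VMA")

#: Chemical elements carried by site records (P and Pt share one column
#: because their EDS peaks overlap and cannot be separated).
ELEMENT_COLUMNS = (
    "Zn", "Cu", "P+Pt", "Ca", "Cl", "F", "Fe", "K", "Mg", "Mn", "Na", "S", "Si",
)


class DegenerateDataError(ValueError):
    """All observations identical: rank statistics are undefined."""


@dataclass
class SiteRecord:
    """One co-located EDS + nanoindentation measurement site."""

    specimen_id: str
    mandible_side: str
    region: str
    site_id: int
    H: float
    E: float
    atomic_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mandible_side not in ("left", "right"):
            raise ValueError(f"mandible_side must be left/right, got {self.mandible_side}")
        if self.region not in REGION_ORDER:
            raise ValueError(f"unknown region '{self.region}'")
        if self.H <= 0 or self.E <= 0:
            raise ValueError("H and E must be positive")
        total = sum(v for v in self.atomic_pct.values() if np.isfinite(v))
        if any(v < 0 for v in self.atomic_pct.values() if np.isfinite(v)) or total > 100:
            raise ValueError("atomic percentages must be >= 0 and sum to <= 100")


def site_frame(records: list[SiteRecord]) -> pd.DataFrame:
    """Tidy DataFrame of site records (one row per site).

    Missing atomic-% entries (peaks below background noise) become NaN and
    are handled pairwise-complete by the correlation matrix.
    """
    rows = []
    for r in records:
        row = {
            "specimen_id": r.specimen_id,
            "mandible_side": r.mandible_side,
            "region": r.region,
            "site_id": r.site_id,
            "H_GPa": r.H,
            "E_GPa": r.E,
        }
        for el in ELEMENT_COLUMNS:
            row[el] = r.atomic_pct.get(el, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class TestResult:
    """Outcome of one hypothesis test (optionally one post-hoc pair)."""

    name: str
    statistic: float
    p: float
    df: int | None = None
    pair: tuple[str, str] | None = None
    p_adjusted: float | None = None


# ---------------------------------------------------------------------------
# Spearman


def spearman_matrix(data: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    """Pairwise-complete Spearman rank correlation matrix.

    Ties receive average ranks.  Pairs with fewer than 3 complete
    observations, or with a constant column, are reported as NaN (undefined),
    never coerced to 0.
    """
    if columns is None:
        columns = [c for c in data.columns if pd.api.types.is_numeric_dtype(data[c])]
    k = len(columns)
    out = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    for i in range(k):
        for j in range(i + 1, k):
            x = data[columns[i]].to_numpy(dtype=float)
            y = data[columns[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.unique(x[ok]).size < 2 or np.unique(y[ok]).size < 2:
                rho = np.nan
            else:
                rho = sps.spearmanr(x[ok], y[ok]).statistic
            out.iloc[i, j] = out.iloc[j, i] = rho
    return out


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def kruskal_wallis(groups: dict[str, np.ndarray]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-squared p (df = k - 1)."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        raise DegenerateDataError("all observations identical")
    H, p = sps.kruskal(*arrays)
    return TestResult("kruskal_wallis", float(H), float(p), df=len(groups) - 1)


# ---------------------------------------------------------------------------
# Dunn post-hoc with Bonferroni


def dunn_bonferroni(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """All pairwise Dunn z tests on pooled ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))
    with tie term T = sum(t^3 - t) over tie groups; two-sided normal p;
    adjusted p = min(1, m p) with m = k(k-1)/2 pairs.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    sizes = np.array([a.size for a in arrays])
    if np.any(sizes == 0):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    N = pooled.size
    if np.unique(pooled).size == 1:
        raise DegenerateDataError("all observations identical")
    ranks = sps.rankdata(pooled)
    bounds = np.cumsum(sizes)
    mean_ranks = {}
    for g, a, b in zip(names, np.r_[0, bounds[:-1]], bounds):
        mean_ranks[g] = ranks[a:b].mean()
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var_base = N * (N + 1) / 12.0 - tie_term / (12.0 * (N - 1))
    m = len(names) * (len(names) - 1) // 2
    results = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[names[i]] - mean_ranks[names[j]]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            results.append(
                TestResult(
                    "dunn",
                    float(z),
                    float(min(1.0, p)),
                    pair=(names[i], names[j]),
                    p_adjusted=float(min(1.0, m * p)),
                )
            )
    return results


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney_W(
    x: np.ndarray, y: np.ndarray, exact_limit: int = 10_000
) -> TestResult:
    """Mann-Whitney test returning the first-sample U statistic as W.

    W = (pooled rank sum of x) - n1(n1+1)/2, i.e. the number of pairs
    (x_i, y_j) with x_i > y_j plus half the tied pairs.  The p-value is
    two-sided: exact enumeration when n1*n2 <= ``exact_limit`` and the data
    are tie-free, otherwise the tie- and continuity-corrected normal
    approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = x.size * y.size <= exact_limit
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult("mann_whitney_W", float(res.statistic), float(res.pvalue))
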