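"""Cross-dating statistics and common-spline detrending.

Cross-dating quality is summarized by each tree's interseries correlation
(its series against the mean of all the others) and the expressed
population signal

    EPS = n * rbar / (n * rbar + (1 - rbar)),

which measures how well a finite sample of n chronologies with mean
interseries correlation rbar represents the hypothetical population
chronology. In natural stands 0.85 is the customary adequacy threshold;
common-garden material typically scores much higher.

Detrending removes the age-related decline in ring width. Because all
trees in a common garden share one germination year, a *single* spline
shared by every tree is fitted to the pooled standardized data — fitting
individual splines would partly absorb genuine population differences.
The standardization is then reversed with each tree's own mean and SD so
detrended values stay in millimetres and between-tree level differences
are retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .ringio import TreeChronology
from .spline import SmoothingSpline, fit_smoothing_spline

logger = logging.getLogger(__name__)

CommonSpline = SmoothingSpline


def eps(n: int | float, rbar: float) -> float:
    """Expressed population signal for n series with mean correlation rbar.

    The formula lives on rbar in (0, 1]; a non-positive mean interseries
    correlation means there is no common signal to express, so EPS is 0.
    """
    if rbar <= 0.0:
        return 0.0
    return n * rbar / (n * rbar + (1.0 - rbar))


@dataclass
class CrossdatingReport:
    """Interseries correlations and EPS for a set of tree chronologies."""

    r_by_tree: dict[str, float]
    n_series: int
    rbar: float
    eps: float

    def summary(self) -> dict:
        return {"n_series": self.n_series, "rbar": self.rbar, "eps": self.eps}


def interseries_correlations(
    chronos: list[TreeChronology],
    min_overlap: int = 5,
    use_detrended: bool = False,
) -> CrossdatingReport:
    """Leave-one-out interseries correlations and EPS.

    Each tree's series is correlated (Pearson) with the arithmetic mean
    series of all *other* trees over their overlapping years. Trees whose
    overlap has zero variance are excluded with a warning.
    """
    if len(chronos) < 3:
        raise ValueError(f"need >= 3 series for cross-dating, got {len(chronos)}")
    field = "detrended_mm" if use_detrended else "width_mm"
    all_years = np.unique(np.concatenate([c.years for c in chronos]))
    n_trees = len(chronos)
    # stack into a (trees, years) matrix with NaN where absent
    mat = np.full((n_trees, len(all_years)), np.nan)
    for i, c in enumerate(chronos):
        vals = getattr(c, field)
        if vals is None:
            raise ValueError(f"tree {c.tree_id}: no detrended values")
        mat[i, np.searchsorted(all_years, c.years)] = vals

    counts = np.sum(~np.isnan(mat), axis=0)
    sums = np.nansum(mat, axis=0)
    r_by_tree: dict[str, float] = {}
    for i, c in enumerate(chronos):
        have = ~np.isnan(mat[i])
        others_n = counts - have.astype(int)
        ok = have & (others_n > 0)
        if np.sum(ok) < min_overlap:
            raise ValueError(
                f"tree {c.tree_id}: fewer than {min_overlap} overlapping years"
            )
        own = mat[i, ok]
        others_mean = (sums[ok] - own) / others_n[ok]
        if np.std(own) == 0 or np.std(others_mean) == 0:
            logger.warning(
                "tree %s: zero-variance overlap, excluded from EPS", c.tree_id
            )
            continue
        r_by_tree[c.tree_id] = float(np.corrcoef(own, others_mean)[0, 1])
    if len(r_by_tree) < 3:
        raise ValueError("fewer than 3 usable series after exclusions")
    n = len(r_by_tree)
    rbar = float(np.mean(list(r_by_tree.values())))
    return CrossdatingReport(
        r_by_tree=r_by_tree, n_series=n, rbar=rbar, eps=eps(n, rbar)
    )


def normalize(chrono: TreeChronology) -> np.ndarray:
    """Per-year z-scores using the tree's stored window mean and sample SD."""
    if chrono.raw_sd <= 0:
        raise ValueError(f"tree {chrono.tree_id}: raw_sd must be > 0")
    return (chrono.width_mm - chrono.raw_mean) / chrono.raw_sd


def fit_common_spline(
    chronos: list[TreeChronology], stiffness: float = 0.7
) -> CommonSpline:
    """Fit one cubic smoothing spline to the pooled normalized chronologies.

    Every (tree, year) point enters with equal weight, so years with more
    surviving trees carry proportionally more weight. The pooled fit is by
    construction invariant to the order of trees.
    """
    xs, zs = [], []
    for c in chronos:
        z = normalize(c)
        xs.append(c.years.astype(float))
        zs.append(z)
    x = np.concatenate(xs)
    z = np.concatenate(zs)
    return fit_smoothing_spline(x, z, stiffness=stiffness)


def detrend_reverse(chrono: TreeChronology, spline: CommonSpline) -> TreeChronology:
    """Subtract the common spline in z-space, then reverse standardization.

        detrended(t) = (z(t) - f(t)) * raw_sd + raw_mean

    Output stays in mm; a tree's level (raw_mean) is preserved whenever the
    spline has zero mean over the window, so absolute growth differences
    between provenances survive detrending.
    """
    z = normalize(chrono)
    f = spline(chrono.years.astype(float))
    detrended = (z - f) * chrono.raw_sd + chrono.raw_mean
    return replace(chrono, detrended_mm=detrended)


def detrend_chronologies(
    chronos: list[TreeChronology], stiffness: float = 0.7
) -> tuple[list[TreeChronology], CommonSpline]:
    """Pooled common-spline fit followed by reversed standardization for all."""
    spline = fit_common_spline(chronos, stiffness=stiffness)
    return [detrend_reverse(c, spline) for c in chronos], spline
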