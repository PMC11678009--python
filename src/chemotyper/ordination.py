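"""PCA of preprocessed metabolite profiles with per-group confidence ellipses.

PCA is computed by singular value decomposition of the column-centred
matrix; no missing values are accepted (imputation precedes ordination).
Component signs are fixed deterministically so that the largest-magnitude
loading of each component is positive — score-plot orientation is
otherwise arbitrary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MetaboliteTable, TableState, ValidationError

__all__ = ["PcaResult", "GroupEllipse", "fit_pca", "group_ellipse"]


@dataclass
class PcaResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # metabolites x components
    variance_fraction: np.ndarray  # per retained component, in [0, 1]

    def variance_pct(self, component: int) -> float:
        """Variance explained by a component (1-based), in percent."""
        return float(self.variance_fraction[component - 1] * 100.0)


@dataclass
class GroupEllipse:
    group: object
    center: np.ndarray        # 2-vector
    semi_axes: np.ndarray     # 2 positive reals, major first
    angle: float              # radians, orientation of the major axis
    level: float = 0.95


def fit_pca(table: MetaboliteTable, n_components: int) -> PcaResult:
    """SVD-based PCA of a complete (imputed) table.

    variance_fraction_i = sigma_i^2 / sum(sigma^2) over all singular
    values, so retained fractions sum to <= 1 and full-rank
    reconstruction is exact.
    """
    table.require_state(TableState.IMPUTED, TableState.LOG_SCALED)
    table.require_complete()
    X = table.values.to_numpy()
    n, m = X.shape
    max_rank = min(n - 1, m)
    if not 1 <= n_components <= max_rank:
        raise ValidationError(
            f"n_components must lie in [1, {max_rank}] for a {n}x{m} table"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| element of each component positive
    for c in range(len(s)):
        idx = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, idx] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    total = float(np.sum(s**2))
    frac = (s**2 / total)[:n_components]
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    scores = pd.DataFrame(
        (U[:, :n_components] * s[:n_components]),
        index=table.values.index,
        columns=comp_names,
    )
    loadings = pd.DataFrame(
        Vt[:n_components].T, index=table.values.columns, columns=comp_names
    )
    return PcaResult(scores, loadings, frac)


def group_ellipse(
    scores: pd.DataFrame,
    labels: pd.Series,
    level: float = 0.95,
) -> list[GroupEllipse]:
    """Confidence (data) ellipses of 2-D score clouds, one per group.

    The ellipse is the set of points at squared Mahalanobis distance
    equal to the chi-square quantile at `level` with 2 degrees of
    freedom, computed from each group's 2x2 sample covariance.  Groups
    with fewer than 3 samples are skipped with a warning.
    """
    if not 0 < level < 1:
        raise ValidationError(f"level must lie in (0, 1), got {level}")
    if scores.shape[1] != 2:
        raise ValidationError("group_ellipse expects a 2-column score matrix")
    radius2 = stats.chi2.ppf(level, df=2)
    out: list[GroupEllipse] = []
    for group, idx in labels.groupby(labels).groups.items():
        pts = scores.loc[idx].to_numpy()
        if pts.shape[0] < 3:
            warnings.warn(f"group {group!r} has < 3 samples; ellipse skipped",
                          stacklevel=2)
            continue
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        eigval, eigvec = np.linalg.eigh(cov)  # ascending
        eigval = np.clip(eigval, 0.0, None)
        semi = np.sqrt(eigval[::-1] * radius2)  # major first
        major = eigvec[:, 1]
        angle = float(np.arctan2(major[1], major[0])) % np.pi
        out.append(GroupEllipse(group, center, semi, angle, level))
    return out
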