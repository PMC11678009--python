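"""Preprocessing chain for GC-MS abundance tables.

The chain mirrors the conventional untargeted-metabolomics recipe:

1. **Sample-median normalization** — each sample's abundances are divided
   by that sample's median over non-missing metabolites, removing
   per-sample injection/extraction scale.
2. **Dixon outlier exclusion** — within each replicate group
   (genotype x condition x time) the single most extreme value of each
   metabolite is tested with Dixon's two-sided Q test (gap/range) against
   tabulated critical values; a flagged value becomes missing.
3. **Log transform + autoscaling** — natural log, then each metabolite
   column is centred and scaled to unit sample standard deviation.
4. **Group-aware KNN imputation** — a missing cell is imputed from the k
   most similar metabolite rows only when the metabolite was observed in
   at least one other replicate of the same group (the "technical error"
   rule); metabolites absent from a whole group stay missing.

Every removal and imputation is logged in a :class:`PreprocessReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    MetaboliteTable,
    SampleMetadata,
    TableState,
    ValidationError,
)

__all__ = [
    "PreprocessReport",
    "PreprocessConfig",
    "median_normalize",
    "dixon_filter",
    "log_autoscale",
    "knn_impute",
    "preprocess_pipeline",
    "dixon_critical_value",
    "DIXON_CRITICAL",
]

# Two-sided critical values for Dixon's r10 ("Q") ratio, Rorabacher (1991),
# for group sizes n = 3..30 at overall significance 0.10, 0.05 and 0.01.
DIXON_CRITICAL: dict[float, dict[int, float]] = {
    0.10: {
        3: 0.941, 4: 0.765, 5: 0.642, 6: 0.560, 7: 0.507, 8: 0.468,
        9: 0.437, 10: 0.412, 11: 0.392, 12: 0.376, 13: 0.361, 14: 0.349,
        15: 0.338, 16: 0.329, 17: 0.320, 18: 0.313, 19: 0.306, 20: 0.300,
        21: 0.295, 22: 0.290, 23: 0.285, 24: 0.281, 25: 0.277, 26: 0.273,
        27: 0.269, 28: 0.266, 29: 0.263, 30: 0.260,
    },
    0.05: {
        3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568, 8: 0.526,
        9: 0.493, 10: 0.466, 11: 0.444, 12: 0.426, 13: 0.410, 14: 0.396,
        15: 0.384, 16: 0.374, 17: 0.365, 18: 0.356, 19: 0.349, 20: 0.342,
        21: 0.337, 22: 0.331, 23: 0.326, 24: 0.321, 25: 0.317, 26: 0.312,
        27: 0.308, 28: 0.305, 29: 0.301, 30: 0.298,
    },
    0.01: {
        3: 0.994, 4: 0.926, 5: 0.821, 6: 0.740, 7: 0.680, 8: 0.634,
        9: 0.598, 10: 0.568, 11: 0.542, 12: 0.522, 13: 0.503, 14: 0.488,
        15: 0.475, 16: 0.463, 17: 0.452, 18: 0.442, 19: 0.433, 20: 0.425,
        21: 0.418, 22: 0.411, 23: 0.404, 24: 0.399, 25: 0.393, 26: 0.388,
        27: 0.384, 28: 0.380, 29: 0.376, 30: 0.372,
    },
}


def dixon_critical_value(n: int, alpha: float = 0.05) -> float:
    """Tabulated two-sided critical value for Dixon's r10 ratio."""
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    if alpha not in DIXON_CRITICAL:
        raise ValidationError(
            f"no critical table for alpha={alpha}; available: "
            f"{sorted(DIXON_CRITICAL)}"
        )
    table = DIXON_CRITICAL[alpha]
    if n not in table:
        raise ValidationError(f"Dixon test tabulated for 3 <= n <= 30, got n={n}")
    return table[n]


@dataclass
class PreprocessReport:
    """Log of all destructive preprocessing decisions."""

    # (metabolite_id, sample_id, observed value, Q statistic, critical value)
    outliers_removed: list[tuple] = field(default_factory=list)
    # (metabolite_id, sample_id, imputed value)
    imputed_cells: list[tuple] = field(default_factory=list)
    # (metabolite_id, group tuple) cells left missing (absent from whole group)
    left_missing: list[tuple] = field(default_factory=list)
    normalization_factors: dict[str, float] = field(default_factory=dict)

    def merge(self, other: "PreprocessReport") -> None:
        self.outliers_removed.extend(other.outliers_removed)
        self.imputed_cells.extend(other.imputed_cells)
        self.left_missing.extend(other.left_missing)
        self.normalization_factors.update(other.normalization_factors)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m, s, v, q, crit in self.outliers_removed:
            rows.append(
                {"action": "outlier_removed", "metabolite_id": m, "sample_id": s,
                 "value": v, "q_statistic": q, "critical_value": crit}
            )
        for m, s, v in self.imputed_cells:
            rows.append(
                {"action": "imputed", "metabolite_id": m, "sample_id": s,
                 "value": v, "q_statistic": np.nan, "critical_value": np.nan}
            )
        for m, g in self.left_missing:
            rows.append(
                {"action": "left_missing", "metabolite_id": m, "sample_id": str(g),
                 "value": np.nan, "q_statistic": np.nan, "critical_value": np.nan}
            )
        cols = ["action", "metabolite_id", "sample_id", "value",
                "q_statistic", "critical_value"]
        return pd.DataFrame(rows, columns=cols)


def median_normalize(table: MetaboliteTable) -> tuple[MetaboliteTable, dict[str, float]]:
    """Divide each sample by its median over non-missing metabolites.

    Idempotent: on an already-normalized table every sample median is 1.
    """
    table.require_state(TableState.RAW, TableState.NORMALIZED)
    values = table.values.copy()
    factors: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows handled below
        medians = values.median(axis=1, skipna=True)
    for sid, med in medians.items():
        if np.isnan(med):
            raise ValidationError(f"sample {sid!r} has no observed values")
        if med == 0:
            raise ValidationError(f"sample {sid!r} has median 0; cannot normalize")
        factors[str(sid)] = float(med)
    normalized = values.div(medians, axis=0)
    return MetaboliteTable(normalized, TableState.NORMALIZED), factors


def _dixon_q(values: np.ndarray) -> tuple[float, int]:
    """Two-sided r10 statistic and index of the tested (most extreme) value.

    Q = gap/range for whichever end of the sorted sample has the larger
    gap to its neighbour.  Ties go to the upper end (deterministic).
    """
    order = np.argsort(values, kind="stable")
    x = values[order]
    rng = x[-1] - x[0]
    low_gap = x[1] - x[0]
    high_gap = x[-1] - x[-2]
    if high_gap >= low_gap:
        return float(high_gap / rng), int(order[-1])
    return float(low_gap / rng), int(order[0])


def dixon_filter(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    alpha: float = 0.05,
) -> tuple[MetaboliteTable, PreprocessReport]:
    """Remove (mark missing) single-value outliers within replicate groups.

    For each metabolite x (genotype, condition, time) group with 3-30
    observed values, the most extreme value is flagged when its Q = gap /
    range exceeds the two-sided critical value; at most one value per
    metabolite per group is removed.  Groups with fewer than 3 observed
    values are skipped with a warning; constant groups (range 0) are
    never tested.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must lie in (0, 1), got {alpha}")
    dixon_critical_value(3, alpha)  # validate table availability up front
    metadata.validate_against(table)

    values = table.values.copy()
    report = PreprocessReport()
    arr = values.to_numpy()
    sample_ids = np.array(table.sample_ids)
    groups = metadata.group_key().loc[table.sample_ids]
    warned_small = False
    for _, idx in groups.groupby(groups).groups.items():
        rows = np.array([table.sample_ids.index(s) for s in idx])
        for j, mid in enumerate(table.metabolite_ids):
            col = arr[rows, j]
            mask = ~np.isnan(col)
            n = int(mask.sum())
            if n < 3:
                if n > 0 and not warned_small:
                    warnings.warn(
                        "replicate groups with fewer than 3 observed values "
                        "are not tested for outliers",
                        stacklevel=2,
                    )
                    warned_small = True
                continue
            if n > 30:
                warnings.warn(
                    f"group size {n} exceeds the tabulated range; skipped",
                    stacklevel=2,
                )
                continue
            obs = col[mask]
            if np.ptp(obs) == 0:
                continue
            q, local_idx = _dixon_q(obs)
            crit = dixon_critical_value(n, alpha)
            if q > crit:
                row_global = rows[mask][local_idx]
                sid = str(sample_ids[row_global])
                report.outliers_removed.append(
                    (mid, sid, float(arr[row_global, j]), q, crit)
                )
                arr[row_global, j] = np.nan
    out = MetaboliteTable(pd.DataFrame(arr, index=values.index, columns=values.columns),
                          table.state)
    return out, report


def log_autoscale(table: MetaboliteTable) -> MetaboliteTable:
    """Natural log, then centre/scale each metabolite column to sd 1 (n-1).

    Constant columns are scaled to all zeros rather than dropped so that
    metabolite indices stay aligned across strata.
    """
    table.require_state(TableState.RAW, TableState.NORMALIZED)
    arr = table.values.to_numpy().copy()
    bad = np.argwhere(arr <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-positive value at sample {table.sample_ids[i]!r}, metabolite "
            f"{table.metabolite_ids[j]!r}: normalization must precede the log "
            "transform and all abundances must be positive"
        )
    logged = np.log(arr)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(logged, axis=0)
        sd = np.nanstd(logged, axis=0, ddof=1)
    centred = logged - mean
    scaled = np.where(sd > 0, centred / np.where(sd > 0, sd, 1.0), 0.0)
    scaled[np.isnan(logged)] = np.nan
    out = pd.DataFrame(scaled, index=table.values.index, columns=table.values.columns)
    return MetaboliteTable(out, TableState.LOG_SCALED)


def knn_impute(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    k: int = 10,
) -> tuple[MetaboliteTable, PreprocessReport]:
    """Impute missing cells from the k most similar metabolite rows.

    A missing cell (metabolite i, sample j) is imputed only when
    metabolite i is observed in at least one other replicate of sample
    j's group.  Similarity between metabolite rows is the Euclidean
    distance over mutually non-missing samples, normalised by overlap so
    rows with different overlaps are comparable; the imputed value is the
    unweighted mean of the k nearest donors' entries at sample j.
    """
    table.require_state(TableState.LOG_SCALED, TableState.NORMALIZED)
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    metadata.validate_against(table)

    arr = table.values.to_numpy().copy()
    n_samples, n_metab = arr.shape
    report = PreprocessReport()
    groups = metadata.group_key().loc[table.sample_ids]
    group_rows: dict[tuple, np.ndarray] = {
        g: np.array([table.sample_ids.index(s) for s in idx])
        for g, idx in groups.groupby(groups).groups.items()
    }

    original = arr.copy()  # distances use pre-imputation values only
    missing_cols = np.where(np.isnan(original).any(axis=0))[0]
    warned_k = False
    for j in missing_cols:
        col = original[:, j]
        col_dists = _metabolite_distances(original, j)
        for g, rows in group_rows.items():
            miss_rows = rows[np.isnan(col[rows])]
            if miss_rows.size == 0:
                continue
            if np.isnan(col[rows]).all():
                report.left_missing.append((table.metabolite_ids[j], g))
                continue
            for i in miss_rows:
                observed_here = ~np.isnan(original[i, :])
                candidates = np.where(observed_here & ~np.isnan(col_dists))[0]
                candidates = candidates[candidates != j]
                if candidates.size == 0:
                    report.left_missing.append((table.metabolite_ids[j], g))
                    continue
                kk = min(k, candidates.size)
                if candidates.size < k and not warned_k:
                    warnings.warn(
                        "fewer complete donor rows than k; using all available",
                        stacklevel=2,
                    )
                    warned_k = True
                order = np.argsort(col_dists[candidates], kind="stable")[:kk]
                nearest = candidates[order]
                value = float(np.mean(original[i, nearest]))
                arr[i, j] = value
                report.imputed_cells.append(
                    (table.metabolite_ids[j], table.sample_ids[i], value)
                )
    out_state = (
        TableState.IMPUTED
        if table.state is TableState.LOG_SCALED
        else TableState.NORMALIZED
    )
    out = MetaboliteTable(
        pd.DataFrame(arr, index=table.values.index, columns=table.values.columns),
        out_state,
    )
    return out, report


def _metabolite_distances(arr: np.ndarray, target_col: int) -> np.ndarray:
    """Distances from metabolite `target_col` to every other metabolite row.

    Root-mean-square difference over mutually non-missing samples
    (overlap-normalised Euclidean distance, so rows with different
    overlaps are comparable).  NaN where no samples overlap.
    """
    target = arr[:, target_col]
    diff2 = (arr - target[:, None]) ** 2  # NaN wherever either is missing
    overlap = (~np.isnan(diff2)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        msd = np.nansum(diff2, axis=0) / np.where(overlap > 0, overlap, 1)
    dists = np.sqrt(msd)
    dists[overlap == 0] = np.nan
    return dists


@dataclass
class PreprocessConfig:
    """Tunable knobs of the preprocessing chain."""

    dixon_alpha: float = 0.05
    knn_k: int = 10
    #: impute before the log/autoscale step instead of after (sensitivity mode)
    impute_before_scale: bool = False


def preprocess_pipeline(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    config: PreprocessConfig | None = None,
) -> tuple[MetaboliteTable, PreprocessReport]:
    """Run median normalization -> Dixon filter -> log/autoscale -> KNN impute."""
    config = config or PreprocessConfig()
    table.require_state(TableState.RAW)
    report = PreprocessReport()

    table, factors = median_normalize(table)
    report.normalization_factors = factors

    table, dixon_report = dixon_filter(table, metadata, alpha=config.dixon_alpha)
    report.merge(dixon_report)

    if config.impute_before_scale:
        # sensitivity mode: impute on the normalized scale, then transform
        table, knn_report = knn_impute(table, metadata, k=config.knn_k)
        report.merge(knn_report)
        table = log_autoscale(table)
        return MetaboliteTable(table.values, TableState.IMPUTED), report

    table = log_autoscale(table)
    table, knn_report = knn_impute(table, metadata, k=config.knn_k)
    report.merge(knn_report)
    return table, report
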