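"""Two-class orthogonal projections to latent structures discriminant
analysis (OPLS-DA), implemented from first principles.

The model splits predictor variance into one class-predictive component
and (by default) one class-orthogonal component:

* initial predictive weight ``w ∝ Xᵀy`` (unit norm);
* for each orthogonal component, ``w_o ∝ p − (wᵀp)w`` is the part of the
  X-loading not aligned with the predictive direction; ``t_o = X w_o``,
  ``p_o = Xᵀt_o / t_oᵀt_o`` and X is deflated by ``t_o p_oᵀ``;
* the predictive component is then recomputed on the deflated matrix.

Diagnostics follow the standard chemometrics conventions: R²X of the
predictive component (fraction of the original centred X variance
captured by ``t pᵀ``), R²Y (class variance explained in-sample), Q²Y
(cross-validated predictive ability, 1 − PRESS/SS) and a label
permutation p-value for Q²Y.  Variable importance in projection (VIP)
for the single predictive component is ``√M · |w_j|`` (with ‖w‖ = 1), so
the VIP² values average to exactly 1.

Differentially accumulating metabolites (DAMs) are selected from the
predictive loadings and VIP; thresholds are always recorded with the
resulting table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import (
    MetaboliteTable,
    SampleMetadata,
    TableState,
    ValidationError,
)

__all__ = [
    "OplsdaModel",
    "DamTable",
    "fit_oplsda",
    "q2_cv",
    "permutation_test",
    "vip",
    "select_dams",
    "compare_loadings",
    "multi_component_vip",
]

_DEGENERATE_TOL = 1e-12


@dataclass
class OrthogonalComponent:
    weights: np.ndarray   # w_o, unit norm
    scores: np.ndarray    # t_o
    loadings: np.ndarray  # p_o
    r2x: float


@dataclass
class OplsdaModel:
    """Fitted two-class OPLS model (one predictive + n orthogonal components)."""

    metabolite_ids: list[str]
    sample_ids: list[str]
    class_encoding: dict[str, int]           # label -> +1 / -1
    weights: np.ndarray                      # w, unit norm
    scores: np.ndarray                       # t
    loadings: np.ndarray                     # p
    y_loading: float                         # c
    orthogonal: list[OrthogonalComponent]
    r2x_predictive: float
    r2x_orthogonal: list[float]
    r2y: float
    x_mean: np.ndarray
    y_mean: float
    vip: np.ndarray | None = None
    q2y: float | None = None
    permutation_p: float | None = None

    @property
    def positive_class(self) -> str:
        return next(k for k, v in self.class_encoding.items() if v == 1)

    def loading_series(self) -> pd.Series:
        return pd.Series(self.loadings, index=self.metabolite_ids, name="loading")

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Continuous class prediction (±1 scale) for new rows of X."""
        Xc = np.asarray(X, dtype=float) - self.x_mean
        for comp in self.orthogonal:
            t_o = Xc @ comp.weights
            Xc = Xc - np.outer(t_o, comp.loadings)
        t = Xc @ self.weights
        return t * self.y_loading + self.y_mean


@dataclass
class DamTable:
    """Selected differentially accumulating metabolites with the thresholds used."""

    frame: pd.DataFrame  # metabolite_id, loading, vip, direction, log2_fc
    vip_min: float
    loading_quantile: float
    lfc_min: float | None = None
    contrast: tuple[str, str] | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.frame["metabolite_id"])


def _design(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    contrast: tuple[str, str],
    contrast_factor: str,
    sample_ids: list[str] | None,
) -> tuple[np.ndarray, np.ndarray, list[str], dict[str, int]]:
    """Assemble X, y (±1) for the two contrast classes."""
    neg_label, pos_label = contrast
    if neg_label == pos_label:
        raise ValidationError("contrast must name two distinct class labels")
    pool = sample_ids if sample_ids is not None else table.sample_ids
    labels = metadata.frame.loc[pool, contrast_factor]
    keep = [s for s in pool if labels[s] in (neg_label, pos_label)]
    y = np.array([1.0 if labels[s] == pos_label else -1.0 for s in keep])
    if (y == 1).sum() < 3 or (y == -1).sum() < 3:
        raise ValidationError(
            f"both classes need >= 3 samples; got {int((y == 1).sum())} "
            f"{pos_label!r} vs {int((y == -1).sum())} {neg_label!r}"
        )
    X = table.values.loc[keep].to_numpy()
    encoding = {neg_label: -1, pos_label: 1}
    return X, y, keep, encoding


def _fit_core(
    X: np.ndarray, y: np.ndarray, n_orthogonal: int
) -> dict:
    """O-PLS fit on already centred X, y. Returns raw component arrays."""
    ss_x0 = float(np.sum(X**2))
    ss_y = float(np.sum(y**2))
    if ss_y < _DEGENERATE_TOL:
        raise ValidationError("class vector has zero variance")
    Xd = X.copy()
    orthogonal: list[OrthogonalComponent] = []
    for _ in range(n_orthogonal):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw < _DEGENERATE_TOL:
            raise ValidationError("degenerate contrast: X'y is numerically zero")
        w = w / nw
        t = Xd @ w
        p = Xd.T @ t / float(t @ t)
        w_o = p - float(w @ p) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-10:
            break  # no class-orthogonal structure left
        w_o = w_o / n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / float(t_o @ t_o)
        r2x_o = float(t_o @ t_o) * float(p_o @ p_o) / ss_x0
        Xd = Xd - np.outer(t_o, p_o)
        orthogonal.append(OrthogonalComponent(w_o, t_o, p_o, r2x_o))
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw < _DEGENERATE_TOL:
        raise ValidationError("degenerate contrast: X'y is numerically zero")
    w = w / nw
    t = Xd @ w
    p = Xd.T @ t / float(t @ t)
    c = float(t @ y) / float(t @ t)
    r2x_pred = float(t @ t) * float(p @ p) / ss_x0
    resid = y - t * c
    r2y = 1.0 - float(np.sum(resid**2)) / ss_y
    return {
        "weights": w, "scores": t, "loadings": p, "y_loading": c,
        "orthogonal": orthogonal, "r2x_predictive": r2x_pred,
        "r2x_orthogonal": [o.r2x for o in orthogonal], "r2y": r2y,
    }


def fit_oplsda(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    contrast: tuple[str, str],
    n_orthogonal: int = 1,
    contrast_factor: str = "condition",
    sample_ids: list[str] | None = None,
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model.

    Parameters
    ----------
    contrast
        Pair (negative label, positive label); the positive class is
        encoded +1 (by convention, hypoxia — so positive loadings mean
        higher under submergence).
    contrast_factor
        Metadata column holding the class labels.
    sample_ids
        Optional subset of samples to model (e.g. one time point).
    """
    table.require_state(TableState.IMPUTED, TableState.LOG_SCALED)
    X, y, keep, encoding = _design(table, metadata, contrast, contrast_factor,
                                   sample_ids)
    if np.isnan(X).any():
        raise ValidationError("X contains missing values; impute first")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    core = _fit_core(X - x_mean, y - y_mean, n_orthogonal)
    model = OplsdaModel(
        metabolite_ids=table.metabolite_ids,
        sample_ids=keep,
        class_encoding=encoding,
        x_mean=x_mean,
        y_mean=y_mean,
        **core,
    )
    model.vip = vip(model)
    return model


def vip(model: OplsdaModel) -> np.ndarray:
    """Predictive-component VIP: sqrt(M) * |w_j| (w unit norm).

    Satisfies sum(VIP²) = M exactly.
    """
    if model.weights is None:
        raise ValidationError("model is not fitted")
    m = len(model.metabolite_ids)
    w = model.weights
    return np.sqrt(m) * np.abs(w) / np.linalg.norm(w)


def multi_component_vip(model: OplsdaModel) -> np.ndarray:
    """Classic multi-component PLS VIP over predictive + orthogonal parts.

    Provided for comparison; the predictive-only variant is the default
    reported by :func:`vip`.
    """
    m = len(model.metabolite_ids)
    comps = [(model.weights, model.scores, model.y_loading)]
    for o in model.orthogonal:
        # orthogonal components carry no y-variance by construction; their
        # SSY contribution is 0, so they only enter through the weight norm
        comps.append((o.weights, o.scores, 0.0))
    ssy = np.array([(c * np.linalg.norm(t)) ** 2 for w, t, c in comps])
    if ssy.sum() == 0:
        return np.zeros(m)
    w2 = np.stack([(w / np.linalg.norm(w)) ** 2 for w, t, c in comps])
    return np.sqrt(m * (ssy @ w2) / ssy.sum())


def _stratified_folds(
    y: np.ndarray, folds: int, fold_seed: int
) -> list[np.ndarray]:
    """Deterministic class-stratified fold assignment (round-robin deal)."""
    rng = np.random.default_rng(fold_seed)
    assignment = np.empty(len(y), dtype=int)
    offset = 0
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignment[i] = (pos + offset) % folds
        offset += len(idx)  # stagger classes across folds
    return [np.where(assignment == f)[0] for f in range(folds)]


def q2_cv(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    contrast: tuple[str, str],
    n_orthogonal: int = 1,
    folds: int = 7,
    fold_seed: int = 0,
    contrast_factor: str = "condition",
    sample_ids: list[str] | None = None,
) -> float:
    """Cross-validated Q²Y = 1 − PRESS/SS(y) with stratified folds."""
    table.require_state(TableState.IMPUTED, TableState.LOG_SCALED)
    X, y, _, _ = _design(table, metadata, contrast, contrast_factor, sample_ids)
    return _q2_core(X, y, n_orthogonal, folds, fold_seed)


def _q2_core(
    X: np.ndarray, y: np.ndarray, n_orthogonal: int, folds: int, fold_seed: int
) -> float:
    n = len(y)
    if folds < 2:
        raise ValidationError("folds must be >= 2")
    if folds > n:
        raise ValidationError(f"folds={folds} exceeds the {n} available samples")
    fold_idx = _stratified_folds(y, folds, fold_seed)
    # a training split must retain both classes
    for f, held in enumerate(fold_idx):
        train = np.setdiff1d(np.arange(n), held)
        if len(np.unique(y[train])) < 2:
            raise ValidationError(
                f"fold {f} leaves a single-class training set; use fewer folds"
            )
    press = 0.0
    for held in fold_idx:
        if held.size == 0:
            continue
        train = np.setdiff1d(np.arange(n), held)
        Xt, yt = X[train], y[train]
        x_mean = Xt.mean(axis=0)
        y_mean = float(yt.mean())
        core = _fit_core(Xt - x_mean, yt - y_mean, n_orthogonal)
        Xh = X[held] - x_mean
        for comp in core["orthogonal"]:
            t_o = Xh @ comp.weights
            Xh = Xh - np.outer(t_o, comp.loadings)
        y_hat = (Xh @ core["weights"]) * core["y_loading"] + y_mean
        press += float(np.sum((y[held] - y_hat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def permutation_test(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    contrast: tuple[str, str],
    n_perm: int = 1000,
    seed: int = 0,
    n_orthogonal: int = 1,
    folds: int = 7,
    contrast_factor: str = "condition",
    sample_ids: list[str] | None = None,
) -> float:
    """Label-permutation p-value for Q²Y with the add-one estimator.

    p = (1 + #{permuted Q²Y >= observed Q²Y}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValidationError("n_perm must be >= 99 for a meaningful p-value")
    X, y, _, _ = _design(table, metadata, contrast, contrast_factor, sample_ids)
    rng = np.random.default_rng(seed)
    observed = _q2_core(X, y, n_orthogonal, folds, fold_seed=seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        q2p = _q2_core(X, y_perm, n_orthogonal, folds, fold_seed=seed)
        if q2p >= observed:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def select_dams(
    model: OplsdaModel,
    table: MetaboliteTable,
    metadata: SampleMetadata,
    vip_min: float = 1.0,
    loading_quantile: float = 0.75,
    lfc_min: float | None = None,
    contrast_factor: str = "condition",
) -> DamTable:
    """Select differentially accumulating metabolites (DAMs).

    Retains metabolites with VIP >= `vip_min` whose |predictive loading|
    reaches the `loading_quantile` quantile of all |loadings|; an
    optional absolute log2 fold-change floor (`lfc_min`) can be added.
    Direction 'up' means higher in the positive class of the model's
    encoding.  The log2 fold change of group means is computed on the
    supplied abundance table, which must be on the normalized (pre-log)
    scale.

    Thresholds are recorded on the returned table.
    """
    if model.vip is None:
        raise ValidationError("model is not fitted")
    if vip_min < 0:
        raise ValidationError("vip_min must be non-negative")
    if not 0 <= loading_quantile <= 1:
        raise ValidationError("loading_quantile must lie in [0, 1]")
    table.require_state(TableState.RAW, TableState.NORMALIZED)

    loadings = model.loading_series()
    abs_load = loadings.abs()
    cut = float(np.quantile(abs_load.to_numpy(), loading_quantile))
    pos_label = model.positive_class
    neg_label = next(k for k in model.class_encoding if k != pos_label)

    labels = metadata.frame.loc[model.sample_ids, contrast_factor]
    pos_samples = [s for s in model.sample_ids if labels[s] == pos_label]
    neg_samples = [s for s in model.sample_ids if labels[s] == neg_label]
    pos_mean = table.values.loc[pos_samples].mean(axis=0, skipna=True)
    neg_mean = table.values.loc[neg_samples].mean(axis=0, skipna=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(pos_mean / neg_mean)

    rows = []
    for i, mid in enumerate(model.metabolite_ids):
        v = float(model.vip[i])
        load = float(loadings.iloc[i])
        if v < vip_min or abs(load) < cut:
            continue
        fc = float(lfc.get(mid, np.nan))
        if lfc_min is not None and (np.isnan(fc) or abs(fc) < lfc_min):
            continue
        rows.append(
            {
                "metabolite_id": mid,
                "loading": load,
                "vip": v,
                "direction": "up" if load > 0 else "down",
                "log2_fc": fc,
            }
        )
    frame = pd.DataFrame(
        rows, columns=["metabolite_id", "loading", "vip", "direction", "log2_fc"]
    )
    return DamTable(frame, vip_min, loading_quantile, lfc_min,
                    contrast=(neg_label, pos_label))


def compare_loadings(
    model_a: OplsdaModel, model_b: OplsdaModel
) -> tuple[float, float]:
    """Spearman correlation of predictive loadings over shared metabolites.

    Ties are mid-ranked; the p-value uses the large-sample t
    approximation.  Requires >= 10 shared metabolite ids.
    """
    shared = [m for m in model_a.metabolite_ids if m in set(model_b.metabolite_ids)]
    if len(shared) < 10:
        raise ValidationError(
            f"models share only {len(shared)} metabolites; >= 10 required"
        )
    a = model_a.loading_series().loc[shared]
    b = model_b.loading_series().loc[shared]
    rho, p = stats.spearmanr(a, b)
    return float(rho), float(p)
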