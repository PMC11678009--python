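"""Metabolite set enrichment analysis (MSEA) on loading-ranked lists.

The statistic is the weighted Kolmogorov–Smirnov running sum used by
GSEA-family tools: walking down the ranked list, hitting a set member
increments the sum by |score|^q normalised over the set's hits, missing
decrements by 1/(N − m); the enrichment score (ES) is the signed
extremum of largest magnitude.  Because the ranking here comes from
model loadings (one value per metabolite) rather than per-sample
statistics, the null is built from random same-size metabolite sets
drawn from the ranked universe, not from sample-label permutation.

NES normalises ES by the mean |null ES| of matching sign; p-values use
the add-one permutation estimator restricted to the matching sign, and
are Benjamini–Hochberg adjusted across tested sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from statsmodels.stats.multitest import multipletests

from .datamodel import MetaboliteSetCollection, ValidationError
from .oplsda import OplsdaModel

__all__ = [
    "RankedList",
    "EnrichmentResult",
    "rank_from_loadings",
    "enrichment_score",
    "msea_run",
    "pathway_overlap_graph",
]


@dataclass
class RankedList:
    """Metabolite ids with scores, sorted descending (ties id-ascending)."""

    ids: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.scores):
            raise ValidationError("ids and scores differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError("ranked list contains duplicated ids")
        order = sorted(
            range(len(self.ids)), key=lambda i: (-self.scores[i], self.ids[i])
        )
        self.ids = [self.ids[i] for i in order]
        self.scores = np.asarray([self.scores[i] for i in order], dtype=float)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class EnrichmentResult:
    frame: pd.DataFrame  # set_id, size, es, nes, p, padj, direction
    min_size: int
    n_perm: int

    def __len__(self) -> int:
        return len(self.frame)

    def significant(self, padj_max: float = 0.05) -> pd.DataFrame:
        return self.frame[self.frame["padj"] <= padj_max]


def rank_from_loadings(model: OplsdaModel) -> RankedList:
    """Rank metabolites by predictive loading, descending.

    With hypoxia as the positive class, positive scores mean
    up-regulation under hypoxia.  Tie scores fall back to id-lexicographic
    order (logged).
    """
    if model.vip is None:
        raise ValidationError("model is not fitted")
    loadings = model.loading_series()
    values = loadings.to_numpy()
    if len(np.unique(values)) != len(values):
        warnings.warn("tied loadings broken by id-lexicographic order",
                      stacklevel=2)
    return RankedList(list(loadings.index), values)


def enrichment_score(
    ranked: RankedList,
    set_members: list[str],
    weight_exponent: float = 1.0,
) -> float:
    """Signed extremum of the weighted KS running sum for one set."""
    member_set = set(set_members)
    hits = np.array([mid in member_set for mid in ranked.ids])
    if not hits.any():
        raise ValidationError("no set members present in the ranked list")
    return _es_from_hits(np.abs(ranked.scores) ** weight_exponent, hits)


def _es_from_hits(weights: np.ndarray, hits: np.ndarray) -> float:
    """Running-sum ES given |score|^q weights and a boolean hit mask."""
    n = len(weights)
    m = int(hits.sum())
    hit_w = weights[hits]
    total = hit_w.sum()
    if total == 0:
        # all hit scores are zero: fall back to unweighted increments
        hit_w = np.ones(m)
        total = float(m)
    full_w = weights.copy()
    full_w[hits] = hit_w
    inc = np.where(hits, full_w / total, 0.0)
    if n == m:
        return 1.0  # no misses: the sum climbs to exactly 1
    dec = np.where(hits, 0.0, 1.0 / (n - m))
    running = np.cumsum(inc - dec)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def _es_batch(
    weights: np.ndarray, n: int, positions: np.ndarray
) -> np.ndarray:
    """Vectorised ES for many same-size random sets.

    `positions` is (n_perm, m), each row sorted ascending 0-based
    positions of hits in the ranked list.  Extrema of the running sum
    occur at the top of each hit (maximum candidates) and just before
    each hit (minimum candidates); after the last hit the sum decays
    monotonically to 0, so no new extremum can appear there.
    """
    n_perm, m = positions.shape
    w = weights[positions]                    # (n_perm, m)
    totals = w.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        w[zero] = 1.0
        totals = w.sum(axis=1, keepdims=True)
    cum = np.cumsum(w, axis=1) / totals       # value contributed by hits
    k = np.arange(m)
    miss_before = (positions - k) / (n - m)   # misses before each hit
    at_hit = cum - miss_before                # after processing hit k
    before_hit = np.concatenate(
        [np.zeros((n_perm, 1)), cum[:, :-1]], axis=1
    ) - miss_before                           # just before hit k
    max_es = at_hit.max(axis=1)
    min_es = before_hit.min(axis=1)
    return np.where(max_es >= -min_es, max_es, min_es)


def msea_run(
    ranked: RankedList,
    sets: MetaboliteSetCollection,
    min_size: int = 3,
    n_perm: int = 10000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> EnrichmentResult:
    """Run enrichment for every set with >= min_size members in the list."""
    universe = list(ranked.ids)
    usable = sets.restrict(universe, min_size=1)
    dropped = [sid for sid in usable if len(usable[sid]) < min_size]
    if dropped:
        warnings.warn(
            f"{len(dropped)} sets below min_size={min_size} dropped", stacklevel=2
        )
    tested = {sid: usable[sid] for sid in usable if len(usable[sid]) >= min_size}
    if not tested:
        warnings.warn("no metabolite sets survive filtering", stacklevel=2)
        frame = pd.DataFrame(
            columns=["set_id", "size", "es", "nes", "p", "padj", "direction"]
        )
        return EnrichmentResult(frame, min_size, n_perm)

    n = len(universe)
    weights = np.abs(ranked.scores) ** weight_exponent
    pos_of = {mid: i for i, mid in enumerate(universe)}
    rng = np.random.default_rng(seed)

    rows = []
    null_cache: dict[int, np.ndarray] = {}
    for sid, members in tested.items():
        m = len(members)
        hits = np.zeros(n, dtype=bool)
        hits[[pos_of[x] for x in members]] = True
        es = _es_from_hits(weights, hits)
        if m not in null_cache:
            # random same-size member draws from the universe
            draw = np.argsort(rng.random((n_perm, n)), axis=1)[:, :m]
            draw.sort(axis=1)
            null_cache[m] = _es_batch(weights, n, draw)
        null = null_cache[m]
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        extreme = int((np.abs(null[same_sign]) >= abs(es)).sum())
        p = (1 + extreme) / (1 + n_same) if n_same else 1.0
        mean_null = float(np.abs(null[same_sign]).mean()) if n_same else np.nan
        nes = es / mean_null if mean_null and not np.isnan(mean_null) else np.nan
        rows.append(
            {
                "set_id": sid, "size": m, "es": es, "nes": nes, "p": p,
                "direction": "up" if es >= 0 else "down",
            }
        )
    frame = pd.DataFrame(rows)
    frame["padj"] = multipletests(frame["p"].to_numpy(), method="fdr_bh")[1]
    frame = frame[["set_id", "size", "es", "nes", "p", "padj", "direction"]]
    return EnrichmentResult(frame, min_size, n_perm)


def pathway_overlap_graph(
    result: EnrichmentResult,
    sets: MetaboliteSetCollection,
    padj_max: float | None = 0.05,
    universe: list[str] | None = None,
) -> nx.Graph:
    """Graph of enriched sets; edges join sets sharing >= 1 member.

    Nodes carry |NES| (plot size), padj (colour key) and direction.
    `padj_max=None` includes every tested set.
    """
    frame = result.frame
    if padj_max is not None:
        frame = frame[frame["padj"] <= padj_max]
    graph = nx.Graph()
    members: dict[str, set] = {}
    for _, row in frame.iterrows():
        sid = row["set_id"]
        if sid not in sets:
            raise ValidationError(f"enrichment row references unknown set {sid!r}")
        mem = set(sets[sid])
        if universe is not None:
            mem &= set(universe)
        members[sid] = mem
        graph.add_node(
            sid,
            abs_nes=float(abs(row["nes"])) if pd.notna(row["nes"]) else 0.0,
            padj=float(row["padj"]),
            direction=row["direction"],
        )
    ids = list(members)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if members[a] & members[b]:
                graph.add_edge(a, b)
    return graph
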