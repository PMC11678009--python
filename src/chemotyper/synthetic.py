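"""Synthetic GC-MS metabolomics generator with machine-readable ground truth.

The generator emulates the factorial design of a submergence-stress
chemotyping study — 2 genotypes x 2 oxygen conditions x 3 sampling days
x >= 4 biological replicates, ~370 metabolites — and the statistical
structure the downstream analysis assumes:

* a dominant oxygen-condition effect carried by ``n_dams`` planted
  differentially accumulating metabolites (log-scale shifts of random
  sign);
* a smaller genotype effect on all metabolites that decays geometrically
  over time under hypoxia only (the "leveling" of varietal differences);
* an age trend that is attenuated under hypoxia (developmental arrest);
* latent-factor correlation blocks whose member loadings are sign-flipped
  for a condition-specific fraction of members, rewiring the positive /
  negative edge balance between conditions;
* per-sample lognormal scale factors, sporadic multiplicative single-cell
  outliers, and sparse missing values (MCAR by default, optional
  intensity-dependent censoring).

Effects live on the natural-log scale so the preprocessing chain (log +
autoscale) linearises them; abundances are exponentiated, scaled and
perturbed afterwards.  All randomness flows from one seeded generator,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .datamodel import (
    MetaboliteAnnotation,
    MetaboliteSetCollection,
    MetaboliteTable,
    SampleMetadata,
    TableState,
    ValidationError,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_dataset", "truth_summary"]

_CHEM_CLASSES = (
    "amino_acid", "carboxylate", "sugar", "disaccharide", "sugar_phosphate",
    "sterol", "fatty_acid", "phenolic", "nucleobase", "glycoside",
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_metabolites: int = 370
    n_replicates: int = 4
    genotypes: tuple[str, ...] = ("varA", "varB")
    conditions: tuple[str, str] = ("normoxia", "hypoxia")
    times: tuple[int, ...] = (3, 5, 7)

    #: baseline log-abundance mean/sd across metabolites
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 0.5

    #: scale of planted hypoxia effects (log units); magnitudes are drawn
    #: around this value so every planted DAM is genuinely differential
    condition_effect_sd: float = 2.0
    #: diffuse hypoxia response shared by all non-DAM metabolites (log
    #: units): submergence rearranges the whole profile, not just the
    #: strong markers; kept well below the DAM selection thresholds
    condition_diffuse_sd: float = 0.01
    #: scale of planted genotype effects (log units), applied to
    #: n_genotype_dams metabolites disjoint from the hypoxia DAMs
    genotype_effect_sd: float = 0.25
    n_genotype_dams: int = 60
    #: geometric decay of the genotype effect per time step under hypoxia
    genotype_shrink_rate: float = 0.55
    #: per-metabolite linear age trend scale (log units per day, centred)
    age_effect_sd: float = 0.02
    #: multiplier on the age trend under hypoxia (developmental arrest)
    age_attenuation_hypoxia: float = 0.3

    n_dams: int = 40
    n_enriched_sets: int = 4
    n_background_sets: int = 16
    set_size: int = 10

    n_latent_factors: int = 5
    block_size: int = 12
    factor_loading_sd: float = 0.8
    #: fraction of block members whose loading sign flips, per condition
    sign_mixing_fraction: dict = field(
        default_factory=lambda: {"normoxia": 0.0, "hypoxia": 0.3}
    )
    #: condition-specific block activity: some co-regulation blocks are
    #: strong only under hypoxia (stress-induced hubs) or only under
    #: normoxia; the rest are shared.  Inactive blocks keep a residual
    #: loading (`inactive_loading_factor` x nominal).
    hypoxia_only_blocks: int = 3
    normoxia_only_blocks: int = 1
    inactive_loading_factor: float = 0.25

    noise_sd: float = 0.1
    missing_prob: float = 0.01
    missing_mode: str = "mcar"  # or "censor" (intensity-dependent)
    outlier_prob: float = 0.002
    outlier_multiplier: float = 30.0
    sample_scale_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        for name in ("missing_prob", "outlier_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        for cond, frac in self.sign_mixing_fraction.items():
            if not 0 <= frac <= 1:
                raise ValidationError(
                    f"sign_mixing_fraction[{cond!r}] must lie in [0, 1]"
                )
        if self.n_dams > self.n_metabolites:
            raise ValidationError("n_dams cannot exceed n_metabolites")
        if self.set_size > self.n_metabolites:
            raise ValidationError("set_size cannot exceed n_metabolites")
        if self.n_enriched_sets and self.set_size > max(self.n_dams // 2, 1):
            raise ValidationError(
                "set_size exceeds the number of same-sign planted DAMs; "
                "increase n_dams or shrink set_size"
            )
        needed = (self.n_dams + self.n_latent_factors * self.block_size
                  + self.n_genotype_dams)
        if needed > self.n_metabolites:
            raise ValidationError(
                f"planted structure needs {needed} metabolites but only "
                f"{self.n_metabolites} are configured"
            )
        if self.missing_mode not in ("mcar", "censor"):
            raise ValidationError("missing_mode must be 'mcar' or 'censor'")
        if self.hypoxia_only_blocks + self.normoxia_only_blocks > self.n_latent_factors:
            raise ValidationError(
                "condition-specific blocks exceed n_latent_factors"
            )
        if not (0 < self.genotype_shrink_rate <= 1):
            raise ValidationError("genotype_shrink_rate must lie in (0, 1]")


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset."""

    dam_effects: dict[str, float]              # id -> signed hypoxia shift
    genotype_effects: dict[str, float]         # id -> beta (varB - varA)
    age_effects: dict[str, float]              # id -> gamma per day
    enriched_sets: dict[str, str]              # set_id -> 'up' | 'down'
    blocks: list[list[str]]                    # latent-factor membership
    block_activity: list[dict[str, float]]     # per block: condition -> multiplier
    flipped_members: dict[str, set]            # condition -> ids with flipped sign
    outlier_cells: list[tuple[str, str]]       # (sample_id, metabolite_id)
    missing_cells: list[tuple[str, str]]
    scale_factors: dict[str, float]

    def dam_ids(self) -> list[str]:
        return list(self.dam_effects)

    def block_pairs(self, condition: str | None = None) -> set[tuple[str, str]]:
        """Within-block (co-regulated) unordered pairs, ids sorted.

        With a condition, only blocks active in that condition
        (loading multiplier >= 0.5) contribute pairs.
        """
        pairs: set[tuple[str, str]] = set()
        for block, activity in zip(self.blocks, self.block_activity):
            if condition is not None and activity.get(condition, 1.0) < 0.5:
                continue
            for i, a in enumerate(block):
                for b in block[i + 1:]:
                    pairs.add((a, b) if a < b else (b, a))
        return pairs

    def pair_sign(self, condition: str, a: str, b: str) -> int:
        """Expected correlation sign of a within-block pair in a condition."""
        flipped = self.flipped_members.get(condition, set())
        sa = -1 if a in flipped else 1
        sb = -1 if b in flipped else 1
        return sa * sb


def _magnitudes(rng: np.random.Generator, n: int, scale: float) -> np.ndarray:
    """Effect magnitudes concentrated near `scale`, bounded away from zero."""
    return np.clip(rng.normal(scale, scale / 4, size=n), 0.3 * scale, None)


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[
    MetaboliteTable,
    SampleMetadata,
    MetaboliteAnnotation,
    MetaboliteSetCollection,
    GroundTruth,
]:
    """Generate one synthetic study with full ground truth."""
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_metabolites
    width = len(str(m))
    metabolite_ids = [f"M{i + 1:0{width}d}" for i in range(m)]

    # --- design ---------------------------------------------------------
    design = list(
        product(config.genotypes, config.conditions, config.times,
                range(1, config.n_replicates + 1))
    )
    sample_ids = [
        f"{g}_{c[:3]}_d{t}_r{r}" for (g, c, t, r) in design
    ]
    n = len(design)
    meta = pd.DataFrame(
        {
            "genotype": [g for g, _, _, _ in design],
            "condition": [c for _, c, _, _ in design],
            "time_das": [t for _, _, t, _ in design],
            "replicate": [r for _, _, _, r in design],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    metadata = SampleMetadata(meta)

    # --- planted effects ------------------------------------------------
    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, size=m)
    alpha = np.zeros(m)
    dam_idx = np.arange(config.n_dams)
    signs = np.where(np.arange(config.n_dams) % 2 == 0, 1.0, -1.0)
    alpha[dam_idx] = signs * _magnitudes(rng, config.n_dams,
                                         config.condition_effect_sd)
    diffuse = rng.normal(0.0, config.condition_diffuse_sd, size=m)
    diffuse[dam_idx] = 0.0
    alpha = alpha + diffuse
    gamma = rng.normal(0.0, config.age_effect_sd, size=m)

    # latent blocks occupy the ids immediately after the DAM block, and the
    # genotype-affected metabolites follow the blocks, so the planted
    # effect classes stay disjoint and attribution is unambiguous
    blocks: list[list[int]] = []
    start = config.n_dams
    for f in range(config.n_latent_factors):
        blocks.append(list(range(start, start + config.block_size)))
        start += config.block_size
    beta = np.zeros(m)
    geno_idx = np.arange(start, start + config.n_genotype_dams)
    geno_signs = np.where(np.arange(config.n_genotype_dams) % 2 == 0, 1.0, -1.0)
    beta[geno_idx] = geno_signs * _magnitudes(
        rng, config.n_genotype_dams, config.genotype_effect_sd
    )
    loading_mag = np.zeros(m)
    for block in blocks:
        loading_mag[block] = _magnitudes(
            rng, len(block), config.factor_loading_sd
        )
    flipped: dict[str, set] = {}
    for cond in config.conditions:
        frac = float(config.sign_mixing_fraction.get(cond, 0.0))
        flip: set[int] = set()
        for block in blocks:
            k = int(round(frac * len(block)))
            if k:
                flip.update(rng.choice(block, size=k, replace=False).tolist())
        flipped[cond] = flip

    # condition-specific block activity: stress-induced blocks come first,
    # then the normoxia-only block(s); the remainder are shared
    block_activity: list[dict[str, float]] = []
    weak = config.inactive_loading_factor
    for f in range(config.n_latent_factors):
        if f < config.hypoxia_only_blocks:
            block_activity.append({"normoxia": weak, "hypoxia": 1.0})
        elif f < config.hypoxia_only_blocks + config.normoxia_only_blocks:
            block_activity.append({"normoxia": 1.0, "hypoxia": weak})
        else:
            block_activity.append({"normoxia": 1.0, "hypoxia": 1.0})

    # --- assemble log abundances ---------------------------------------
    log_x = np.tile(mu, (n, 1))
    times = np.array([t for _, _, t, _ in design], dtype=float)
    is_hyp = np.array([c == "hypoxia" for _, c, _, _ in design])
    geno_sign = np.array(
        [0.5 if g == config.genotypes[-1] else -0.5 for g, _, _, _ in design]
    )
    steps = np.array([config.times.index(t) for _, _, t, _ in design])
    shrink = np.where(is_hyp, config.genotype_shrink_rate ** steps, 1.0)
    age_mult = np.where(is_hyp, config.age_attenuation_hypoxia, 1.0)
    t_centred = times - np.mean(config.times)

    log_x += np.outer(is_hyp.astype(float), alpha)
    log_x += np.outer(geno_sign * shrink, beta)
    log_x += np.outer(t_centred * age_mult, gamma)

    cond_sign = np.ones((n, m))
    for s in range(n):
        cond = design[s][1]
        for i in flipped[cond]:
            cond_sign[s, i] = -1.0
    for f, block in enumerate(blocks):
        z = rng.standard_normal(n)
        lam = np.zeros(m)
        lam[block] = loading_mag[block]
        activity = np.array(
            [block_activity[f][design[s][1]] for s in range(n)]
        )
        log_x += (z * activity)[:, None] * lam[None, :] * cond_sign

    log_x += rng.normal(0.0, config.noise_sd, size=(n, m))

    # --- exponentiate, scale, perturb -----------------------------------
    values = np.exp(log_x)
    scale = np.exp(rng.normal(0.0, config.sample_scale_sd, size=n))
    values *= scale[:, None]

    outlier_mask = rng.random((n, m)) < config.outlier_prob
    values[outlier_mask] *= config.outlier_multiplier

    if config.missing_mode == "mcar":
        missing_mask = rng.random((n, m)) < config.missing_prob
    else:  # intensity-dependent left censoring at the same expected rate
        ranks = values.argsort(axis=0).argsort(axis=0) / max(n - 1, 1)
        low = ranks < 0.1
        missing_mask = low & (rng.random((n, m)) < config.missing_prob * 10)
    values = values.astype(float)
    values[missing_mask] = np.nan
    outlier_mask &= ~missing_mask  # a masked cell is just missing

    table = MetaboliteTable(
        pd.DataFrame(values, index=sample_ids, columns=metabolite_ids),
        TableState.RAW,
    )

    # --- annotation -----------------------------------------------------
    chem_class = np.array(
        [_CHEM_CLASSES[i % len(_CHEM_CLASSES)] for i in range(m)], dtype=object
    )
    for f, block in enumerate(blocks):  # co-regulated blocks share a class
        chem_class[block] = _CHEM_CLASSES[f % len(_CHEM_CLASSES)]
    annotated = rng.random(m) < 0.6
    annotation = MetaboliteAnnotation(
        pd.DataFrame(
            {
                "display_name": [
                    f"compound_{mid}" if annotated[i] else f"unknown_{mid}"
                    for i, mid in enumerate(metabolite_ids)
                ],
                "chem_class": chem_class,
                "kegg_compound": [
                    f"C{10000 + i}" if annotated[i] else None
                    for i in range(m)
                ],
                "retention_index": 1000.0 + 4.5 * np.arange(m),
            },
            index=pd.Index(metabolite_ids, name="metabolite_id"),
        )
    )

    # --- metabolite sets -------------------------------------------------
    dam_set = set(dam_idx.tolist())
    up_ids = [metabolite_ids[i] for i in dam_idx if alpha[i] > 0]
    down_ids = [metabolite_ids[i] for i in dam_idx if alpha[i] < 0]
    non_dam = [metabolite_ids[i] for i in range(m) if i not in dam_set]
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    truth_sets: dict[str, str] = {}
    n_up = (config.n_enriched_sets + 1) // 2
    for s in range(config.n_enriched_sets):
        direction = "up" if s < n_up else "down"
        pool = up_ids if direction == "up" else down_ids
        members = rng.choice(pool, size=config.set_size, replace=False).tolist()
        sid = f"path_enr_{direction}_{s + 1}"
        sets[sid] = sorted(members)
        descriptions[sid] = f"planted {direction}-regulated pathway"
        truth_sets[sid] = direction
    for s in range(config.n_background_sets):
        members = rng.choice(non_dam, size=config.set_size, replace=False).tolist()
        sid = f"path_bg_{s + 1}"
        sets[sid] = sorted(members)
        descriptions[sid] = "background pathway"
    collection = MetaboliteSetCollection(sets, descriptions)

    truth = GroundTruth(
        dam_effects={metabolite_ids[i]: float(alpha[i]) for i in dam_idx},
        genotype_effects={metabolite_ids[i]: float(beta[i]) for i in geno_idx},
        age_effects={metabolite_ids[i]: float(gamma[i]) for i in range(m)},
        enriched_sets=truth_sets,
        blocks=[[metabolite_ids[i] for i in block] for block in blocks],
        block_activity=block_activity,
        flipped_members={
            cond: {metabolite_ids[i] for i in idx} for cond, idx in flipped.items()
        },
        outlier_cells=[
            (sample_ids[i], metabolite_ids[j])
            for i, j in np.argwhere(outlier_mask)
        ],
        missing_cells=[
            (sample_ids[i], metabolite_ids[j])
            for i, j in np.argwhere(missing_mask)
        ],
        scale_factors={sample_ids[i]: float(scale[i]) for i in range(n)},
    )
    return table, metadata, annotation, collection, truth


def truth_summary(truth: GroundTruth) -> pd.DataFrame:
    """Flat table of planted effects for the test suite and reports."""
    rows = []
    for mid, eff in truth.dam_effects.items():
        rows.append({"section": "dam", "id": mid, "value": eff,
                     "label": "up" if eff > 0 else "down"})
    for sid, direction in truth.enriched_sets.items():
        rows.append({"section": "enriched_set", "id": sid, "value": np.nan,
                     "label": direction})
    for b, block in enumerate(truth.blocks):
        for mid in block:
            rows.append({"section": "block", "id": mid, "value": float(b),
                         "label": f"block_{b}"})
    for cond, ids in truth.flipped_members.items():
        for mid in sorted(ids):
            rows.append({"section": "sign_flip", "id": mid, "value": np.nan,
                         "label": cond})
    for sid, mid in truth.outlier_cells:
        rows.append({"section": "outlier", "id": f"{sid}:{mid}",
                     "value": np.nan, "label": ""})
    for sid, mid in truth.missing_cells:
        rows.append({"section": "missing", "id": f"{sid}:{mid}",
                     "value": np.nan, "label": ""})
    for sid, f in truth.scale_factors.items():
        rows.append({"section": "scale_factor", "id": sid, "value": f,
                     "label": ""})
    return pd.DataFrame(rows, columns=["section", "id", "value", "label"])
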