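"""End-to-end orchestration: preprocessing through networks, with provenance.

:func:`run_pipeline` chains the analysis stages in their canonical
order — preprocess, PCA, per-time-point hypoxia-vs-control OPLS-DA per
genotype (with DAM tables and set enrichment), intervarietal models
under hypoxia with loading comparisons, and correlation networks with
metrics, dissimilarities and a Ward dendrogram — writing every result
table plus a :class:`RunManifest` to a run directory.  Reruns with the
same config and seed reproduce the outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .datamodel import (
    MetaboliteAnnotation,
    MetaboliteTable,
    SampleMetadata,
    TableState,
    ValidationError,
)
from .msea import msea_run, pathway_overlap_graph, rank_from_loadings
from .netcomp import (
    build_network,
    network_dissimilarity,
    network_metrics,
    ward_cluster,
)
from .oplsda import (
    compare_loadings,
    fit_oplsda,
    permutation_test,
    q2_cv,
    select_dams,
)
from .ordination import fit_pca, group_ellipse
from .preprocess import PreprocessConfig, median_normalize, preprocess_pipeline
from .synthetic import GeneratorConfig, generate_dataset, truth_summary

__all__ = ["RunManifest", "PipelineError", "group_mean_matrix", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config: dict
    seeds: dict = field(default_factory=dict)
    input_digests: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "seeds": self.seeds,
                "input_digests": self.input_digests,
                "stage_seconds": self.stage_seconds,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def group_mean_matrix(
    table: MetaboliteTable,
    metadata: SampleMetadata,
    annotation: MetaboliteAnnotation | None = None,
) -> pd.DataFrame:
    """Per-metabolite means over (genotype x condition x time) groups,
    centred and scaled across groups (heatmap matrix).

    Rows are metabolites, ordered by chemical class when annotation is
    supplied; columns are group labels.  Each row has mean 0 across
    groups; constant rows scale to zeros.
    """
    table.require_state(TableState.IMPUTED, TableState.LOG_SCALED,
                        TableState.NORMALIZED)
    metadata.validate_against(table)
    groups = metadata.group_key().loc[table.sample_ids]
    means = {}
    for g, idx in sorted(groups.groupby(groups).groups.items()):
        if len(idx) == 0:
            raise ValidationError(f"group {g} has no samples")
        label = "_".join(str(x) for x in g)
        means[label] = table.values.loc[idx].mean(axis=0, skipna=True)
    frame = pd.DataFrame(means)
    centred = frame.sub(frame.mean(axis=1), axis=0)
    sd = frame.std(axis=1, ddof=1)
    scaled = centred.div(sd.where(sd > 0, 1.0), axis=0)
    scaled[sd == 0] = 0.0
    if annotation is not None:
        order = (
            annotation.frame.reindex(scaled.index)["chem_class"]
            .fillna("~unannotated")
            .sort_values(kind="stable")
            .index
        )
        scaled = scaled.loc[order]
    return scaled


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_config(config_path) -> dict:
    with open(config_path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if "output_dir" not in cfg:
        raise ValidationError("config must define output_dir")
    has_input = "inputs" in cfg
    has_sim = "simulate" in cfg
    if has_input == has_sim:
        raise ValidationError(
            "config must define exactly one of 'inputs' or 'simulate'"
        )
    if has_input:
        for key in ("matrix", "metadata"):
            p = cfg["inputs"].get(key)
            if not p or not Path(p).exists():
                raise ValidationError(f"input file for {key!r} missing: {p}")
    return cfg


def run_pipeline(config_path) -> RunManifest:
    """Execute the configured analysis end to end; returns the manifest."""
    cfg = _load_config(config_path)
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    rng = np.random.default_rng(seed)
    manifest = RunManifest(config=cfg, seeds={"root": seed})
    opts = cfg.get("options", {})
    n_perm = int(opts.get("n_perm", 199))
    msea_perm = int(opts.get("msea_n_perm", 2000))
    folds = int(opts.get("folds", 7))
    q_threshold = float(opts.get("network_q", 0.05))
    per_time_networks = bool(opts.get("per_time_networks", False))

    def emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        manifest.outputs.append(name)
        return path

    def stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                manifest.stage_seconds[name] = round(
                    time.perf_counter() - self_inner.t0, 4
                )
                if exc is not None:
                    (out_dir / "manifest.json").write_text(manifest.to_json())
                    raise PipelineError(name, exc) from exc
                return False

        return _Timer()

    sets = None
    with stage("load"):
        if "simulate" in cfg:
            gen_kwargs = dict(cfg["simulate"] or {})
            gen_kwargs.setdefault("seed", seed)
            gcfg = GeneratorConfig(**gen_kwargs)
            table, metadata, annotation, sets, truth = generate_dataset(gcfg)
            emit("truth.tsv", lambda p: cio.write_table(truth_summary(truth), p))
            emit("simulated_matrix.tsv", lambda p: cio.write_table(table, p))
            emit("metadata.tsv", lambda p: cio.write_table(metadata, p))
            emit("annotation.tsv", lambda p: cio.write_table(annotation, p))
            emit("sets.gmt", lambda p: cio.write_gmt(sets, p))
        else:
            inputs = cfg["inputs"]
            table, metadata, annotation = cio.load_dataset(
                inputs["matrix"], inputs["metadata"], inputs.get("annotation")
            )
            if inputs.get("sets"):
                sets = cio.load_metabolite_sets(inputs["sets"])
            for key, p in inputs.items():
                if p:
                    manifest.input_digests[key] = _digest(Path(p))

    with stage("preprocess"):
        pcfg = PreprocessConfig(
            dixon_alpha=float(opts.get("dixon_alpha", 0.05)),
            knn_k=int(opts.get("knn_k", 10)),
        )
        normalized, _ = median_normalize(table)
        processed, report = preprocess_pipeline(table, metadata, pcfg)
        complete_cols = ~processed.values.isna().any(axis=0)
        if not complete_cols.all():
            processed = MetaboliteTable(
                processed.values.loc[:, complete_cols], TableState.IMPUTED
            )
            normalized = MetaboliteTable(
                normalized.values.loc[:, complete_cols], TableState.NORMALIZED
            )
        emit("preprocessed.tsv", lambda p: cio.write_table(processed, p))
        emit("preprocess_report.tsv",
             lambda p: cio.write_table(report.to_frame().set_index("action"), p))
        emit("group_mean_heatmap.tsv",
             lambda p: cio.write_table(
                 group_mean_matrix(processed, metadata, annotation), p))

    with stage("pca"):
        n_comp = min(5, processed.n_samples - 1, processed.n_metabolites)
        pca = fit_pca(processed, n_comp)
        emit("pca_scores.tsv", lambda p: cio.write_table(pca.scores, p))
        emit("pca_loadings.tsv", lambda p: cio.write_table(pca.loadings, p))
        emit("pca_variance.tsv", lambda p: cio.write_table(
            pd.DataFrame(
                {"variance_fraction": pca.variance_fraction},
                index=pca.scores.columns[: len(pca.variance_fraction)],
            ), p))
        labels = metadata.frame.loc[processed.sample_ids, "condition"]
        ellipses = group_ellipse(pca.scores.iloc[:, :2], labels)
        emit("pca_ellipses.tsv", lambda p: cio.write_table(
            pd.DataFrame(
                [
                    {"group": e.group, "cx": e.center[0], "cy": e.center[1],
                     "semi_major": e.semi_axes[0], "semi_minor": e.semi_axes[1],
                     "angle_rad": e.angle, "level": e.level}
                    for e in ellipses
                ]
            ).set_index("group"), p))

    genotypes = sorted(metadata.frame["genotype"].unique())
    times = sorted(metadata.frame["time_das"].unique())
    model_rows = []
    hypoxia_models: dict[tuple[str, int], object] = {}
    with stage("oplsda_condition"):
        for geno in genotypes:
            for t in times:
                sel = metadata.select(genotype=geno, time_das=t)
                model = fit_oplsda(
                    processed, metadata, ("normoxia", "hypoxia"),
                    sample_ids=sel,
                )
                q2_seed = int(rng.integers(2**31 - 1))
                model.q2y = q2_cv(
                    processed, metadata, ("normoxia", "hypoxia"),
                    folds=min(folds, len(sel)), fold_seed=q2_seed,
                    sample_ids=sel,
                )
                perm_seed = int(rng.integers(2**31 - 1))
                model.permutation_p = permutation_test(
                    processed, metadata, ("normoxia", "hypoxia"),
                    n_perm=n_perm, seed=perm_seed,
                    folds=min(folds, len(sel)), sample_ids=sel,
                )
                manifest.seeds[f"oplsda_{geno}_{t}das"] = {
                    "q2": q2_seed, "perm": perm_seed,
                }
                hypoxia_models[(geno, t)] = model
                model_rows.append(
                    {"contrast": "hypoxia_vs_normoxia", "genotype": geno,
                     "time_das": t, "r2x_predictive": model.r2x_predictive,
                     "r2y": model.r2y, "q2y": model.q2y,
                     "permutation_p": model.permutation_p}
                )
                dams = select_dams(model, normalized, metadata)
                emit(f"dams_{geno}_{t}das.tsv",
                     lambda p, d=dams: cio.write_table(
                         d.frame.set_index("metabolite_id"), p))

    with stage("msea"):
        if sets is not None:
            for (geno, t), model in hypoxia_models.items():
                ranked = rank_from_loadings(model)
                msea_seed = int(rng.integers(2**31 - 1))
                result = msea_run(ranked, sets, n_perm=msea_perm,
                                  seed=msea_seed)
                manifest.seeds[f"msea_{geno}_{t}das"] = msea_seed
                emit(f"msea_{geno}_{t}das.tsv",
                     lambda p, r=result: cio.write_table(
                         r.frame.set_index("set_id"), p))
                graph = pathway_overlap_graph(result, sets,
                                              universe=ranked.ids)
                emit(f"msea_overlap_{geno}_{t}das.edges.tsv",
                     lambda p, g=graph: pd.DataFrame(
                         sorted(g.edges), columns=["set_a", "set_b"]
                     ).to_csv(p, sep="\t", index=False))

    with stage("oplsda_intervarietal"):
        rows = []
        loading_rhos = []
        for cond in ("hypoxia", "normoxia"):
            for t in times:
                sel = metadata.select(condition=cond, time_das=t)
                model = fit_oplsda(
                    processed, metadata, (genotypes[0], genotypes[1]),
                    contrast_factor="genotype", sample_ids=sel,
                )
                q2_seed = int(rng.integers(2**31 - 1))
                model.q2y = q2_cv(
                    processed, metadata, (genotypes[0], genotypes[1]),
                    contrast_factor="genotype", folds=min(folds, len(sel)),
                    fold_seed=q2_seed, sample_ids=sel,
                )
                dams = select_dams(model, normalized, metadata,
                                   contrast_factor="genotype")
                rows.append(
                    {"contrast": "intervarietal", "condition": cond,
                     "time_das": t, "r2x_predictive": model.r2x_predictive,
                     "r2y": model.r2y, "q2y": model.q2y,
                     "n_dams": len(dams)}
                )
        # similarity of the hypoxia response between genotypes per time
        for t in times:
            rho, p = compare_loadings(
                hypoxia_models[(genotypes[0], t)],
                hypoxia_models[(genotypes[1], t)],
            )
            loading_rhos.append(
                {"time_das": t, "rho": rho, "p": p,
                 "comparison": f"{genotypes[0]}_vs_{genotypes[1]}"}
            )
        emit("intervarietal_models.tsv", lambda p: cio.write_table(
            pd.DataFrame(rows).set_index("contrast"), p))
        emit("loading_similarity.tsv", lambda p: cio.write_table(
            pd.DataFrame(loading_rhos).set_index("time_das"), p))

    with stage("networks"):
        nets = []
        for geno in genotypes:
            for cond in ("normoxia", "hypoxia"):
                stratum = {"genotype": geno, "condition": cond}
                if per_time_networks:
                    for t in times:
                        nets.append(build_network(
                            processed, metadata, {**stratum, "time_das": t},
                            q_threshold=q_threshold,
                            stratum_label=f"{geno}_{cond}_{t}das",
                        ))
                else:
                    nets.append(build_network(
                        processed, metadata, stratum,
                        q_threshold=q_threshold,
                        stratum_label=f"{geno}_{cond}",
                    ))
        metrics = {net.stratum: network_metrics(net).to_dict() for net in nets}
        emit("network_metrics.json", lambda p: p.write_text(
            json.dumps(metrics, indent=2, sort_keys=True)))
        for net in nets:
            emit(f"network_{net.stratum}.edges.tsv",
                 lambda p, nn=net: cio.write_table(
                     nn.to_edge_frame().set_index("id_a"), p))
        for method in ("bray_curtis_degrees", "jaccard_edges"):
            comp = network_dissimilarity(nets, method=method)
            _, newick = ward_cluster(comp)
            emit(f"network_dissimilarity_{method}.tsv",
                 lambda p, c=comp: cio.write_table(c.to_frame(), p))
            emit(f"network_dendrogram_{method}.nwk",
                 lambda p, nw=newick: p.write_text(nw + "\n"))

    with stage("summary"):
        emit("model_summary.tsv", lambda p: cio.write_table(
            pd.DataFrame(model_rows).set_index("contrast"), p))

    (out_dir / "manifest.json").write_text(manifest.to_json())
    manifest.outputs.append("manifest.json")
    return manifest
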