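"""End-to-end pipeline driver.

Stages run in order simulate -> qc -> composition -> score -> deg ->
stratify -> spatial on a synthetic cohort (or user-supplied inputs), each
stage writing CSV outputs with a metadata comment header (version, seed,
parameter hash) and the driver writing a JSON manifest with per-stage
runtimes. Every source of randomness derives from the single configured
seed, so two runs with the same config produce byte-identical CSV bodies.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from . import __version__
from .composition import clr_transform, compare_conditions, sample_compositions
from .deg import (
    OverlapSpec,
    TierThresholds,
    cross_celltype_intersections,
    dual_threshold_overlap,
    significant_degs,
    wilcoxon_de,
)
from .io import write_csv_with_metadata, write_manifest, write_mtx_bundle
from .qc import QCThresholds, lognormalize, run_qc
from .scoring import (
    expression_dot_summary,
    label_cells_by_signature,
    module_score,
    one_vs_rest_enrichment,
)
from .spatial import per_sample_svg
from .stratification import (
    StratificationRule,
    astro_stratify,
    cross_region_consistency,
    fourway_stratify,
    mixed_rate,
    sample_divergence_matrix,
)
from .synthetic import (
    CohortConfig,
    SpatialConfig,
    generate_cohort,
    generate_spatial_sample,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "qc", "composition", "score", "deg", "stratify", "spatial")


@dataclass
class PipelineConfig:
    out_dir: str = "glioprog_out"
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: CohortConfig = field(default_factory=CohortConfig)
    # QC bounds scaled to the synthetic cohort's 600-gene panel and the
    # consensus voting scaled to its size; real-data runs should supply the
    # standard thresholds via the config file.
    qc_thresholds: QCThresholds = field(
        default_factory=lambda: QCThresholds(min_umi=500, min_genes=150, consensus_iters=40)
    )
    tier_thresholds: TierThresholds = field(default_factory=TierThresholds)
    overlap_spec: OverlapSpec = field(default_factory=OverlapSpec)
    strat_rule: StratificationRule = field(default_factory=StratificationRule)
    divergence_min_cells: int = 100
    divergence_k: int = 6
    n_spatial_samples: int = 2
    spatial: SpatialConfig = field(default_factory=SpatialConfig)
    spatial_n_perm: int = 100
    spatial_min_obs: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if hasattr(current, "__dataclass_fields__") and isinstance(value, dict):
                for k2, v2 in value.items():
                    if not hasattr(current, k2):
                        raise ValueError(f"unknown key {key}.{k2}")
                    setattr(current, k2, v2)
            elif key == "stages":
                cfg.stages = tuple(value)
            else:
                setattr(cfg, key, value)
        cfg.cohort.seed = cfg.seed
        return cfg

    def params_hash(self) -> str:
        def default(o):
            if hasattr(o, "__dataclass_fields__"):
                return asdict(o)
            if isinstance(o, pd.DataFrame):
                return o.to_dict()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            return str(o)

        params = asdict(self)
        params.pop("out_dir", None)  # a path, not an analysis parameter
        blob = json.dumps(params, default=default, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "version": __version__,
        "seed": config.seed,
        "params_hash": config.params_hash(),
    }
    manifest: dict = {"outputs": [], "stage_runtime_s": {}, **meta}
    state: dict = {}
    seed_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {s: int(v % (2**31)) for s, v in zip(STAGES, seed_seq.generate_state(len(STAGES)))}

    def emit(name: str, df: pd.DataFrame, index: bool = True) -> None:
        path = out / name
        write_csv_with_metadata(df, path, meta, index=index)
        manifest["outputs"].append(name)

    for stage in config.stages:
        t0 = time.monotonic()
        logger.info("[stage:%s] start", stage)
        try:
            _run_stage(stage, config, state, emit, out, manifest, meta, stage_seeds)
        except Exception as exc:
            for name in manifest["outputs"]:
                p = out / name
                if p.exists() and stage in name:
                    p.rename(p.with_suffix(p.suffix + ".partial"))
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.monotonic() - t0
        manifest["stage_runtime_s"][stage] = round(dt, 3)
        logger.info("[stage:%s] done in %.2fs", stage, dt)

    write_manifest(out / "manifest.json", manifest)
    manifest["outputs"].append("manifest.json")
    return manifest


def _run_stage(stage, config, state, emit, out, manifest, meta, stage_seeds):
    if stage == "simulate":
        matrix, ann, truth = generate_cohort(config.cohort)
        state.update(matrix=matrix, annotations=ann, truth=truth)
        write_mtx_bundle(matrix, out / "counts")
        manifest["outputs"] += ["counts/matrix.mtx", "counts/barcodes.tsv", "counts/features.tsv"]
        emit("cells.csv", ann, index=False)
        (out / "truth.json").write_text(
            json.dumps({"donors": truth.to_dict(orient="records")}, indent=2) + "\n"
        )
        manifest["outputs"].append("truth.json")

    elif stage == "qc":
        matrix, ann = state["matrix"], state["annotations"]
        report = run_qc(
            matrix,
            matrix.marker_sets("cell_class"),
            config.qc_thresholds,
            seed=stage_seeds["qc"],
            sample_labels=ann["donor_id"].to_numpy(),
        )
        kept = report.kept
        state["kept_mask"] = kept
        state["annotations_qc"] = ann[kept].reset_index(drop=True)
        (out / "kept_cells.txt").write_text(
            "\n".join(np.array(matrix.cell_ids)[kept]) + "\n"
        )
        qc_json = {
            "removal_counts": report.removal_counts,
            "n_input": matrix.n_cells,
            "n_kept": int(kept.sum()),
            "gmm_params": report.gmm_params,
            **meta,
        }
        (out / "qc_report.json").write_text(json.dumps(qc_json, indent=2) + "\n")
        manifest["outputs"] += ["kept_cells.txt", "qc_report.json"]

    elif stage == "composition":
        ann = state.get("annotations_qc", state["annotations"])
        table = sample_compositions(ann, level="subpopulation")
        clr = clr_transform(table)
        tests = compare_conditions(clr, table.meta["condition"])
        state.update(composition=table, clr=clr)
        emit("composition.csv", table.counts)
        emit("clr.csv", clr)
        emit("tests.csv", tests)

    elif stage == "score":
        matrix, ann = state["matrix"], state["annotations"]
        kept = state.get("kept_mask", np.ones(matrix.n_cells, dtype=bool))
        lognorm = lognormalize(matrix)[kept]
        gene_ids = matrix.gene_ids
        markers = matrix.marker_sets("subpopulation")
        program_sets = {
            "UPR": sorted(set(markers.get("AR1", []) + markers.get("MH-HSP", []) + markers.get("PDAO", []))),
            "Reactive": sorted(set(markers.get("AR2", []) + markers.get("M1", []))),
        }
        score_df = pd.DataFrame(index=state["annotations_qc"]["cell_id"])
        for i, (name, genes) in enumerate(program_sets.items()):
            msv = module_score(lognorm, gene_ids, genes, seed=stage_seeds["score"] + i)
            score_df[name] = msv.scores.to_numpy()
        labels = label_cells_by_signature(score_df)
        score_df["signature"] = labels.to_numpy()
        enrich = one_vs_rest_enrichment(
            score_df["UPR"].to_numpy(), state["annotations_qc"]["subpopulation"]
        )
        state["scores"] = score_df
        emit("scores.csv", score_df)
        emit("enrichment.csv", enrich)
        dot_genes = sorted(markers.get("AR1", []))[:8]
        dots = expression_dot_summary(
            lognorm, gene_ids, dot_genes, state["annotations_qc"]["subpopulation"]
        )
        emit("dot_summary.csv", dots, index=False)

    elif stage == "deg":
        matrix, ann = state["matrix"], state.get("annotations_qc", state["annotations"])
        kept = state.get("kept_mask", np.ones(matrix.n_cells, dtype=bool))
        lognorm = lognormalize(matrix)[kept]
        # donor groups from the astrocyte rule drive the donor-group contrasts
        astro = sample_compositions(ann, level="subpopulation", within="Astrocyte")
        donor_comp = astro.counts.groupby(level="donor_id").sum()
        assignments = astro_stratify(donor_comp, config.strat_rule)
        donor_group = assignments["label"]
        cell_group = ann["donor_id"].map(donor_group)
        tables = {}
        for cls in ("Astrocyte", "Microglia"):
            cls_mask = (ann["cell_class"] == cls).to_numpy()
            sub = lognorm[cls_mask]
            contrasts = {
                "PDvsCtrl": (ann.loc[cls_mask, "condition"], "PD", "Control"),
                "UPRvsHomeo": (cell_group[cls_mask], "UPR", "Homeostatic"),
                "ReactvsHomeo": (cell_group[cls_mask], "Reactive", "Homeostatic"),
            }
            for cname, (labels, g, ref) in contrasts.items():
                # reciprocal PD-associated donor group excluded entirely
                use = labels.isin([g, ref]).to_numpy()
                table = wilcoxon_de(sub[use], matrix.gene_ids, labels[use], g, ref)
                tables[(cls, cname)] = table
                sig = significant_degs(table, config.tier_thresholds)
                emit(f"deg_{cls}_{cname}.csv", sig)
        for cls in ("Astrocyte", "Microglia"):
            venn = dual_threshold_overlap(
                {c: tables[(cls, c)] for c in ("PDvsCtrl", "UPRvsHomeo", "ReactvsHomeo")},
                config.overlap_spec,
            )
            emit(f"venn_membership_{cls}.csv", venn)
        for cname in ("PDvsCtrl", "UPRvsHomeo", "ReactvsHomeo"):
            upset = cross_celltype_intersections(
                {cls: tables[(cls, cname)] for cls in ("Astrocyte", "Microglia")},
                OverlapSpec(relaxed_lfc=0.25),
            )
            emit(f"upset_counts_{cname}.csv", upset, index=False)
        state["deg_tables"] = tables

    elif stage == "stratify":
        matrix = state["matrix"]
        ann = state.get("annotations_qc", state["annotations"])
        astro = sample_compositions(ann, level="subpopulation", within="Astrocyte")
        assignments = astro_stratify(astro.counts, config.strat_rule)
        assignments = assignments.reset_index()
        emit("assignments.csv", assignments, index=False)
        micro = sample_compositions(ann, level="subpopulation", within="Microglia")
        donor_micro = micro.counts.groupby(level="donor_id").sum()
        totals = donor_micro.sum(axis=1)
        fourway = fourway_stratify(
            donor_micro.get("M1", 0) / totals, donor_micro.get("MH-HSP", 0) / totals
        )
        rate, n_mixed, n_donors = mixed_rate(fourway)
        consistency = cross_region_consistency(assignments)
        emit("fourway.csv", fourway.to_frame())
        emit("consistency.csv", consistency)
        manifest["mixed_rate"] = {"rate": rate, "n_mixed": n_mixed, "n_donors": n_donors}

        kept = state.get("kept_mask", np.ones(matrix.n_cells, dtype=bool))
        lognorm = lognormalize(matrix)[kept]
        pca = PCA(n_components=10, random_state=stage_seeds["stratify"])
        coords = pca.fit_transform(np.asarray(lognorm.todense()))
        samples = ann["donor_id"].astype(str) + "_" + ann["region"].astype(str)
        div = sample_divergence_matrix(
            coords, samples, k=config.divergence_k, min_cells=config.divergence_min_cells
        )
        emit("divergence.csv", div.distances)

    elif stage == "spatial":
        sample_seeds = np.random.SeedSequence(stage_seeds["spatial"]).generate_state(
            config.n_spatial_samples
        ) % (2**31)
        samples = []
        for i in range(config.n_spatial_samples):
            cfg = SpatialConfig(**{**asdict_shallow(config.spatial), "sample_id": f"S{i}"})
            samples.append(generate_spatial_sample(cfg, int(sample_seeds[i])))
        spatial_df = pd.concat([s.to_frame() for s in samples], ignore_index=True)
        emit("spatial_cells.csv", spatial_df, index=False)
        per_sample, agg, top = per_sample_svg(
            samples,
            min_obs=config.spatial_min_obs,
            n_perm=config.spatial_n_perm,
            seed=stage_seeds["spatial"],
        )
        emit("moran_per_sample.csv", per_sample, index=False)
        emit("moran_aggregate.csv", agg, index=False)
        emit("moran_top.csv", top, index=False)

    else:
        raise ValueError(f"unknown stage {stage!r}")


def asdict_shallow(obj) -> dict:
    return {k: getattr(obj, k) for k in obj.__dataclass_fields__}
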