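"""End-to-end pipeline orchestration.

Stages run in dependency order: simulate -> preprocess -> regions ->
neighborhoods -> interactions -> nmf -> predict.  Every stage writes its
outputs into its own subdirectory of the run directory, records SHA-256
hashes in ``MANIFEST.json`` and is skipped on re-run when already complete
(idempotent, resumable).  All stage parameters, including the master seed,
are resolved into ``resolved_config.yaml`` at the start of the run, and a
structured ``run.log`` captures per-stage parameters and timings.

Stage defaults follow the study configuration: 6 µm interaction radius,
20-nearest-neighbour windows, k = 10 neighbourhoods (batch size 1024,
seed 0), region patches of >= 20 cells with 20 µm linkage and 20 µm
expansion, rank-6 NMF, repeated 70/30 random-forest splits.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import interactions as inter_mod
from . import neighbourhoods as cn_mod
from . import nmf as nmf_mod
from . import outcome as out_mod
from . import preprocess as prep_mod
from . import regions as reg_mod
from . import synthetic as syn_mod
from .data_model import CellTable, MarkerPanel, load_cell_table, load_cohort
from .errors import ConfigError

log = logging.getLogger("ecostruct")

STAGES = ("simulate", "preprocess", "regions", "neighborhoods", "interactions", "nmf", "predict")


def _default_params() -> dict:
    return {
        "simulate": {
            "n_subtypes": 4,
            "patients_per_subtype": 10,
            "rois_per_patient": 2,
            "cells_per_roi": 10000.0,
            "roi_size_um": [1000.0, 1000.0],
        },
        "preprocess": {
            "cofactor": 5.0,
            "clip_quantile": 0.999,
            "batch_key": "patient_id",
            "k_neighbors": 30,
            "target_k": 10,
            "similarity_floor": 0.2,
        },
        "regions": {
            "min_cells": 20,
            "max_dist_um": 20.0,
            "margin_um": 20.0,
            "priority": ["epithelial", "immune", "fibrotic"],
            "classes": {
                "epithelial": ["Epithelial"],
                "immune": ["T_cell", "B_cell", "NK_cell", "Myeloid"],
                "fibrotic": ["Fibroblast"],
            },
        },
        "neighborhoods": {"mode": "knn", "param": 20, "k": 10, "batch_size": 1024},
        "interactions": {"radius_um": 6.0, "n_perm": 1000, "alpha": 0.01},
        "nmf": {"k": 6, "k_min": 2, "k_max": 8, "n_restarts": 10,
                "feature_mode": "cell_type_frequency"},
        "predict": {
            "n_repeats": 100,
            "train_frac": 0.7,
            "n_trees": 200,
            "top_k": 5,
            "split_by": "patient",
        },
    }


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration (stage toggles + stage parameters)."""

    out_dir: str = "ecostruct_run"
    seed: int = 0
    cells_path: str | None = None  # external inputs when simulate is off
    cohort_path: str | None = None
    panel_path: str | None = None
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    params: dict = field(default_factory=_default_params)

    def __post_init__(self) -> None:
        defaults = _default_params()
        for stage, dd in defaults.items():
            merged = dict(dd)
            merged.update(self.params.get(stage, {}))
            self.params[stage] = merged
        for s in STAGES:
            self.stages.setdefault(s, True)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")
        if not self.stages["simulate"] and not self.cells_path:
            raise ConfigError("either enable the simulate stage or provide cells_path")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "out_dir": self.out_dir,
            "seed": self.seed,
            "cells_path": self.cells_path,
            "cohort_path": self.cohort_path,
            "panel_path": self.panel_path,
            "stages": dict(self.stages),
            "params": copy.deepcopy(self.params),
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class _Manifest:
    def __init__(self, run_dir: Path):
        self.path = run_dir / "MANIFEST.json"
        self.data = {"completed": [], "files": {}}
        if self.path.exists():
            self.data = json.loads(self.path.read_text())

    def complete(self, stage: str, files: list[Path]) -> None:
        for f in files:
            self.data["files"][str(f.relative_to(self.path.parent))] = _sha256(f)
        if stage not in self.data["completed"]:
            self.data["completed"].append(stage)
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))

    def is_complete(self, stage: str) -> bool:
        return stage in self.data["completed"]


def _seed_for(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the run directory."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(run_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    manifest = _Manifest(run_dir)
    config.to_yaml(run_dir / "resolved_config.yaml")
    try:
        _run_stages(config, run_dir, manifest)
    finally:
        log.removeHandler(fh)
        fh.close()
    return run_dir


def _run_stages(config: PipelineConfig, run_dir: Path, manifest: _Manifest) -> None:
    seed = config.seed
    cells = cohort = truth = None

    def load_inputs() -> tuple[CellTable, object]:
        if config.stages["simulate"]:
            panel = MarkerPanel.from_csv(run_dir / "simulate" / "panel.csv")
            c = load_cell_table(run_dir / "simulate" / "cells.csv", panel)
            m = load_cohort(run_dir / "simulate" / "cohort.csv")
        else:
            panel = (
                MarkerPanel.from_csv(config.panel_path)
                if config.panel_path
                else MarkerPanel.default()
            )
            c = load_cell_table(config.cells_path, panel)
            m = load_cohort(config.cohort_path) if config.cohort_path else None
        return c, m

    # -- simulate ---------------------------------------------------------
    if config.stages["simulate"]:
        out = run_dir / "simulate"
        if manifest.is_complete("simulate") and (out / "cells.csv").exists():
            log.info("simulate: cached")
        else:
            t0 = time.time()
            p = config.params["simulate"]
            sim_cfg = syn_mod.small_config(
                seed=_seed_for(seed, "simulate"),
                cells_per_roi=p["cells_per_roi"],
                n_subtypes=p["n_subtypes"],
                patients_per_subtype=p["patients_per_subtype"],
                rois_per_patient=p["rois_per_patient"],
                roi_size_um=tuple(p["roi_size_um"]),
            )
            log.info("simulate: %s", p)
            cells, cohort, truth = syn_mod.simulate_cohort(sim_cfg)
            out.mkdir(exist_ok=True)
            cells.to_csv(out / "cells.csv")
            cohort.to_csv(out / "cohort.csv")
            truth.to_csv(out / "truth.csv")
            cells.panel.to_csv(out / "panel.csv")
            manifest.complete("simulate", list(out.glob("*.csv")))
            log.info("simulate: %d cells in %.1fs", len(cells), time.time() - t0)

    # -- preprocess -------------------------------------------------------
    prep_out = run_dir / "preprocess"
    if config.stages["preprocess"]:
        if manifest.is_complete("preprocess") and (prep_out / "cells.csv").exists():
            log.info("preprocess: cached")
        else:
            t0 = time.time()
            p = config.params["preprocess"]
            raw_cells, cohort = load_inputs()
            cells = prep_mod.transform_intensities(
                raw_cells, cofactor=p["cofactor"], clip_quantile=p["clip_quantile"]
            )
            cells = prep_mod.correct_batches(cells, batch_key=p["batch_key"])
            cells = prep_mod.assign_phenotypes(
                cells,
                syn_mod.signature_table(),
                k_neighbors=p["k_neighbors"],
                target_k=p["target_k"],
                seed=_seed_for(seed, "cluster"),
                similarity_floor=p["similarity_floor"],
            )
            prep_out.mkdir(exist_ok=True)
            cells.to_csv(prep_out / "cells.csv")
            manifest.complete("preprocess", [prep_out / "cells.csv"])
            log.info("preprocess: done in %.1fs", time.time() - t0)

    def load_prep() -> CellTable:
        panel = (
            MarkerPanel.from_csv(run_dir / "simulate" / "panel.csv")
            if config.stages["simulate"]
            else (MarkerPanel.from_csv(config.panel_path) if config.panel_path
                  else MarkerPanel.default())
        )
        df = pd.read_csv(prep_out / "cells.csv")
        return CellTable(df, panel, raw=False)

    def load_meta():
        if config.stages["simulate"]:
            return load_cohort(run_dir / "simulate" / "cohort.csv")
        return load_cohort(config.cohort_path) if config.cohort_path else None

    # -- regions ----------------------------------------------------------
    if config.stages["regions"]:
        out = run_dir / "regions"
        if manifest.is_complete("regions") and (out / "patches.csv").exists():
            log.info("regions: cached")
        else:
            t0 = time.time()
            p = config.params["regions"]
            cells = load_prep()
            patches = []
            for cls, phens in p["classes"].items():
                mask = reg_mod.positivity_from_labels(cells, phens)
                patches.extend(
                    reg_mod.detect_patches(
                        cells, mask, cls,
                        min_cells=p["min_cells"], max_dist_um=p["max_dist_um"],
                    )
                )
            cells = reg_mod.expand_and_assign(
                patches, cells, margin_um=p["margin_um"], priority=tuple(p["priority"])
            )
            cohort = load_meta()
            out.mkdir(exist_ok=True)
            if cohort is not None:
                joined = cells.with_columns(
                    subtype=cells.df["patient_id"].map(cohort.subtype_of())
                )
                freq, tests = reg_mod.region_composition(joined, "subtype")
                freq.to_csv(out / "composition.csv", index=False)
                tests.to_csv(out / "composition_tests.csv", index=False)
            cells.df[["roi_id", "cell_id", "region", "region_overlap"]].to_csv(
                out / "cell_regions.csv", index=False
            )
            pd.DataFrame(
                [
                    {
                        "patch_id": pa.patch_id,
                        "roi_id": pa.roi_id,
                        "region_class": pa.region_class,
                        "n_cells": pa.n_cells,
                    }
                    for pa in patches
                ]
            ).to_csv(out / "patches.csv", index=False)
            manifest.complete("regions", list(out.glob("*.csv")))
            log.info("regions: %d patches in %.1fs", len(patches), time.time() - t0)

    # -- neighborhoods ----------------------------------------------------
    if config.stages["neighborhoods"]:
        out = run_dir / "neighborhoods"
        if manifest.is_complete("neighborhoods") and (out / "cn_labels.csv").exists():
            log.info("neighborhoods: cached")
        else:
            t0 = time.time()
            p = config.params["neighborhoods"]
            cells = load_prep()
            win = cn_mod.build_windows(cells, mode=p["mode"], param=p["param"])
            labels = cn_mod.cluster_windows(
                win, k=p["k"], batch_size=p["batch_size"], seed=_seed_for(seed, "cn")
            )
            cohort = load_meta()
            grouping = None
            if cohort is not None:
                sub = cohort.subtype_of()
                grouping = {
                    roi: sub.get(pat)
                    for roi, pat in cells.df.groupby("roi_id")["patient_id"].first().items()
                }
            res = cn_mod.cn_prevalence_and_enrichment(
                labels, win, cells.df["roi_id"].to_numpy(), grouping=grouping
            )
            out.mkdir(exist_ok=True)
            pd.DataFrame(
                {"roi_id": cells.df["roi_id"], "cell_id": cells.df["cell_id"], "cn": labels}
            ).to_csv(out / "cn_labels.csv", index=False)
            res.prevalence.rename_axis("core").to_csv(out / "cn_prevalence.csv")
            res.prevalence_z.rename_axis("core").to_csv(out / "cn_prevalence_z.csv")
            res.enrichment.rename_axis("cn").to_csv(out / "cn_enrichment.csv")
            if res.group_tests is not None:
                res.group_tests.to_csv(out / "cn_group_tests.csv", index=False)
            manifest.complete("neighborhoods", list(out.glob("*.csv")))
            log.info("neighborhoods: done in %.1fs", time.time() - t0)

    # -- interactions -----------------------------------------------------
    if config.stages["interactions"]:
        out = run_dir / "interactions"
        if manifest.is_complete("interactions") and (out / "interactions.csv").exists():
            log.info("interactions: cached")
        else:
            t0 = time.time()
            p = config.params["interactions"]
            cells = load_prep()
            res = inter_mod.permutation_test(
                cells,
                radius_um=p["radius_um"],
                n_perm=p["n_perm"],
                alpha=p["alpha"],
                seed=_seed_for(seed, "interactions"),
            )
            out.mkdir(exist_ok=True)
            res.table.to_csv(out / "interactions.csv", index=False)
            res.undefined.to_csv(out / "undefined_pairs.csv", index=False)
            cohort = load_meta()
            comps = []
            if cohort is not None:
                sub = cohort.subtype_of()
                grouping = {
                    roi: sub.get(pat)
                    for roi, pat in cells.df.groupby("roi_id")["patient_id"].first().items()
                }
                names = sorted(set(grouping.values()))
                for i in range(len(names)):
                    for j in range(i + 1, len(names)):
                        c = inter_mod.compare_groups(res, grouping, names[i], names[j])
                        c.insert(0, "group_a_name", names[i])
                        c.insert(1, "group_b_name", names[j])
                        comps.append(c)
            if comps:
                pd.concat(comps, ignore_index=True).to_csv(out / "comparisons.csv", index=False)
            manifest.complete("interactions", list(out.glob("*.csv")))
            log.info("interactions: done in %.1fs", time.time() - t0)

    # -- nmf ---------------------------------------------------------------
    if config.stages["nmf"]:
        out = run_dir / "nmf"
        if manifest.is_complete("nmf") and (out / "W.csv").exists():
            log.info("nmf: cached")
        else:
            t0 = time.time()
            p = config.params["nmf"]
            cells = load_prep()
            V = nmf_mod.build_composition(cells, feature_mode=p["feature_mode"])
            sel = nmf_mod.select_rank(
                V,
                range(p["k_min"], min(p["k_max"], min(V.V.shape) - 1) + 1),
                n_restarts=p["n_restarts"],
                seed=_seed_for(seed, "nmf_rank"),
            )
            model = nmf_mod.nmf_fit(V, p["k"], seed=_seed_for(seed, "nmf"))
            out.mkdir(exist_ok=True)
            pd.DataFrame(
                model.W,
                index=model.features,
                columns=[f"NMF{i + 1}" for i in range(model.k)],
            ).rename_axis("feature").to_csv(out / "W.csv")
            pd.DataFrame(
                model.H,
                index=[f"NMF{i + 1}" for i in range(model.k)],
                columns=model.samples,
            ).rename_axis("program").to_csv(out / "H.csv")
            sel.diagnostics.assign(chosen_k=sel.chosen_k, stable=sel.stable).to_csv(
                out / "rank_diagnostics.csv", index=False
            )
            cohort = load_meta()
            if cohort is not None:
                sub = cohort.subtype_of()
                grouping = {
                    roi: sub.get(pat)
                    for roi, pat in cells.df.groupby("roi_id")["patient_id"].first().items()
                }
                nmf_mod.program_activity_compare(model, grouping).to_csv(
                    out / "program_tests.csv", index=False
                )
            manifest.complete("nmf", list(out.glob("*.csv")))
            log.info("nmf: rank %d chosen, fit k=%d in %.1fs",
                     sel.chosen_k, model.k, time.time() - t0)

    # -- predict -----------------------------------------------------------
    if config.stages["predict"]:
        out = run_dir / "predict"
        if manifest.is_complete("predict") and (out / "importance_subtype.csv").exists():
            log.info("predict: cached")
        else:
            t0 = time.time()
            p = config.params["predict"]
            cells = load_prep()
            cohort = load_meta()
            if cohort is None:
                raise ConfigError("predict stage needs cohort metadata")
            itab = pd.read_csv(run_dir / "interactions" / "interactions.csv")
            feats = out_mod.build_features(cells, itab)
            meta = cohort.df.set_index("patient_id")
            out.mkdir(exist_ok=True)
            feats.X.rename_axis("roi_id").to_csv(out / "features.csv")
            rf_kwargs = dict(
                n_repeats=p["n_repeats"],
                train_frac=p["train_frac"],
                n_trees=p["n_trees"],
                split_by=p["split_by"],
            )
            auc_rows = []
            for label_name in ("subtype", "recurrence"):
                labels = feats.patients.map(meta[label_name]).astype(str)
                labels.index = feats.X.index
                imp = out_mod.repeated_rf(
                    feats, labels, seed=_seed_for(seed, f"rf_{label_name}"), **rf_kwargs
                )
                top = out_mod.topk_model(
                    feats, labels, imp, k=p["top_k"],
                    n_repeats=p["n_repeats"],
                    seed=_seed_for(seed, f"rf_top_{label_name}"),
                    train_frac=p["train_frac"], n_trees=p["n_trees"],
                    split_by=p["split_by"],
                )
                imp.importance.to_csv(out / f"importance_{label_name}.csv", index=False)
                auc_rows.append(
                    {
                        "label": label_name,
                        "mean_auc_full": imp.mean_auc,
                        "pooled_auc_full": imp.pooled_auc,
                        "mean_auc_top": top.mean_auc,
                        "top_features": ";".join(top.selected),
                    }
                )
            pd.DataFrame(auc_rows).to_csv(out / "auc.csv", index=False)
            # survival contrast between recurrence groups
            rec = cohort.df.rename(columns={"pfs_months": "time"})
            if {"time", "event", "recurrence"} <= set(rec.columns):
                km = out_mod.km_logrank(
                    rec.assign(group=rec["recurrence"].map({0: "good", 1: "recurrence"})),
                )
                pd.concat(
                    [c.assign(group=g) for g, c in km.curves.items()], ignore_index=True
                ).to_csv(out / "km.csv", index=False)
                pd.DataFrame(
                    [{"statistic": km.statistic, "p": km.p_value}]
                ).to_csv(out / "logrank.csv", index=False)
            manifest.complete("predict", list(out.glob("*.csv")))
            log.info("predict: done in %.1fs", time.time() - t0)


def report(run_dir) -> dict:
    """Summarise a completed run from its MANIFEST and key outputs."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "MANIFEST.json").read_text())
    summary = {"completed": manifest["completed"], "n_files": len(manifest["files"])}
    auc = run_dir / "predict" / "auc.csv"
    if auc.exists():
        summary["auc"] = pd.read_csv(auc).to_dict(orient="records")
    diag = run_dir / "nmf" / "rank_diagnostics.csv"
    if diag.exists():
        d = pd.read_csv(diag)
        summary["nmf_chosen_k"] = int(d["chosen_k"].iloc[0])
    return summary
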