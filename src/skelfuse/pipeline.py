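"""End-to-end orchestration: simulate -> infer -> classify -> concord -> fuse.

A single global seed deterministically derives an independent substream for
every stage (stable stage-name hashing), so re-running with the same config
and seed reproduces every number, while stages never share a random stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classification import (
    HyperparamGrid,
    evaluate_phase2,
    extract_weight_map,
    nested_cv_phase1,
)
from .concordance import concordance_table
from .data_model import CohortDataset
from .inference import TFCEParams, extract_clusters, permutation_fwe
from .mcca import (
    MultiViewCCA,
    component_group_test,
    prepare_views,
    spatial_maps,
)
from .simulate import SimConfig, generate_cohort

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclasses.dataclass
class RunConfig:
    """Configuration of one full pipeline run (YAML-serializable)."""

    out_dir: str = "skelfuse_run"
    cohort_dir: str | None = None  # None -> simulate
    seed: int = 0
    sim: dict[str, Any] = dataclasses.field(default_factory=dict)
    tfce: dict[str, Any] = dataclasses.field(default_factory=dict)
    n_perm: int = 200
    alpha: float = 0.05
    infer_metrics: list[str] | None = None  # None -> all
    anchor_metric: str = "dti_fa"
    grid: dict[str, Any] = dataclasses.field(default_factory=dict)
    cca_views: list[str] | None = None
    cca_reg_grid: list[float] | None = None
    cca_D_grid: list[int] = dataclasses.field(
        default_factory=lambda: [1, 2, 3, 4, 5]
    )
    stages: list[str] = dataclasses.field(
        default_factory=lambda: ["simulate", "infer", "classify", "concord", "fuse"]
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _write_manifest(path: Path, payload: dict[str, Any]) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=str))


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the configured stages; returns a manifest dict (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / ".partial"
    marker.touch()
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    try:
        dataset = _stage_data(config, out, manifest)
        results: dict[str, Any] = {}
        if "infer" in config.stages:
            results["inference"] = _stage_infer(config, out, dataset, manifest)
        if "classify" in config.stages:
            results["classification"] = _stage_classify(
                config, out, dataset, manifest
            )
        if "concord" in config.stages:
            results["concordance"] = _stage_concord(
                config, out, dataset, results, manifest
            )
        if "fuse" in config.stages:
            results["fusion"] = _stage_fuse(config, out, dataset, manifest)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-named rethrow
        raise StageError("unknown", exc) from exc
    _write_manifest(out / "manifest.json", manifest)
    marker.unlink(missing_ok=True)
    return manifest


def _stage_data(config: RunConfig, out: Path, manifest: dict) -> CohortDataset:
    try:
        if config.cohort_dir is not None:
            dataset = CohortDataset.load(config.cohort_dir)
            manifest["stages"]["data"] = {"source": str(config.cohort_dir)}
        elif "simulate" in config.stages:
            sim_kwargs = dict(config.sim)
            sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
            if "grid_shape" in sim_kwargs:
                sim_kwargs["grid_shape"] = tuple(sim_kwargs["grid_shape"])
            if "metric_names" in sim_kwargs:
                sim_kwargs["metric_names"] = tuple(sim_kwargs["metric_names"])
            if "latent_views" in sim_kwargs:
                sim_kwargs["latent_views"] = tuple(sim_kwargs["latent_views"])
            cfg = SimConfig(**sim_kwargs)
            dataset = generate_cohort(cfg)
            dataset.save(out / "cohort")
            manifest["stages"]["simulate"] = {
                "seed": cfg.seed,
                "n_subjects": dataset.n_subjects,
                "n_voxels": dataset.mask.n_voxels,
                "metrics": dataset.metric_names,
            }
            logger.info(
                "simulate: N=%d M=%d metrics=%d",
                dataset.n_subjects, dataset.mask.n_voxels,
                len(dataset.metric_names),
            )
        else:
            raise ValueError("no cohort_dir given and 'simulate' not enabled")
        return dataset
    except Exception as exc:
        raise StageError("simulate", exc) from exc


def _stage_infer(
    config: RunConfig, out: Path, dataset: CohortDataset, manifest: dict
) -> dict[str, Any]:
    try:
        metrics = config.infer_metrics or dataset.metric_names
        params = TFCEParams(**config.tfce)
        infer_dir = out / "inference"
        results = {}
        for metric in metrics:
            res = permutation_fwe(
                dataset,
                metric,
                direction="A<B",
                params=params,
                n_perm=config.n_perm,
                seed=stage_seed(config.seed, f"infer:{metric}"),
            )
            clusters = extract_clusters(
                res, dataset.mask, config.alpha, params.connectivity
            )
            mdir = infer_dir / metric
            mdir.mkdir(parents=True, exist_ok=True)
            dataset.mask.save_map(res.t_map, mdir / "t.nii.gz")
            dataset.mask.save_map(res.tfce_map, mdir / "tfce.nii.gz")
            dataset.mask.save_map(1.0 - res.p_corr, mdir / "one_minus_p.nii.gz")
            pd.DataFrame(
                {
                    "cluster_size_voxels": [c.size for c in clusters],
                    "peak_value": [c.peak_value for c in clusters],
                    "max_location": [str(c.peak_location) for c in clusters],
                    "corrected_p": [c.p_value for c in clusters],
                }
            ).to_csv(mdir / "clusters.tsv", sep="\t", index=False)
            results[metric] = res
            manifest["stages"].setdefault("infer", {})[metric] = {
                "n_perm": res.n_perm,
                "min_p_corr": float(res.p_corr.min()),
                "n_significant": int((res.p_corr < config.alpha).sum()),
                "n_clusters": len(clusters),
            }
            logger.info(
                "infer %s: %d significant voxels, %d clusters",
                metric, int((res.p_corr < config.alpha).sum()), len(clusters),
            )
        return results
    except Exception as exc:
        raise StageError("infer", exc) from exc


def _stage_classify(
    config: RunConfig, out: Path, dataset: CohortDataset, manifest: dict
) -> dict[str, Any]:
    try:
        cdir = out / "classification"
        cdir.mkdir(parents=True, exist_ok=True)
        grid = HyperparamGrid(
            **{k: tuple(v) for k, v in config.grid.items()}
        ) if config.grid else HyperparamGrid()
        anchor = config.anchor_metric
        phase1 = nested_cv_phase1(
            dataset, anchor, grid=grid,
            seed=stage_seed(config.seed, "classify:phase1"),
        )
        consensus = phase1.consensus_params
        reports = {anchor: phase1}
        for metric in dataset.metric_names:
            if metric == anchor:
                continue
            reports[metric] = evaluate_phase2(
                dataset, metric, consensus,
                seed=stage_seed(config.seed, f"classify:phase2:{metric}"),
            )
        rows = []
        for metric, rep in reports.items():
            row: dict[str, Any] = {"metric": metric}
            for s, v in rep.mean_scores.items():
                row[f"{s}_mean_pct"] = 100.0 * v
                row[f"{s}_sd_pct"] = 100.0 * rep.sd_scores[s]
            rows.append(row)
        pd.DataFrame(rows).to_csv(cdir / "scores.tsv", sep="\t", index=False)
        payload = {
            "anchor_metric": anchor,
            "consensus_params": list(consensus),
            "per_metric": {
                m: {
                    "mean_scores": r.mean_scores,
                    "sd_scores": r.sd_scores,
                    "per_fold_params": [list(f.chosen_params) for f in r.folds],
                }
                for m, r in reports.items()
            },
        }
        (cdir / "report.json").write_text(json.dumps(payload, indent=1))
        weight_maps = {}
        for metric, rep in reports.items():
            if rep.weight_map is not None:
                weight_maps[metric] = rep.weight_map
                dataset.mask.save_map(
                    rep.weight_map, cdir / f"weight_{metric}.nii.gz"
                )
        manifest["stages"]["classify"] = {
            "anchor": anchor,
            "consensus_params": list(consensus),
            "mean_scores": phase1.mean_scores,
        }
        logger.info(
            "classify: consensus=%s anchor accuracy=%.3f",
            consensus, phase1.mean_scores["accuracy"],
        )
        return {"reports": reports, "weight_maps": weight_maps}
    except Exception as exc:
        raise StageError("classify", exc) from exc


def _stage_concord(
    config: RunConfig,
    out: Path,
    dataset: CohortDataset,
    results: dict,
    manifest: dict,
) -> Any:
    try:
        weight_maps = results.get("classification", {}).get("weight_maps", {})
        p_maps = {
            m: res.p_corr for m, res in results.get("inference", {}).items()
        }
        records, frame = concordance_table(weight_maps, p_maps)
        codir = out / "concordance"
        codir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(codir / "concordance.tsv", sep="\t", index=False)
        frame.to_json(codir / "concordance.json", orient="records", indent=1)
        manifest["stages"]["concord"] = {
            "n_metrics": len(records),
            "pearson_r": {r.metric: r.pearson_r for r in records},
        }
        return records
    except Exception as exc:
        raise StageError("concord", exc) from exc


def _stage_fuse(
    config: RunConfig, out: Path, dataset: CohortDataset, manifest: dict
) -> dict[str, Any]:
    try:
        views = prepare_views(dataset, config.cca_views)
        est = MultiViewCCA(
            reg_grid=config.cca_reg_grid,
            D_grid=tuple(config.cca_D_grid),
            random_state=stage_seed(config.seed, "fuse"),
        )
        est.fit(views)
        report = component_group_test(
            est.model_, dataset.labels, alpha=config.alpha
        )
        fdir = out / "fusion"
        fdir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "component": t.component,
                "view": t.view,
                "U": t.U,
                "p_raw": t.p_raw,
                "p_adj": t.p_adj,
                "n": t.n_after_outlier_removal,
                "significant": t.significant,
            }
            for t in report.tests
        ]
        pd.DataFrame(rows).to_csv(fdir / "tests.tsv", sep="\t", index=False)
        payload = {
            "reg": est.reg_,
            "D": est.D_,
            "ccc": est.ccc_.tolist(),
            "component_labels": report.labels,
            "tests": rows,
        }
        (fdir / "report.json").write_text(json.dumps(payload, indent=1))
        for d, label in report.labels.items():
            if label == "none":
                continue
            zmaps = spatial_maps(est.model_, views, d)
            for view, z in zmaps.items():
                full = np.zeros(dataset.mask.n_voxels)
                # prepare_views may have dropped constant features
                sd = dataset.metrics[view].std(axis=0, ddof=0)
                full[sd > 0] = z
                dataset.mask.save_map(
                    full, fdir / f"zmap_c{d}_{view}.nii.gz"
                )
        manifest["stages"]["fuse"] = {
            "reg": est.reg_,
            "D": est.D_,
            "component_labels": report.labels,
        }
        logger.info(
            "fuse: c*=%.4g D*=%d labels=%s", est.reg_, est.D_, report.labels
        )
        return {"model": est.model_, "report": report}
    except Exception as exc:
        raise StageError("fuse", exc) from exc
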