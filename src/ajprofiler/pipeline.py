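"""End-to-end pipeline orchestration from a structured YAML config.

Stages: QC -> illumination correction -> segmentation -> ROI sampling ->
(optional CNN training) -> embedding -> profiling -> statistics.  Every
stage writes its artifacts under the output directory and is skipped on
re-run when its outputs already exist (unless forced), so a run can resume.
One global seed is expanded into per-stage sub-seeds by a fixed counter
scheme: adding a stage never perturbs the randomness of the others.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import preprocess, profiling, roi, segmentation, stats, synthgen
from .model import ModelConfig, MorphologyCNN, build_model
from .model import embed as model_embed
from .model import train as model_train
from .utils import stage_seed

log = logging.getLogger("ajprofiler")

STAGES = ("qc", "correct", "segment", "sample", "train", "embed", "profile", "stats")


@dataclass
class PipelineConfig:
    manifest: str = "manifest.csv"
    outdir: str = "out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # outlier thresholds are deliberately opt-in: the reference protocol used
    # visual inspection, and robust-z cutoffs are unstable on few images
    qc: dict = field(default_factory=lambda: {"thresholds": {}})
    correct: dict = field(
        default_factory=lambda: {
            "local_window": 33, "sd_mult": 3.0, "smooth_sigma": 64.0, "max_iter": 10
        }
    )
    segment: dict = field(default_factory=lambda: {"min_nucleus_area": 80, "gradient": "morph"})
    roi: dict = field(default_factory=lambda: {"n_per_well": 200, "size": 64, "min_spacing": 8})
    train: dict = field(
        default_factory=lambda: {
            "enabled": True, "n_per_class": 100, "val_per_class": 30,
            "max_epochs": 5, "batch_size": 64, "learning_rate": 1e-4,
        }
    )
    model_path: str | None = None
    profile: dict = field(
        default_factory=lambda: {
            "fit_size": 10000, "n_neighbors": 30, "min_dist": 0.0,
            "min_cluster_size": None, "min_samples": None
        }
    )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key {k!r}")
            cur = getattr(cfg, k)
            if isinstance(cur, dict) and isinstance(v, dict):
                cur.update(v)
            else:
                setattr(cfg, k, v)
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def validate_config(config: PipelineConfig, check_paths: bool = True) -> list[str]:
    """Return a list of problems (empty iff the config is runnable)."""
    problems = []
    if check_paths and not os.path.exists(config.manifest):
        problems.append(f"manifest: file not found: {config.manifest}")
    if config.roi.get("size", 64) % 2:
        problems.append("roi.size: must be even")
    if config.roi.get("n_per_well", 0) < 0:
        problems.append("roi.n_per_well: must be >= 0")
    if config.train.get("learning_rate", 1e-4) <= 0:
        problems.append("train.learning_rate: must be > 0")
    if config.train.get("batch_size", 64) < 1:
        problems.append("train.batch_size: must be >= 1")
    if config.train.get("max_epochs", 1) < 1:
        problems.append("train.max_epochs: must be >= 1")
    if not config.train.get("enabled", True) and not config.model_path:
        problems.append("model_path: required when train.enabled is false")
    if config.profile.get("fit_size", 0) < 100:
        problems.append("profile.fit_size: must be >= 100")
    for s in config.stages:
        if s not in STAGES:
            problems.append(f"stages.{s}: unknown stage")
    return problems


def _done(path: str) -> bool:
    return os.path.exists(path)


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Execute all enabled stages; return (and write) the JSON run report."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = config.outdir
    os.makedirs(out, exist_ok=True)
    report: dict = {"stages": {}, "discarded_sites": [], "seed": config.seed}

    manifest = pd.read_csv(config.manifest)
    required = {"plate", "well", "site", "condition", "nuclei_path", "junction_path"}
    missing_cols = required - set(manifest.columns)
    if missing_cols:
        raise ValueError(f"manifest missing columns: {sorted(missing_cols)}")
    manifest = manifest.sort_values(["plate", "well", "site"]).reset_index(drop=True)

    # drop sites with a missing channel file
    keep = []
    for _, row in manifest.iterrows():
        ok = os.path.exists(row.nuclei_path) and os.path.exists(row.junction_path)
        if not ok:
            report["discarded_sites"].append(
                {"plate": row.plate, "well": row.well, "site": row.site, "reason": "missing_channel_file"}
            )
            log.warning("site %s/%s/%s dropped: missing channel file", row.plate, row.well, row.site)
        keep.append(ok)
    manifest = manifest[keep].reset_index(drop=True)
    report["stages"]["manifest"] = {"n_sites": len(manifest)}

    # ---- QC --------------------------------------------------------------
    qc_csv = os.path.join(out, "qc.csv")
    if config.stages.get("qc", True) and (force or not _done(qc_csv)):
        rows, metrics_by_channel = [], {"nuclei": [], "junction": []}
        for _, row in manifest.iterrows():
            for channel, path in (("nuclei", row.nuclei_path), ("junction", row.junction_path)):
                m = preprocess.compute_qc_metrics(tifffile.imread(path))
                metrics_by_channel[channel].append(m)
                rows.append({"plate": row.plate, "well": row.well, "site": row.site, "channel": channel, **m.as_dict()})
        for channel, ms in metrics_by_channel.items():
            preprocess.flag_outliers(ms, config.qc.get("thresholds"))
        flat = metrics_by_channel["nuclei"] + metrics_by_channel["junction"]
        site_ids = [(r.plate, r.well, r.site) for _, r in manifest.iterrows()] * 2
        site_flags = preprocess.propagate_site_flags([m.outlier_flag for m in flat], site_ids)
        qc_df = pd.DataFrame(rows)
        qc_df["outlier_flag"] = [m.outlier_flag for m in flat]
        qc_df["reason"] = [m.reason for m in flat]
        qc_df["site_discarded"] = site_flags
        qc_df.to_csv(qc_csv, index=False)
    qc_df = pd.read_csv(qc_csv) if os.path.exists(qc_csv) else None
    if qc_df is not None and config.stages.get("qc", True):
        bad = qc_df[qc_df.site_discarded][["plate", "well", "site"]].drop_duplicates()
        for _, b in bad.iterrows():
            report["discarded_sites"].append(
                {"plate": b.plate, "well": b.well, "site": b.site, "reason": "qc_outlier"}
            )
        bad_keys = {tuple(x) for x in bad.to_numpy()}
        manifest = manifest[
            [ (r.plate, r.well, r.site) not in bad_keys for _, r in manifest.iterrows() ]
        ].reset_index(drop=True)
    report["stages"]["qc"] = {"n_sites_pass": len(manifest)}

    # ---- illumination correction ----------------------------------------
    corr_dir = os.path.join(out, "corrected")
    os.makedirs(corr_dir, exist_ok=True)
    corrected_paths: dict[tuple, dict[str, str]] = {}
    do_correct = config.stages.get("correct", True)
    marker = os.path.join(corr_dir, ".done")
    if do_correct and (force or not _done(marker)):
        for (plate, channel), group in _by_plate_channel(manifest):
            imgs = [tifffile.imread(p) for p in group["path"]]
            if len(imgs) >= 3:
                corr = preprocess.estimate_illumination(
                    imgs,
                    local_window=config.correct["local_window"],
                    sd_mult=config.correct["sd_mult"],
                    smooth_sigma=config.correct["smooth_sigma"],
                    max_iter=config.correct["max_iter"],
                    channel=channel,
                    plate=str(plate),
                )
                tifffile.imwrite(
                    os.path.join(corr_dir, f"{plate}_{channel}_field.tif"),
                    corr.field.astype(np.float32),
                )
            else:
                corr = preprocess.CorrectionImage(np.ones_like(imgs[0], dtype=np.float64))
            for path, img in zip(group["path"], imgs):
                fixed = preprocess.correct_illumination(img, corr)
                tifffile.imwrite(_corrected_path(corr_dir, path), fixed)
        open(marker, "w").close()
    if do_correct:
        get_img = lambda p: tifffile.imread(_corrected_path(corr_dir, p))
    else:
        get_img = lambda p: tifffile.imread(p)
    report["stages"]["correct"] = {"enabled": do_correct}

    # ---- segmentation ----------------------------------------------------
    seg_dir = os.path.join(out, "segmentation")
    os.makedirs(seg_dir, exist_ok=True)
    border_coords: dict[tuple, np.ndarray] = {}
    seg_counts = []
    half = config.roi.get("size", 64) // 2
    for _, row in manifest.iterrows():
        key = (row.plate, row.well, row.site)
        stem = os.path.join(seg_dir, f"{row.plate}_{row.well}_{row.site}")
        if config.stages.get("segment", True) and (force or not _done(stem + "_cells.tif")):
            nuclei = segmentation.segment_nuclei(
                segmentation.normalize_quantile(get_img(row.nuclei_path)),
                min_area=config.segment["min_nucleus_area"],
            )
            if nuclei.max() == 0:
                report["discarded_sites"].append(
                    {"plate": row.plate, "well": row.well, "site": row.site, "reason": "no_nuclei"}
                )
                continue
            res = segmentation.segment_cells(
                segmentation.normalize_quantile(get_img(row.junction_path)),
                nuclei,
                gradient=config.segment["gradient"],
                provenance={"plate": row.plate, "well": row.well, "site": row.site},
            )
            tifffile.imwrite(stem + "_nuclei.tif", res.nucleus_labels.astype(np.uint16))
            tifffile.imwrite(stem + "_cells.tif", res.cell_labels.astype(np.uint16))
            tifffile.imwrite(stem + "_border.tif", res.border_mask.astype(np.uint8))
            from scipy import ndimage as _ndi

            labs = np.unique(nuclei[nuclei > 0])
            coms = _ndi.center_of_mass(nuclei > 0, nuclei, labs) if len(labs) else []
            pd.DataFrame(
                {
                    "label": labs,
                    "centroid_row": [c[0] for c in coms],
                    "centroid_col": [c[1] for c in coms],
                    "area_px": [(nuclei == l).sum() for l in labs],
                }
            ).to_csv(stem + "_nuclei.csv", index=False)
        if _done(stem + "_cells.tif"):
            cells = tifffile.imread(stem + "_cells.tif").astype(np.int32)
            border = tifffile.imread(stem + "_border.tif").astype(bool)
            res = segmentation.SegmentationResult(cells, cells, border)
            border_coords[key] = segmentation.border_pixels(res, margin=half)
            seg_counts.append({"plate": row.plate, "well": row.well, "site": row.site,
                               "n_cells": res.n_cells, "n_border_px": len(border_coords[key])})
    pd.DataFrame(seg_counts).to_csv(os.path.join(seg_dir, "summary.csv"), index=False)
    report["stages"]["segment"] = {"n_sites": len(border_coords)}

    # ---- ROI sampling ----------------------------------------------------
    roi_dir = os.path.join(out, "rois")
    os.makedirs(roi_dir, exist_ok=True)
    wells = manifest.groupby(["plate", "well"], sort=True)
    well_rois: dict[tuple, roi.ROISet] = {}
    n_per_well = config.roi.get("n_per_well", 200)
    for wi, ((plate, well), group) in enumerate(wells):
        prefix = os.path.join(roi_dir, f"{plate}_{well}")
        sites = [r for _, r in group.iterrows() if (r.plate, r.well, r.site) in border_coords]
        if not sites:
            continue
        if config.stages.get("sample", True) and (force or not _done(prefix + ".tif")):
            quotas = roi.per_image_quota(n_per_well, len(sites))
            parts = []
            for q, row in zip(quotas, sites):
                if q == 0:
                    continue
                img = segmentation.normalize_quantile(get_img(row.junction_path))
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    parts.append(
                        roi.sample_rois(
                            img,
                            border_coords[(row.plate, row.well, row.site)],
                            q,
                            size=config.roi["size"],
                            min_spacing=config.roi["min_spacing"],
                            seed=stage_seed(config.seed, 40 + wi),
                            meta={"plate": row.plate, "well": row.well, "site": row.site,
                                  "condition": row.condition},
                        )
                    )
            rs = roi.ROISet.concat(parts)
            rs.save(prefix)
        if _done(prefix + ".tif"):
            well_rois[(plate, well)] = roi.ROISet.load(prefix)
    report["stages"]["sample"] = {"n_wells": len(well_rois),
                                  "n_rois": int(sum(len(r) for r in well_rois.values()))}

    # ---- model -----------------------------------------------------------
    model_file = os.path.join(out, "model")
    model = None
    if config.model_path:
        model = MorphologyCNN.load(config.model_path)
    elif config.stages.get("train", True) and (force or not _done(model_file + ".npz")):
        tcfg = config.train
        n_tr, n_va = tcfg.get("n_per_class", 100), tcfg.get("val_per_class", 30)
        train_set = synthgen.make_training_set(
            n_tr + n_va, synthgen.SynthConfig(seed=stage_seed(config.seed, 50))
        )
        rng = np.random.default_rng(stage_seed(config.seed, 51))
        idx = rng.permutation(len(train_set))
        n_val_total = n_va * 5
        va, tr = train_set.subset(idx[:n_val_total]), train_set.subset(idx[n_val_total:])
        mcfg = ModelConfig(
            max_epochs=tcfg.get("max_epochs", 5),
            batch_size=tcfg.get("batch_size", 64),
            learning_rate=tcfg.get("learning_rate", 1e-4),
            patience=tcfg.get("patience"),
            target_val_acc=tcfg.get("target_val_acc"),
            seed=stage_seed(config.seed, 52),
        )
        model = build_model(mcfg)
        model, hist = model_train(model, tr, va, mcfg)
        hist.to_csv(os.path.join(out, "training_history.csv"), index=False)
        model.save(model_file)
    elif _done(model_file + ".npz"):
        model = MorphologyCNN.load(model_file)
    if model is None and config.stages.get("embed", True) and well_rois:
        raise ValueError("no trained model available and training is disabled")
    if model is not None:
        report["stages"]["train"] = {"n_parameters": model.n_parameters()}

    # ---- embeddings ------------------------------------------------------
    emb_dir = os.path.join(out, "embeddings")
    os.makedirs(emb_dir, exist_ok=True)
    well_emb: dict[tuple, np.ndarray] = {}
    for (plate, well), rs in sorted(well_rois.items()):
        path = os.path.join(emb_dir, f"{plate}_{well}.npz")
        if config.stages.get("embed", True) and model is not None and (force or not _done(path)):
            np.savez_compressed(path, embeddings=model_embed(model, rs).astype(np.float32))
        if _done(path):
            well_emb[(plate, well)] = np.load(path)["embeddings"]
    report["stages"]["embed"] = {"n_wells": len(well_emb)}

    # ---- profiling -------------------------------------------------------
    prof_csv = os.path.join(out, "profiles.csv")
    bundle_path = os.path.join(out, "reducer_bundle.pkl")
    if config.stages.get("profile", True) and well_emb and (force or not _done(prof_csv)):
        pool = np.concatenate([well_emb[k] for k in sorted(well_emb)])
        fit_size = min(config.profile["fit_size"], len(pool))
        rng = np.random.default_rng(stage_seed(config.seed, 60))
        sel = rng.choice(len(pool), size=fit_size, replace=False) if fit_size < len(pool) else np.arange(len(pool))
        params = profiling.ReducerParams(
            n_neighbors=config.profile["n_neighbors"],
            min_dist=config.profile["min_dist"],
            min_cluster_size=config.profile["min_cluster_size"],
            min_samples=config.profile.get("min_samples"),
        )
        bundle = profiling.fit_reducer(pool[np.sort(sel)], params, seed=stage_seed(config.seed, 61))
        bundle.save(bundle_path)
        pd.DataFrame(
            {"umap_1": bundle.fit_coords[:, 0], "umap_2": bundle.fit_coords[:, 1],
             "cluster": bundle.fit_labels}
        ).to_csv(os.path.join(out, "umap_coords.csv"), index=False)
        rows = []
        for (plate, well), emb_arr in sorted(well_emb.items()):
            labels = profiling.assign_clusters(bundle, emb_arr)
            cond = well_rois[(plate, well)].meta["condition"].iloc[0]
            prof = profiling.occupancy_profile(
                labels, bundle.n_clusters, sample_id=f"{plate}/{well}", condition=str(cond)
            )
            for ci, f in enumerate(prof.frequencies):
                rows.append({
                    "sample_id": prof.sample_id, "condition": prof.condition,
                    "cluster": ci if ci < bundle.n_clusters else -1,
                    "frequency": f, "n_rois": prof.n_rois,
                })
        pd.DataFrame(rows).to_csv(prof_csv, index=False)
    profiles_df = pd.read_csv(prof_csv) if _done(prof_csv) else None
    if profiles_df is not None:
        n_clusters = int(profiles_df[profiles_df.cluster >= 0].cluster.max() + 1) if len(profiles_df) else 0
        report["stages"]["profile"] = {
            "n_clusters": n_clusters,
            "n_profiles": int(profiles_df.sample_id.nunique()),
            "profiles_csv": prof_csv,
        }

    # ---- stats -----------------------------------------------------------
    stats_json = os.path.join(out, "stats.json")
    if config.stages.get("stats", True) and profiles_df is not None and (force or not _done(stats_json)):
        payload = _condition_stats(profiles_df)
        with open(stats_json, "w") as fh:
            json.dump(payload, fh, indent=1)
    report["stages"]["stats"] = {"path": stats_json if _done(stats_json) else None}

    with open(os.path.join(out, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _by_plate_channel(manifest: pd.DataFrame):
    for channel, col in (("nuclei", "nuclei_path"), ("junction", "junction_path")):
        for plate, group in manifest.groupby("plate", sort=True):
            yield (plate, channel), pd.DataFrame({"path": group[col].tolist()})


def _corrected_path(corr_dir: str, original: str) -> str:
    return os.path.join(corr_dir, os.path.basename(original))


def _profile_matrix(profiles_df: pd.DataFrame) -> tuple[np.ndarray, list, list]:
    wide = profiles_df.pivot_table(
        index=["sample_id", "condition"], columns="cluster", values="frequency", sort=True
    ).fillna(0.0)
    mat = wide.to_numpy()
    sample_ids = [i[0] for i in wide.index]
    conditions = [i[1] for i in wide.index]
    return mat, sample_ids, conditions


def _condition_stats(profiles_df: pd.DataFrame) -> dict:
    mat, sample_ids, conditions = _profile_matrix(profiles_df)
    conds = sorted(set(conditions))
    payload: dict = {"conditions": conds}
    # cosine similarity between mean condition profiles
    means = {c: mat[[i for i, cc in enumerate(conditions) if cc == c]].mean(axis=0) for c in conds}
    if len(conds) >= 2:
        sim = stats.similarity_matrix([means[c] for c in conds])
        payload["mean_profile_cosine"] = {"labels": conds, "matrix": sim.tolist()}
    # Hotelling between condition pairs on an LDA-reduced space
    y = np.array(conditions)
    counts = {c: int((y == c).sum()) for c in conds}
    n_comp = min(2, len(conds) - 1)
    if len(conds) >= 2 and min(counts.values()) >= n_comp + 1 and len(mat) > len(conds):
        try:
            lda, Z = stats.fit_lda(mat, y, n_components=n_comp)
            payload["lda_explained_variance_ratio"] = lda.explained_variance_ratio.tolist()
            tests = []
            for i in range(len(conds)):
                for j in range(i + 1, len(conds)):
                    a, b = Z[y == conds[i]], Z[y == conds[j]]
                    if len(a) >= n_comp + 1 and len(b) >= n_comp + 1:
                        r = stats.hotelling_t2(a, b)
                        tests.append({"pair": [conds[i], conds[j]], "t2": r.statistic, "p": r.p_value})
            payload["hotelling_pairs"] = tests
        except (ValueError, np.linalg.LinAlgError) as exc:
            payload["hotelling_error"] = str(exc)
    return payload
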