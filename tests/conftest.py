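"""Shared fixtures. The expensive ones (trained CNN, pipeline runs) are
session-scoped and reused across test modules to keep the suite fast."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from ajprofiler.model import ModelConfig, build_model, train
from ajprofiler.synthgen import SynthConfig, generate_monolayer, make_training_set

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def monolayer25():
    """Reference 25-cell synthetic site (512x512, default conditions)."""
    cfg = SynthConfig(n_cells=25, seed=7)
    nuclei, junction, truth = generate_monolayer(cfg)
    return cfg, nuclei, junction, truth


@pytest.fixture(scope="session")
def training_sets():
    """Balanced labeled sets: (train 500/class + val 100/class, test 300/class)."""
    full = make_training_set(600, SynthConfig(seed=11))
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(full))
    val, tr = full.subset(idx[:500]), full.subset(idx[500:])
    test = make_training_set(300, SynthConfig(seed=777))
    return tr, val, test


@pytest.fixture(scope="session")
def trained_model(training_sets):
    """CNN trained on the 500/class synthetic set at the full screening
    protocol: batch 64, lr 1e-4, 30 epochs."""
    tr, val, _ = training_sets
    cfg = ModelConfig(max_epochs=30, seed=0)
    model = build_model(cfg)
    model, history = train(model, tr, val, cfg)
    return model, history


@pytest.fixture(scope="session")
def mini_dataset(tmp_path_factory):
    """Small on-disk two-condition dataset (manifest + TIFF pairs)."""
    from ajprofiler.synthgen import write_dataset

    outdir = tmp_path_factory.mktemp("mini_data")
    base = SynthConfig(image_size=(256, 256), n_cells=12)
    conds = {"ctrl": {1: 0.7, 4: 0.3}, "stim": {1: 0.3, 4: 0.7}}
    manifest = write_dataset(str(outdir), conds, wells_per_condition=2,
                             sites_per_well=1, base_config=base, seed=5)
    return outdir, manifest


def mini_pipeline_config(manifest_path, outdir, seed=1):
    from ajprofiler.pipeline import PipelineConfig

    cfg = PipelineConfig(manifest=str(manifest_path), outdir=str(outdir), seed=seed)
    cfg.roi["n_per_well"] = 60
    cfg.train.update({"n_per_class": 40, "val_per_class": 10, "max_epochs": 2})
    cfg.profile["fit_size"] = 200
    cfg.correct["smooth_sigma"] = 24
    return cfg


@pytest.fixture(scope="session")
def pipeline_runs(mini_dataset, tmp_path_factory):
    """The mini dataset pushed through the full pipeline twice (same seed)."""
    from ajprofiler.pipeline import run_pipeline

    outdir, _ = mini_dataset
    manifest = outdir / "manifest.csv"
    results = []
    for name in ("runA", "runB"):
        rundir = tmp_path_factory.mktemp(name)
        cfg = mini_pipeline_config(manifest, rundir, seed=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = run_pipeline(cfg)
        results.append((rundir, report))
    return results
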