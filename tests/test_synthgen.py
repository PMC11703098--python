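"""Generator contracts: tessellation, renderers, noise model, training sets."""

import numpy as np
import pytest

from ajprofiler.roi import CLASS_NAMES
from ajprofiler.synthgen import (
    RenderParams,
    SynthConfig,
    apply_vignette_and_noise,
    generate_monolayer,
    make_training_set,
    render_border_segment,
)
from ajprofiler.utils import neighbor_label_pairs


class TestGenerateMonolayer:
    def test_cell_count_matches_config(self, monolayer25):
        _, _, _, truth = monolayer25
        labels = np.unique(truth.cell_label_map)
        assert len(labels[labels > 0]) == 25
        assert len(truth.nucleus_centers) == 25

    def test_single_cell_has_no_borders(self):
        cfg = SynthConfig(image_size=(128, 128), n_cells=1, seed=0)
        _, _, truth = generate_monolayer(cfg)
        assert len(np.unique(truth.cell_label_map)) == 1
        assert not truth.border_class_map.any()

    def test_degenerate_mix_paints_single_class(self):
        cfg = SynthConfig(image_size=(256, 256), n_cells=9, morphology_mix={1: 1.0}, seed=3)
        _, _, truth = generate_monolayer(cfg)
        nz = truth.border_class_map[truth.border_class_map > 0]
        assert nz.size > 0 and np.all(nz == 1)

    def test_deterministic_given_seed(self):
        cfg = SynthConfig(image_size=(256, 256), n_cells=9, seed=21)
        n1, j1, t1 = generate_monolayer(cfg)
        n2, j2, t2 = generate_monolayer(SynthConfig(image_size=(256, 256), n_cells=9, seed=21))
        assert np.array_equal(n1, n2) and np.array_equal(j1, j2)
        assert np.array_equal(t1.cell_label_map, t2.cell_label_map)
        assert np.array_equal(t1.border_class_map, t2.border_class_map)

    def test_rejects_overcrowded_config(self):
        with pytest.raises(ValueError, match="cell area"):
            SynthConfig(image_size=(128, 128), n_cells=200).validate()

    def test_border_pixels_touch_two_cells(self, monolayer25):
        _, _, _, truth = monolayer25
        coords = np.argwhere(truth.border_class_map > 0)
        pairs = neighbor_label_pairs(truth.cell_label_map, coords)
        assert all(len(p) >= 2 for p in pairs)

    def test_vignette_field_positive_and_mix_sums(self, monolayer25):
        _, _, _, truth = monolayer25
        assert np.all(truth.vignette_field > 0)
        assert abs(sum(truth.morphology_mix.values()) - 1.0) < 1e-9


class TestRenderers:
    @staticmethod
    def _render(code, **kw):
        canvas = np.zeros((64, 64))
        poly = np.array([[32.0, 4.0], [32.0, 60.0]])
        render_border_segment(code, poly, canvas, kw.pop("params", None),
                              np.random.default_rng(kw.pop("seed", 0)))
        return canvas

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            self._render(9)

    def test_linear_confined_to_narrow_band(self):
        canvas = self._render(1)
        rows = np.argwhere(canvas > 0.01 * canvas.max())[:, 0]
        assert np.all(np.abs(rows - 32) <= 3)

    def test_foci_wider_than_linear(self):
        def halfwidth(canvas):
            rows = np.argwhere(canvas > 0.1 * canvas.max())[:, 0]
            return np.abs(rows - 32).max()

        assert halfwidth(self._render(3)) > halfwidth(self._render(1))

    def test_fully_gapped_disturbed_draws_nothing(self):
        params = RenderParams(disturbed_gap_fraction=1.0)
        canvas = self._render(4, params=params)
        assert not canvas.any()

    def test_width_separates_linear_from_highly_disturbed(self):
        """Mean band width differs between the extreme classes with a large
        effect size, so the classification task is learnable in principle."""

        def band_width(canvas):
            return (canvas > 0.1 * canvas.max()).sum() / 56.0  # px per unit length

        lin = [band_width(self._render(1, seed=s)) for s in range(8)]
        hd = [band_width(self._render(5, seed=s)) for s in range(8)]
        pooled_sd = np.sqrt((np.var(lin, ddof=1) + np.var(hd, ddof=1)) / 2)
        effect = abs(np.mean(lin) - np.mean(hd)) / pooled_sd
        assert effect > 1.0


class TestVignetteAndNoise:
    def test_identity_field_no_noise(self):
        img = np.full((32, 32), 500.0)
        out = apply_vignette_and_noise(img, np.ones_like(img), (0.0, 0.0), np.random.default_rng(0))
        np.testing.assert_array_equal(out, img)

    def test_corner_to_center_ratio_follows_field(self):
        cfg = SynthConfig(image_size=(128, 128), n_cells=4, vignette_strength=0.5, seed=0)
        _, _, truth = generate_monolayer(cfg)
        flat = np.full((128, 128), 100.0)
        out = apply_vignette_and_noise(flat, truth.vignette_field, (0.0, 0.0), np.random.default_rng(0))
        assert out[64, 64] / 100.0 == pytest.approx(truth.vignette_field[64, 64], rel=1e-9)
        assert out[0, 0] / out[64, 64] == pytest.approx(0.5, abs=0.02)

    def test_gaussian_noise_sd_calibrated(self):
        """Monte-Carlo estimate of per-pixel noise SD matches the config."""
        rng = np.random.default_rng(5)
        img = np.full((16, 16), 5000.0)
        reps = np.stack([
            apply_vignette_and_noise(img, np.ones_like(img), (120.0, 0.0), rng)
            for _ in range(1000)
        ])
        sd = reps.std(axis=0).mean()
        assert abs(sd - 120.0) / 120.0 < 0.10

    def test_nonpositive_field_rejected(self):
        img = np.ones((8, 8))
        with pytest.raises(ValueError):
            apply_vignette_and_noise(img, np.zeros_like(img), (0.0, 0.0), np.random.default_rng(0))


class TestMakeTrainingSet:
    def test_balanced_and_sized(self):
        ts = make_training_set(10, SynthConfig(image_size=(256, 256), n_cells=12, seed=2))
        assert len(ts) == 50
        assert ts.patches.shape[1:] == (64, 64)
        counts = np.bincount(ts.labels, minlength=6)[1:]
        assert np.all(counts == 10)

    def test_labels_match_truth_majority_class(self):
        """Recount the class map under each patch footprint from ground truth."""
        from ajprofiler.synthgen import SynthConfig as SC

        base = SC(image_size=(256, 256), n_cells=12, seed=2)
        ts = make_training_set(5, base)
        sub = ts.subset(np.flatnonzero(ts.labels == 2))
        for _, row in sub.meta.iterrows():
            cfg = base.replace(morphology_mix={2: 1.0}, seed=int(row.source_seed))
            _, _, truth = generate_monolayer(cfg)
            r, c = int(row.row), int(row.col)
            win = truth.border_class_map[r - 32 : r + 32, c - 32 : c + 32]
            nz = win[win > 0]
            assert nz.size and np.bincount(nz).argmax() == 2
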