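"""Simulator: label sampling, geometry, rendering, dataset writing."""

import numpy as np
import pytest

from protloc.classes import CLASS_CODES, CLASS_INDEX, codes_from_vector
from protloc.simdata import (
    MORPHOLOGIES,
    SimConfig,
    generate_dataset,
    generate_samples,
    render_geometry,
    render_sample,
    sample_label_set,
)


class TestLabelSampling:
    def test_degenerate_distribution_gives_single_labels(self, rng):
        for _ in range(50):
            assert sample_label_set(rng, multiloc_probs=(1, 0, 0, 0)).sum() == 1

    def test_seeded_determinism(self):
        a = [sample_label_set(np.random.default_rng(9)) for _ in range(10)]
        b = [sample_label_set(np.random.default_rng(9)) for _ in range(10)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_empty_allowed_list_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_label_set(rng, allowed_classes=())

    def test_bad_probs_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_label_set(rng, multiloc_probs=(0.5, 0.2, 0.1, 0.1))

    def test_multilabel_draws_respect_cooccurrence(self, rng):
        from protloc.simdata import DEFAULT_COOCCURRENCE

        for _ in range(200):
            vec = sample_label_set(rng, multiloc_probs=(0, 0.5, 0.4, 0.1))
            codes = codes_from_vector(vec)
            for c in codes:
                assert any(
                    o in DEFAULT_COOCCURRENCE.get(c, frozenset())
                    for o in codes - {c}
                ), f"{c} incompatible with {codes}"


class TestGeometry:
    def test_invariants(self, rng):
        cells = render_geometry(rng, "lineA", 64)
        assert 1 <= len(cells) <= 6
        for g in cells:
            assert not (g.nucleus & ~g.cell).any()
            r, c = g.centrosome
            assert g.cell[r, c] and not g.nucleus[r, c]

    def test_image_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            render_geometry(rng, "lineA", 32)

    def test_seeded_determinism(self):
        a = render_geometry(np.random.default_rng(5), "lineB", 96)
        b = render_geometry(np.random.default_rng(5), "lineB", 96)
        assert len(a) == len(b)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.cell, y.cell)

    def test_morphology_size_ratio(self):
        """Mean single-cell areas scale as the configured size parameters."""
        areas = {}
        for tag in ("lineB", "lineC"):
            vals = []
            for seed in range(100):
                g = render_geometry(np.random.default_rng(seed), tag, 256, max_cells=1)[0]
                vals.append(g.cell.sum())
            areas[tag] = np.mean(vals)
        pb, pc = MORPHOLOGIES["lineB"], MORPHOLOGIES["lineC"]
        expected = (pb["size_scale"] ** 2 * np.mean(pb["ecc"])) / (
            pc["size_scale"] ** 2 * np.mean(pc["ecc"])
        )
        assert areas["lineB"] / areas["lineC"] == pytest.approx(expected, rel=0.25)


class TestRenderSample:
    def geom(self, seed=3, side=64):
        return render_geometry(np.random.default_rng(seed), "lineA", side)

    def labels(self, *codes):
        vec = np.zeros(13, dtype=np.int8)
        for c in codes:
            vec[CLASS_INDEX[c]] = 1
        return vec

    def test_nucleus_signal_inside_blue_support(self, rng):
        s = render_sample(self.geom(), self.labels("NU"), rng, noise_level=0.0)
        green, blue = s.image[0], s.image[1]
        assert ((green > 0) <= (blue > 0)).all()

    def test_cytosol_signal_excludes_nucleus(self, rng):
        cells = self.geom()
        s = render_sample(cells, self.labels("CY"), rng, noise_level=0.0)
        nuclei = np.zeros_like(cells[0].nucleus)
        for g in cells:
            nuclei |= g.nucleus
        assert s.image[0][nuclei].max() == 0.0

    def test_truth_masks_union_equals_green_support(self, rng):
        s = render_sample(self.geom(), self.labels("NU", "CY", "VE"), rng, noise_level=0.0)
        assert len(s.truth_masks) == 3
        union = np.zeros_like(s.image[0], dtype=bool)
        for m in s.truth_masks.values():
            union |= m
        np.testing.assert_array_equal(s.image[0] > 0, union)

    def test_empty_labels_rejected(self, rng):
        with pytest.raises(ValueError):
            render_sample(self.geom(), np.zeros(13, dtype=np.int8), rng)

    @pytest.mark.parametrize("code", CLASS_CODES)
    def test_every_class_renders_nonempty_mask(self, code, rng):
        s = render_sample(self.geom(seed=7), self.labels(code), rng, noise_level=0.0)
        assert s.truth_masks[code].any()

    def test_image_bounded_and_noise_confined(self, rng):
        s = render_sample(self.geom(), self.labels("VE"), rng, noise_level=0.05)
        assert s.image.min() >= 0.0 and s.image.max() <= 1.0


class TestGenerateDataset:
    def test_seeded_csv_is_byte_identical(self, tmp_path):
        cfg = SimConfig(image_side=64)
        generate_dataset(10, cfg, seed=7, out_dir=tmp_path / "a")
        generate_dataset(10, cfg, seed=7, out_dir=tmp_path / "b")
        assert (tmp_path / "a/labels.csv").read_bytes() == (tmp_path / "b/labels.csv").read_bytes()

    def test_file_layout(self, tmp_path):
        table = generate_dataset(5, SimConfig(), seed=1, out_dir=tmp_path)
        assert len(table) == 5
        assert len(list(tmp_path.glob("*_green.png"))) == 5
        assert len(list(tmp_path.glob("*.png"))) == 20

    def test_every_class_appears_in_large_run(self):
        samples = generate_samples(400, SimConfig(), seed=3)
        seen = set()
        for s in samples:
            seen |= codes_from_vector(s.labels)
        assert seen == set(CLASS_CODES)

    def test_zero_samples_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            generate_dataset(0, SimConfig(), seed=1, out_dir=tmp_path)

    def test_in_memory_determinism(self):
        a = generate_samples(6, SimConfig(), seed=11)
        b = generate_samples(6, SimConfig(), seed=11)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)
            np.testing.assert_array_equal(x.labels, y.labels)
            assert x.cell_line == y.cell_line

    def test_roundtrip_through_disk(self, tmp_path):
        from protloc.io import read_dataset

        cfg = SimConfig(image_side=64)
        samples = generate_samples(4, cfg, seed=2)
        generate_dataset(4, cfg, seed=2, out_dir=tmp_path)
        images, labels, tags, ids = read_dataset(tmp_path)
        assert images.shape == (4, 4, 64, 64)
        for i, s in enumerate(samples):
            np.testing.assert_array_equal(labels[i], s.labels)
            assert tags[i] == s.cell_line
            # 16-bit quantization error only
            assert np.abs(images[i] - s.image).max() < 1e-4
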