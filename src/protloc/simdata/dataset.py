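"""Sample rendering and dataset generation.

A rendered sample is a 4-channel image in [0, 1], channel order
(green, blue, red, yellow):

* green — the protein of interest: sum of the class-specific patterns
  of every annotated class, with per-cell intensity jitter, plus
  additive Gaussian background noise (green only);
* blue — nucleus counterstain: the filled nuclei;
* red — microtubule reference staining: filaments radiating from each
  cell's centrosome;
* yellow — endoplasmic-reticulum reference staining: a perinuclear
  reticular mesh.

``generate_dataset`` writes one grayscale 16-bit PNG per channel plus a
``labels.csv`` table (sample_id, cell_line, space-separated class
codes), matching the per-channel file convention of cell-atlas style
datasets, and optionally the ground-truth masks as a multi-page TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from ..classes import CLASS_CODES, codes_from_vector
from .geometry import MORPHOLOGY_FREQS, CellGeometry, render_geometry
from .labels import DEFAULT_MULTILOC_PROBS, sample_label_set
from .patterns import PATTERN_RENDERERS, render_class_mask

__all__ = ["SimConfig", "SyntheticSample", "render_sample", "generate_samples", "generate_dataset"]

# relative green-channel brightness by compartment type: punctate organelles
# (centrosome, nucleoli, vesicles, Golgi) concentrate fluorophore into small
# foci and read brighter than diffuse, membrane or filamentous signals
CLASS_INTENSITY: dict[str, float] = {
    "CE": 0.80, "NI": 0.80, "VE": 0.80, "GA": 0.80,
    "NM": 0.70, "PM": 0.70,
    "MT": 0.65, "MC": 0.65, "AF": 0.65, "IF": 0.65,
    "NU": 0.55, "CY": 0.55, "ER": 0.55,
}


@dataclass
class SimConfig:
    """Simulator settings; defaults define the standard study conditions."""

    image_side: int = 64
    multiloc_probs: tuple[float, ...] = DEFAULT_MULTILOC_PROBS
    allowed_classes: tuple[str, ...] = CLASS_CODES
    class_weights: dict[str, float] | None = None   # None -> default imbalance
    noise_sigma: float = 0.02
    intensity_jitter: float = 0.2       # per-cell multiplicative jitter, +/-20%
    morphology_freqs: dict[str, float] = field(
        default_factory=lambda: dict(MORPHOLOGY_FREQS)
    )
    write_masks: bool = False


@dataclass
class SyntheticSample:
    """One generated 4-channel image with its ground truth."""

    sample_id: str
    image: np.ndarray                   # (4, S, S) float in [0, 1]
    labels: np.ndarray                  # binary 13-vector
    truth_masks: dict[str, np.ndarray]  # class code -> bool (S, S)
    cell_line: str

    def validate(self) -> None:
        if self.image.min() < 0 or self.image.max() > 1:
            raise ValueError("image values must lie in [0, 1]")
        present = codes_from_vector(self.labels)
        if set(self.truth_masks) != present:
            raise ValueError("truth masks must cover exactly the present classes")
        for code, mask in self.truth_masks.items():
            if not mask.any():
                raise ValueError(f"empty truth mask for class {code}")


def render_sample(
    cells: list[CellGeometry],
    labels: np.ndarray,
    rng: np.random.Generator,
    noise_level: float = 0.02,
    intensity_jitter: float = 0.2,
    sample_id: str = "",
) -> SyntheticSample:
    """Render a 4-channel image for the given cells and annotation."""
    present = sorted(codes_from_vector(labels), key=CLASS_CODES.index)
    if not present:
        raise ValueError("labels must contain at least one present class")
    side = cells[0].cell.shape[0]
    green = np.zeros((side, side))
    truth: dict[str, np.ndarray] = {}
    # per-cell brightness jitter shared by all green patterns of that cell
    gains = [1.0 + rng.uniform(-intensity_jitter, intensity_jitter) for _ in cells]
    # additive compositing: where patterns of co-localizing classes overlap
    # the intensities sum (as fluorescence does), so e.g. nucleoli remain
    # visible as bright foci on top of a diffuse nuclear signal; punctate
    # compartments concentrate signal and so appear brighter than diffuse ones
    for code in present:
        mask = np.zeros((side, side), dtype=bool)
        for g, gain in zip(cells, gains):
            m = PATTERN_RENDERERS[code](g, rng)
            mask |= m
            green[m] += CLASS_INTENSITY[code] * gain
        truth[code] = mask

    blue = np.zeros((side, side))
    red = np.zeros((side, side))
    yellow = np.zeros((side, side))
    for g, gain in zip(cells, gains):
        blue[g.nucleus] = 0.9 * gain
        red[PATTERN_RENDERERS["MT"](g, rng)] = 0.8 * gain
        yellow[PATTERN_RENDERERS["ER"](g, rng)] = 0.8 * gain

    if noise_level > 0:
        green = green + rng.normal(0.0, noise_level, size=green.shape)
    image = np.clip(np.stack([green, blue, red, yellow]), 0.0, 1.0)
    sample = SyntheticSample(sample_id, image, np.asarray(labels), truth, cells[0].morphology_tag)
    sample.validate()
    return sample


def _draw_morphology(rng: np.random.Generator, freqs: dict[str, float]) -> str:
    tags = sorted(freqs)
    p = np.array([freqs[t] for t in tags], dtype=float)
    return str(rng.choice(tags, p=p / p.sum()))


def generate_samples(n: int, config: SimConfig, seed: int) -> list[SyntheticSample]:
    """Generate ``n`` samples in memory, fully determined by ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    samples = []
    # one independent child stream per sample: stable under reordering
    for i, ss in enumerate(np.random.SeedSequence(seed).spawn(n)):
        rng = np.random.default_rng(ss)
        tag = _draw_morphology(rng, config.morphology_freqs)
        cells = render_geometry(rng, tag, config.image_side)
        labels = sample_label_set(
            rng,
            multiloc_probs=config.multiloc_probs,
            class_weights=config.class_weights,
            allowed_classes=config.allowed_classes,
        )
        samples.append(
            render_sample(
                cells,
                labels,
                rng,
                noise_level=config.noise_sigma,
                intensity_jitter=config.intensity_jitter,
                sample_id=f"sample_{i:05d}",
            )
        )
    return samples


_CHANNEL_NAMES = ("green", "blue", "red", "yellow")


def write_sample(sample: SyntheticSample, out_dir: Path) -> None:
    for ch, name in enumerate(_CHANNEL_NAMES):
        arr = np.round(sample.image[ch] * 65535).astype(np.uint16)
        iio.imwrite(out_dir / f"{sample.sample_id}_{name}.png", arr)


def generate_dataset(
    n: int, config: SimConfig, seed: int, out_dir: str | Path
) -> pd.DataFrame:
    """Write ``n`` samples and ``labels.csv`` to ``out_dir``; returns the table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in generate_samples(n, config, seed):
        write_sample(sample, out_dir)
        if config.write_masks:
            codes = sorted(sample.truth_masks, key=CLASS_CODES.index)
            stack = np.stack([sample.truth_masks[c] for c in codes]).astype(np.uint8)
            tifffile.imwrite(out_dir / f"{sample.sample_id}_masks.tif", stack)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "cell_line": sample.cell_line,
                "classes": " ".join(
                    sorted(codes_from_vector(sample.labels), key=CLASS_CODES.index)
                ),
            }
        )
    table = pd.DataFrame(rows, columns=["sample_id", "cell_line", "classes"])
    table.to_csv(out_dir / "labels.csv", index=False, lineterminator="\n")
    return table
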