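"""Readers and writers for the on-disk dataset and result artifacts.

Dataset layout: one grayscale PNG (or TIFF) per channel per sample,
named ``<id>_green/blue/red/yellow.png``, plus ``labels.csv`` with
columns sample_id, cell_line, classes (space-separated class codes).
Prediction tables are CSVs with a sample_id column followed by the 13
confidence columns in canonical class order.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .classes import CLASS_CODES, label_vector

__all__ = [
    "read_labels",
    "read_image",
    "read_dataset",
    "write_predictions",
    "read_predictions",
    "write_thresholds",
    "read_thresholds",
    "write_matrix",
    "write_heatmaps",
]

CHANNEL_NAMES = ("green", "blue", "red", "yellow")


def read_labels(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype=str)
    required = {"sample_id", "cell_line", "classes"}
    if not required <= set(table.columns):
        raise ValueError(f"labels table must have columns {sorted(required)}")
    return table


def _find_channel(data_dir: Path, sample_id: str, name: str) -> Path:
    for ext in (".png", ".tif", ".tiff"):
        p = data_dir / f"{sample_id}_{name}{ext}"
        if p.exists():
            return p
    raise FileNotFoundError(f"missing {name} channel for sample {sample_id}")


def read_image(data_dir: str | Path, sample_id: str) -> np.ndarray:
    """Load the 4 channel files of one sample as a (4, H, W) float array in [0, 1]."""
    data_dir = Path(data_dir)
    channels = []
    for name in CHANNEL_NAMES:
        arr = np.asarray(iio.imread(_find_channel(data_dir, sample_id, name)), dtype=float)
        if arr.ndim != 2:
            raise ValueError(f"channel file for {sample_id}/{name} is not grayscale")
        scale = 65535.0 if arr.max() > 255 else 255.0
        channels.append(arr / scale)
    return np.stack(channels)


def read_dataset(
    data_dir: str | Path,
) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Load a simulated dataset directory.

    Returns (images (n, 4, S, S), labels (n, 13), cell_line tags, ids),
    in labels.csv row order.
    """
    data_dir = Path(data_dir)
    table = read_labels(data_dir / "labels.csv")
    images, labels = [], []
    for _, row in table.iterrows():
        images.append(read_image(data_dir, row.sample_id))
        labels.append(label_vector(str(row.classes).split()))
    return (
        np.stack(images),
        np.stack(labels),
        list(table.cell_line),
        list(table.sample_id),
    )


def write_predictions(path: str | Path, ids: list[str], confidences: np.ndarray) -> None:
    table = pd.DataFrame(np.asarray(confidences), columns=list(CLASS_CODES))
    table.insert(0, "sample_id", ids)
    table.to_csv(path, index=False, lineterminator="\n")


def read_predictions(path: str | Path) -> tuple[list[str], np.ndarray]:
    table = pd.read_csv(path)
    return list(table.sample_id), table[list(CLASS_CODES)].to_numpy(dtype=float)


def write_thresholds(path: str | Path, thresholds: np.ndarray) -> None:
    pd.DataFrame({"class": CLASS_CODES, "threshold": np.asarray(thresholds)}).to_csv(
        path, index=False, lineterminator="\n"
    )


def read_thresholds(path: str | Path) -> np.ndarray:
    table = pd.read_csv(path)
    order = {c: i for i, c in enumerate(table["class"])}
    return np.array([table["threshold"].iloc[order[c]] for c in CLASS_CODES], dtype=float)


def write_matrix(path: str | Path, matrix: np.ndarray) -> None:
    """13x13 matrix as CSV with class codes on both axes."""
    pd.DataFrame(np.asarray(matrix), index=list(CLASS_CODES), columns=list(CLASS_CODES)).to_csv(
        path, lineterminator="\n"
    )


def write_heatmaps(path: str | Path, heatmaps: np.ndarray) -> None:
    """13-page TIFF, one page per class in canonical order."""
    tifffile.imwrite(path, np.asarray(heatmaps, dtype=np.float32), photometric="minisblack")
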