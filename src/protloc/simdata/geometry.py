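"""Cell geometry synthesis: ellipse cells with nuclei and centrosomes.

Each synthetic image contains 1-6 non-overlapping cells.  A cell is an
ellipse; its nucleus is a smaller, slightly offset ellipse strictly
inside it, and the centrosome is a point in the cytoplasm next to the
nucleus (microtubules radiate from it).  Morphology tags emulate
cell-line heterogeneity: each tag sets its own size and eccentricity
distributions, so images from different "cell lines" differ in cell
area and elongation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import ellipse as draw_ellipse

__all__ = ["CellGeometry", "MORPHOLOGIES", "MORPHOLOGY_FREQS", "render_geometry"]


# size_scale multiplies the linear cell radius; ecc is the ratio of the
# minor to the major semi-axis (sampled uniformly in the given range).
MORPHOLOGIES: dict[str, dict] = {
    "lineA": {"size_scale": 1.0, "ecc": (0.75, 0.95)},   # medium, round
    "lineB": {"size_scale": 1.35, "ecc": (0.40, 0.65)},  # large, elongated
    "lineC": {"size_scale": 0.75, "ecc": (0.80, 1.00)},  # small, round
}

# lineC is the deliberate minority "cell line" for stratified evaluation
MORPHOLOGY_FREQS: dict[str, float] = {"lineA": 0.50, "lineB": 0.40, "lineC": 0.10}


@dataclass
class CellGeometry:
    """Pixel-level geometry of one cell."""

    cell: np.ndarray        # bool (S, S), the whole cell
    nucleus: np.ndarray     # bool (S, S), strictly inside `cell`
    centrosome: tuple[int, int]
    morphology_tag: str

    def validate(self) -> None:
        if not (self.nucleus & ~self.cell).sum() == 0:
            raise ValueError("nucleus must be contained in the cell")
        r, c = self.centrosome
        if not self.cell[r, c] or self.nucleus[r, c]:
            raise ValueError("centrosome must lie in the cytoplasm")

    @property
    def cytoplasm(self) -> np.ndarray:
        return self.cell & ~self.nucleus

    @property
    def radius(self) -> float:
        """Equivalent circular radius of the cell, in pixels."""
        return float(np.sqrt(self.cell.sum() / np.pi))


def _make_cell(rng: np.random.Generator, tag: str, side: int) -> CellGeometry | None:
    params = MORPHOLOGIES[tag]
    base_r = 0.16 * side * params["size_scale"]
    major = base_r * rng.uniform(0.85, 1.15)
    minor = major * rng.uniform(*params["ecc"])
    theta = rng.uniform(0, np.pi)
    margin = major + 1
    if 2 * margin >= side:
        major = minor = min(major, (side - 2) / 2.0)
        margin = major + 1
        theta = 0.0
    r0 = rng.uniform(margin, side - margin)
    c0 = rng.uniform(margin, side - margin)

    cell = np.zeros((side, side), dtype=bool)
    rr, cc = draw_ellipse(r0, c0, major, minor, shape=(side, side), rotation=theta)
    cell[rr, cc] = True
    if cell.sum() < 16:
        return None

    # nucleus: ~45% linear size, offset at most 25% of the cell radius
    nuc = np.zeros((side, side), dtype=bool)
    off = 0.22 * major
    nr0 = r0 + rng.uniform(-off, off) * np.cos(theta)
    nc0 = c0 + rng.uniform(-off, off) * np.sin(theta)
    rr, cc = draw_ellipse(nr0, nc0, 0.45 * major, 0.45 * minor, shape=(side, side), rotation=theta)
    nuc[rr, cc] = True
    nuc &= cell
    if nuc.sum() < 4 or (nuc & ~cell).any():
        return None

    # centrosome: walk outward from the nucleus center until leaving the
    # nucleus while staying in the cell
    phi = rng.uniform(0, 2 * np.pi)
    for step in np.arange(1.0, major, 0.5):
        r = int(round(nr0 + step * np.sin(phi)))
        c = int(round(nc0 + step * np.cos(phi)))
        if 0 <= r < side and 0 <= c < side and cell[r, c] and not nuc[r, c]:
            geom = CellGeometry(cell, nuc, (r, c), tag)
            try:
                geom.validate()
            except ValueError:
                return None
            return geom
    return None


def render_geometry(
    rng: np.random.Generator,
    morphology_tag: str,
    image_side: int,
    max_cells: int | None = None,
) -> list[CellGeometry]:
    """Place 1-6 non-overlapping cells of one morphology in an image.

    Raises ``ValueError`` if the image is too small (< 64 px) for a cell.
    """
    if image_side < 64:
        raise ValueError(f"image_side must be >= 64, got {image_side}")
    if morphology_tag not in MORPHOLOGIES:
        raise KeyError(f"unknown morphology tag {morphology_tag!r}")
    target = int(rng.integers(1, 7)) if max_cells is None else max_cells
    occupied = np.zeros((image_side, image_side), dtype=bool)
    cells: list[CellGeometry] = []
    attempts = 0
    while len(cells) < target and attempts < 60:
        attempts += 1
        geom = _make_cell(rng, morphology_tag, image_side)
        if geom is None:
            continue
        # keep a 1-px gap between cells
        dil = np.zeros_like(geom.cell)
        dil[:-1] |= geom.cell[1:]
        dil[1:] |= geom.cell[:-1]
        dil[:, :-1] |= geom.cell[:, 1:]
        dil[:, 1:] |= geom.cell[:, :-1]
        dil |= geom.cell
        if (dil & occupied).any():
            continue
        occupied |= dil
        cells.append(geom)
    if not cells:
        raise ValueError("could not place any cell; image too small or crowded")
    return cells
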