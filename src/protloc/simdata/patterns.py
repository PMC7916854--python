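"""Per-class organelle pattern renderers.

Each renderer takes one cell's geometry and returns a boolean mask of
the fluorescence support the class would show in that cell: filled
nucleus for NU, nucleolar blobs for NI, a nuclear-rim ring for NM,
cytosol for CY, a plasma-membrane ring for PM, scattered cytoplasmic
dots for VE, short curved filaments for MC, filaments radiating from
the centrosome for MT, a single centrosomal dot for CE, a compact
juxtanuclear patch for GA, a perinuclear reticular mesh for ER, long
straight fibers for AF, and a wavy cytoplasmic meshwork for IF.

These are qualitative stand-ins for the characteristic appearance of
each compartment, not photorealistic renderings; their purpose is to be
mutually distinguishable and anchored to the correct subcellular region.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line

from .geometry import CellGeometry

__all__ = ["render_class_mask", "PATTERN_RENDERERS"]


def _ring(region: np.ndarray, width: int) -> np.ndarray:
    inner = ndi.binary_erosion(region, iterations=max(1, width))
    ring = region & ~inner
    return ring if ring.any() else region


def _dots(
    rng: np.random.Generator, support: np.ndarray, n: int, radius: int
) -> np.ndarray:
    out = np.zeros_like(support)
    coords = np.argwhere(support)
    if len(coords) == 0:
        return out
    picks = coords[rng.integers(0, len(coords), size=n)]
    for r, c in picks:
        rr, cc = draw_disk((r, c), radius + 0.5, shape=support.shape)
        out[rr, cc] = True
    return out & support


def _curve(
    rng: np.random.Generator,
    support: np.ndarray,
    start: tuple[int, int],
    length: int,
    wobble: float,
) -> np.ndarray:
    """A wobbly discrete path of ~`length` steps clipped to `support`."""
    out = np.zeros_like(support)
    r, c = float(start[0]), float(start[1])
    phi = rng.uniform(0, 2 * np.pi)
    for _ in range(length):
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < support.shape[0] and 0 <= ci < support.shape[1]):
            break
        if support[ri, ci]:
            out[ri, ci] = True
        phi += rng.uniform(-wobble, wobble)
        r += np.sin(phi)
        c += np.cos(phi)
    return out


def _nu(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    return g.nucleus.copy()


def _ni(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    interior = ndi.binary_erosion(g.nucleus, iterations=1)
    if not interior.any():
        interior = g.nucleus
    n = int(rng.integers(1, 5))
    radius = max(1, int(round(0.25 * np.sqrt(g.nucleus.sum() / np.pi))))
    out = _dots(rng, interior, n, radius) & g.nucleus
    return out if out.any() else interior


def _nm(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    return _ring(g.nucleus, max(1, int(round(0.20 * np.sqrt(g.nucleus.sum() / np.pi)))))


def _cy(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    return g.cytoplasm


def _pm(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    return _ring(g.cell, max(1, int(round(0.15 * g.radius))))


def _ve(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    n = max(12, int(1.6 * g.radius))
    radius = min(3, max(1, int(round(0.15 * g.radius))))
    out = _dots(rng, g.cytoplasm, n, radius)
    return out if out.any() else _dots(rng, g.cell, n, radius)


def _mc(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(g.cell)
    coords = np.argwhere(g.cytoplasm)
    n_fil = max(4, int(0.6 * g.radius))
    length = max(4, int(0.8 * g.radius))
    for _ in range(n_fil):
        start = coords[rng.integers(0, len(coords))]
        out |= _curve(rng, g.cytoplasm, tuple(start), length, wobble=0.5)
    return out if out.any() else g.cytoplasm


def _mt(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(g.cell)
    boundary = np.argwhere(_ring(g.cell, 1))
    n_rays = min(len(boundary), max(14, int(2.0 * g.radius)))
    picks = boundary[rng.choice(len(boundary), size=n_rays, replace=False)]
    r0, c0 = g.centrosome
    for r1, c1 in picks:
        rr, cc = draw_line(r0, c0, int(r1), int(c1))
        out[rr, cc] = True
    return out & g.cell


def _ce(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(g.cell)
    rr, cc = draw_disk(g.centrosome, 2.0, shape=g.cell.shape)
    out[rr, cc] = True
    out &= g.cell
    if not out.any():
        out[g.centrosome] = True
    return out


def _ga(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    # compact patch hugging the nucleus on one side
    band = ndi.binary_dilation(g.nucleus, iterations=max(2, int(0.25 * g.radius)))
    band &= g.cytoplasm
    coords = np.argwhere(band)
    if len(coords) == 0:
        return _ce(g, rng)
    center = coords[rng.integers(0, len(coords))]
    out = np.zeros_like(g.cell)
    rr, cc = draw_disk(tuple(center), max(2.0, 0.30 * g.radius), shape=g.cell.shape)
    out[rr, cc] = True
    return out & band


def _er(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    # reticular mesh in a perinuclear band: threshold smoothed noise
    band = ndi.binary_dilation(g.nucleus, iterations=max(2, int(0.45 * g.radius)))
    band &= g.cytoplasm
    noise = rng.random(g.cell.shape)
    mesh = ndi.gaussian_filter(noise, 1.0) > 0.5
    out = band & mesh
    return out if out.any() else band


def _af(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    # long straight fibers: chords between random boundary points
    out = np.zeros_like(g.cell)
    boundary = np.argwhere(_ring(g.cell, 1))
    for _ in range(int(rng.integers(3, 7))):
        p0 = boundary[rng.integers(0, len(boundary))]
        p1 = boundary[rng.integers(0, len(boundary))]
        rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
        out[rr, cc] = True
    out &= g.cell
    return out if out.any() else _ring(g.cell, 1)


def _if(g: CellGeometry, rng: np.random.Generator) -> np.ndarray:
    # wavy filament meshwork filling the cytoplasm
    out = np.zeros_like(g.cell)
    coords = np.argwhere(g.cytoplasm)
    n_fil = max(5, int(0.8 * g.radius))
    length = max(8, int(1.6 * g.radius))
    for _ in range(n_fil):
        start = coords[rng.integers(0, len(coords))]
        out |= _curve(rng, g.cytoplasm, tuple(start), length, wobble=0.9)
    return out if out.any() else g.cytoplasm


PATTERN_RENDERERS = {
    "AF": _af, "CE": _ce, "CY": _cy, "ER": _er, "GA": _ga, "IF": _if,
    "MT": _mt, "MC": _mc, "NM": _nm, "NI": _ni, "NU": _nu, "PM": _pm, "VE": _ve,
}


def render_class_mask(
    code: str, cells: list[CellGeometry], rng: np.random.Generator
) -> np.ndarray:
    """Union over cells of the class-specific pattern; always nonempty."""
    renderer = PATTERN_RENDERERS[code]
    out = np.zeros_like(cells[0].cell)
    for g in cells:
        out |= renderer(g, rng)
    if not out.any():  # pragma: no cover - renderers guarantee nonempty
        out[cells[0].centrosome] = True
    return out
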