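"""The 13 organelle localization classes and label-vector helpers.

The canonical ordering is fixed alphabetically by code and is used
everywhere a 13-vector or a 13-channel stack appears: actin filaments
(AF), centrosome (CE), cytosol (CY), endoplasmic reticulum (ER), Golgi
apparatus (GA), intermediate filaments (IF), microtubules (MT),
mitochondria (MC), nuclear membrane (NM), nucleoli (NI), nucleus (NU),
plasma membrane (PM), vesicles (VE).
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np

CLASS_CODES: tuple[str, ...] = (
    "AF", "CE", "CY", "ER", "GA", "IF", "MT", "MC", "NM", "NI", "NU", "PM", "VE",
)
N_CLASSES = len(CLASS_CODES)
CLASS_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASS_CODES)}

CLASS_NAMES: dict[str, str] = {
    "AF": "actin filaments",
    "CE": "centrosome",
    "CY": "cytosol",
    "ER": "endoplasmic reticulum",
    "GA": "Golgi apparatus",
    "IF": "intermediate filaments",
    "MT": "microtubules",
    "MC": "mitochondria",
    "NM": "nuclear membrane",
    "NI": "nucleoli",
    "NU": "nucleus",
    "PM": "plasma membrane",
    "VE": "vesicles",
}


def label_vector(codes: Iterable[str]) -> np.ndarray:
    """Binary 13-vector with 1s at the positions of ``codes``."""
    vec = np.zeros(N_CLASSES, dtype=np.int8)
    for code in codes:
        if code not in CLASS_INDEX:
            raise KeyError(f"unknown organelle class code: {code!r}")
        vec[CLASS_INDEX[code]] = 1
    return vec


def codes_from_vector(vec: np.ndarray) -> frozenset[str]:
    """Set of class codes present in a binary 13-vector."""
    vec = np.asarray(vec)
    if vec.shape != (N_CLASSES,):
        raise ValueError(f"expected a {N_CLASSES}-vector, got shape {vec.shape}")
    return frozenset(CLASS_CODES[i] for i in np.flatnonzero(vec))
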