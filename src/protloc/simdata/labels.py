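"""Multi-label annotation sampling.

A sample carries 1-4 simultaneous localization classes.  The number of
classes k is drawn from the multilocalization distribution (defaults
match the dataset-wide fractions 60.6% / 33.3% / 5.8% / 0.3% for
k = 1..4); the classes themselves are drawn from an imbalanced class
frequency vector, constrained by a co-occurrence whitelist so that
synthetic combinations remain spatially coherent (e.g. nucleoli with
nucleus, vesicles with cytosol).
"""

from __future__ import annotations

import numpy as np

from ..classes import CLASS_CODES, label_vector

__all__ = [
    "DEFAULT_MULTILOC_PROBS",
    "DEFAULT_CLASS_WEIGHTS",
    "DEFAULT_COOCCURRENCE",
    "sample_label_set",
]

DEFAULT_MULTILOC_PROBS: tuple[float, ...] = (0.606, 0.333, 0.058, 0.003)

# qualitative class imbalance: nucleus and cytosol dominate
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "AF": 0.02, "CE": 0.03, "CY": 0.18, "ER": 0.06, "GA": 0.06, "IF": 0.03,
    "MT": 0.07, "MC": 0.08, "NM": 0.05, "NI": 0.07, "NU": 0.21, "PM": 0.04,
    "VE": 0.10,
}

# allowed class pairs (symmetric closure taken at import time)
_PAIRS: tuple[tuple[str, str], ...] = (
    ("NU", "NI"), ("NU", "NM"), ("NU", "CY"), ("NU", "VE"), ("NU", "MT"),
    ("NU", "MC"), ("NU", "GA"), ("NU", "CE"), ("NU", "ER"),
    ("CY", "VE"), ("CY", "MT"), ("CY", "MC"), ("CY", "PM"), ("CY", "AF"),
    ("CY", "IF"), ("CY", "ER"), ("CY", "GA"), ("CY", "CE"),
    ("ER", "VE"), ("ER", "GA"), ("ER", "NM"),
    ("VE", "GA"), ("VE", "PM"),
    ("MT", "CE"),
    ("PM", "AF"),
    ("AF", "IF"),
)

DEFAULT_COOCCURRENCE: dict[str, frozenset[str]] = {}
for _a, _b in _PAIRS:
    DEFAULT_COOCCURRENCE.setdefault(_a, set()).add(_b)  # type: ignore[arg-type]
    DEFAULT_COOCCURRENCE.setdefault(_b, set()).add(_a)  # type: ignore[arg-type]
DEFAULT_COOCCURRENCE = {k: frozenset(v) for k, v in DEFAULT_COOCCURRENCE.items()}


def sample_label_set(
    rng: np.random.Generator,
    multiloc_probs: tuple[float, ...] = DEFAULT_MULTILOC_PROBS,
    cooccurrence: dict[str, frozenset[str]] | None = None,
    class_weights: dict[str, float] | None = None,
    allowed_classes: tuple[str, ...] = CLASS_CODES,
) -> np.ndarray:
    """Draw one multi-label annotation as a binary 13-vector.

    ``k`` (the localization count) is drawn from ``multiloc_probs``;
    classes are then accreted one at a time, each new class weighted by
    the class frequencies and required to be whitelist-compatible with
    at least one class already chosen.
    """
    if len(allowed_classes) == 0:
        raise ValueError("allowed class list is empty: unsatisfiable configuration")
    probs = np.asarray(multiloc_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("multiloc_probs must sum to 1")
    cooc = DEFAULT_COOCCURRENCE if cooccurrence is None else cooccurrence
    weights = DEFAULT_CLASS_WEIGHTS if class_weights is None else class_weights

    k = int(rng.choice(len(probs), p=probs)) + 1

    def weighted_pick(candidates: list[str]) -> str:
        w = np.array([weights.get(c, 1.0) for c in candidates], dtype=float)
        w /= w.sum()
        return str(rng.choice(candidates, p=w))

    chosen: list[str] = [weighted_pick(list(allowed_classes))]
    while len(chosen) < k:
        candidates = [
            c
            for c in allowed_classes
            if c not in chosen
            and any(c in cooc.get(m, frozenset()) for m in chosen)
        ]
        if not candidates:
            raise ValueError(
                f"co-occurrence rules cannot extend {chosen} to {k} classes"
            )
        chosen.append(weighted_pick(candidates))
    return label_vector(chosen)
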