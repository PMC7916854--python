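"""End-to-end experiment helper: simulate, train, calibrate, evaluate.

This is the programmatic counterpart of the command-line workflow: it
generates (or accepts) a dataset, builds the requested network variant,
trains it under the standard protocol, calibrates per-class thresholds
on the training split only, and evaluates on the held-out test split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibrate_eval import EvalReport, ThresholdSet, calibrate_thresholds, evaluate
from .fcn_targets import build_training_targets
from .nets import Model, NetworkSpec, build_model, predict_batch
from .simdata import SimConfig, SyntheticSample, generate_samples
from .trainer import TrainConfig, TrainData, TrainState, split_dataset, train

__all__ = [
    "ExperimentResult",
    "samples_to_arrays",
    "fcn_target_stacks",
    "run_experiment",
    "BENCHMARK_CLASSES",
    "benchmark_sim_config",
    "benchmark_net_spec",
    "benchmark_train_config",
    "BENCHMARK_N_SAMPLES",
    "BENCHMARK_TRAIN_COUNT",
]

# The CPU-scale benchmark: 600 images at 64 px, six well-separated
# localization classes drawn balanced, <= 40% multi-label, 15 epochs.
BENCHMARK_CLASSES: tuple[str, ...] = ("NU", "NI", "CY", "VE", "MT", "PM")
BENCHMARK_N_SAMPLES = 600
BENCHMARK_TRAIN_COUNT = 480


def benchmark_sim_config() -> SimConfig:
    return SimConfig(
        image_side=64,
        allowed_classes=BENCHMARK_CLASSES,
        class_weights={c: 1.0 for c in BENCHMARK_CLASSES},
        multiloc_probs=(0.60, 0.30, 0.08, 0.02),
    )


def benchmark_net_spec(seed: int = 11) -> NetworkSpec:
    return NetworkSpec(input_side=64, base_kernels=8, fc_widths=(128, 64, 13), seed=seed)


def benchmark_train_config(seed: int = 11) -> TrainConfig:
    return TrainConfig(batch_size=8, max_epochs=15, seed=seed)


@dataclass
class ExperimentResult:
    model: Model
    state: TrainState
    thresholds: ThresholdSet
    report: EvalReport              # on the test split
    train_report: EvalReport        # on the training split (calibration data)
    test_confidences: np.ndarray
    test_truths: np.ndarray
    test_tags: list[str]


def samples_to_arrays(
    samples: list[SyntheticSample],
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack samples into (images, label matrix, cell-line tags)."""
    images = np.stack([s.image for s in samples])
    labels = np.stack([s.labels for s in samples])
    tags = [s.cell_line for s in samples]
    return images, labels, tags


def fcn_target_stacks(images: np.ndarray, labels: np.ndarray, out_side: int) -> np.ndarray:
    """Per-sample (13, out, out) binary target stacks from the green channel."""
    return np.stack(
        [build_training_targets(img[0], lab, out_side) for img, lab in zip(images, labels)]
    )


def run_experiment(
    variant: str,
    sim_config: SimConfig,
    n_samples: int,
    train_count: int,
    net_spec: NetworkSpec,
    train_config: TrainConfig,
    seed: int,
    samples: list[SyntheticSample] | None = None,
) -> ExperimentResult:
    """Simulate, train one variant, calibrate on train, evaluate on test."""
    net_spec.variant = variant
    if samples is None:
        samples = generate_samples(n_samples, sim_config, seed)
    images, labels, tags = samples_to_arrays(samples)

    train_ids, val_ids, test_ids = split_dataset(
        len(samples), train_count, train_config.val_fraction
    )
    if variant == "FCN":
        targets = fcn_target_stacks(images, labels, net_spec.fcn_out_side)
    else:
        targets = labels.astype(float)

    model = build_model(net_spec)
    model, state = train(
        model, TrainData(images, targets, train_ids, val_ids), train_config
    )

    # calibration must only ever see the training block
    calib_ids = np.concatenate([train_ids, val_ids])
    calib_conf = predict_batch(model, images[calib_ids])
    thresholds = calibrate_thresholds(calib_conf, labels[calib_ids])

    train_report = evaluate(
        calib_conf, labels[calib_ids], thresholds, [tags[i] for i in calib_ids]
    )
    test_conf = predict_batch(model, images[test_ids])
    report = evaluate(
        test_conf, labels[test_ids], thresholds, [tags[i] for i in test_ids]
    )
    return ExperimentResult(
        model=model,
        state=state,
        thresholds=thresholds,
        report=report,
        train_report=train_report,
        test_confidences=test_conf,
        test_truths=labels[test_ids],
        test_tags=[tags[i] for i in test_ids],
    )
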