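"""Controlled benchmarking harness: splits, augmentation, factorial run matrix.

The harness wires the normalization strategies, the phantom (or any
manifest-described) datasets and a classifier contract into a factorial
experiment: every (dataset, normalization method, model, seed) combination
is trained and evaluated under identical settings, with patient-level
stratified 80/20 splits, normalization statistics fitted on the training
partition only, and seed-averaged pivot tables as output.

The classifier contract is deliberately thin so heavy CNN backbones can be
plugged in, while the bundled fast implementations (majority-class dummy,
regularized logistic regression on downsampled pixels) keep the test suite
free of any deep-learning runtime.  A reference lightweight CNN (three
conv/ReLU/max-pool stages + two fully connected layers) is available via
:func:`build_lightweight_cnn` when torch is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from radnorm.errors import ContractError, InputError
from radnorm.eval_metrics import confusion, metrics
from radnorm.image_io import DatasetManifest, GrayImage
from radnorm.intensity_norm import (
    DatasetStats,
    NormalizationSpec,
    adaptive_normalize,
    ablation_variant,
    minmax_scale,
    resize_bilinear,
    zscore_apply,
    zscore_fit,
)

__all__ = [
    "ExperimentConfig",
    "ClassifierContract",
    "MajorityClassifier",
    "LogisticPixelClassifier",
    "build_lightweight_cnn",
    "RunResult",
    "ResultsTable",
    "stratified_group_split",
    "balance_classes",
    "augment_geometric",
    "prepare_inputs",
    "train_and_evaluate",
    "run_matrix",
    "ablation_matrix",
    "ABLATION_CONDITIONS",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared hyperparameters for every run (defaults = the benchmark settings)."""

    learning_rate: float = 1e-4
    batch_size: int = 100
    max_epochs: int = 20
    weight_decay: float = 1e-5
    train_fraction: float = 0.8
    seeds: tuple[int, ...] = (42, 123, 456)
    loss: str = "cross-entropy"
    input_size: tuple[int, int] = (256, 256)
    augment: bool = False  # geometric augmentation of the training partition

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ContractError("train_fraction must lie in (0, 1)")
        if self.loss != "cross-entropy":
            raise ContractError("only cross-entropy loss is supported")


class ClassifierContract(Protocol):
    """Minimal interface a pluggable classifier must satisfy.

    Implementations must be deterministic given the rng passed to ``fit``
    and return class-1 probabilities in [0, 1].
    """

    def fit(
        self,
        images: np.ndarray,
        labels: np.ndarray,
        config: ExperimentConfig,
        rng: np.random.Generator,
    ) -> "ClassifierContract": ...

    def predict_proba(self, images: np.ndarray) -> np.ndarray: ...

    def loss(self, images: np.ndarray, labels: np.ndarray) -> float: ...


_EPS = 1e-7


def _cross_entropy(proba: np.ndarray, labels: np.ndarray) -> float:
    p = np.clip(proba, _EPS, 1.0 - _EPS)
    return float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean())


class MajorityClassifier:
    """Predicts the training majority class (ties break to the negative class)."""

    def __init__(self) -> None:
        self._proba = 0.0

    def fit(self, images, labels, config, rng):
        labels = np.asarray(labels)
        self._proba = 1.0 if (labels == 1).sum() > (labels == 0).sum() else 0.0
        return self

    def predict_proba(self, images) -> np.ndarray:
        return np.full(len(images), self._proba)

    def loss(self, images, labels) -> float:
        return _cross_entropy(self.predict_proba(images), np.asarray(labels))


class LogisticPixelClassifier:
    """L2-regularized logistic regression on downsampled pixels.

    The fast deterministic fallback used by the test suite; trains in
    milliseconds on CPU yet picks up the lesion signal of the phantoms.
    """

    def __init__(self, feature_size: tuple[int, int] = (12, 12), C: float = 0.1) -> None:
        self.feature_size = feature_size
        self.C = C
        self._model = None
        self._mu: Optional[np.ndarray] = None
        self._sd: Optional[np.ndarray] = None

    def _features(self, images: np.ndarray) -> np.ndarray:
        h, w = self.feature_size
        feats = np.stack(
            [
                resize_bilinear(GrayImage(img, "standardized"), h, w).pixels.ravel()
                for img in images
            ]
        )
        return feats

    def fit(self, images, labels, config, rng):
        from sklearn.linear_model import LogisticRegression

        X = self._features(images)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        X = (X - self._mu) / self._sd
        self._model = LogisticRegression(
            C=self.C, max_iter=500, random_state=int(rng.integers(2**31))
        )
        self._model.fit(X, np.asarray(labels))
        return self

    def predict_proba(self, images) -> np.ndarray:
        X = (self._features(images) - self._mu) / self._sd
        return self._model.predict_proba(X)[:, 1]

    def loss(self, images, labels) -> float:
        return _cross_entropy(self.predict_proba(images), np.asarray(labels))


def build_lightweight_cnn(**kwargs):
    """Reference ~1.2M-parameter CNN (3x conv/ReLU/max-pool, 2 FC, softmax).

    Requires the optional ``torch`` dependency; the test suite does not use it.
    """
    try:
        from radnorm._torch_cnn import LightweightCNNClassifier
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "build_lightweight_cnn requires torch (pip install radnorm[cnn])"
        ) from exc
    return LightweightCNNClassifier(**kwargs)


# ---------------------------------------------------------------------------
# splitting and class balancing
# ---------------------------------------------------------------------------


def stratified_group_split(
    manifest: DatasetManifest, train_fraction: float, seed: int
) -> tuple[DatasetManifest, DatasetManifest]:
    """Patient-level stratified split into training and validation manifests.

    No patient appears in both partitions; a patient with images of both
    classes is assigned wholly to one side (grouping dominates, stratified by
    the patient's majority label).  Per-class image proportions approximate
    ``train_fraction`` within the granularity patient grouping allows.
    Deterministic given ``seed``.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ContractError("train_fraction must lie in (0, 1)")
    labels = manifest.labels
    patients: dict[str, list[int]] = {}
    for i, rec in enumerate(manifest):
        patients.setdefault(rec.patient_id, []).append(i)

    # feasibility: no single patient may dominate a class beyond the split
    for cls in (0, 1):
        cls_total = int((labels == cls).sum())
        if cls_total == 0:
            continue
        for pid, idxs in patients.items():
            share = sum(1 for i in idxs if labels[i] == cls) / cls_total
            if share > max(train_fraction, 1.0 - train_fraction):
                raise InputError(
                    f"patient {pid!r} holds {share:.0%} of class {cls}; "
                    "stratified patient-level split is infeasible"
                )

    def _patient_label(idxs: list[int]) -> int:
        return int(np.mean([labels[i] for i in idxs]) >= 0.5)

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for cls in (0, 1):
        pids = sorted(p for p, idxs in patients.items() if _patient_label(idxs) == cls)
        if not pids:
            continue
        rng.shuffle(pids)
        cls_images = sum(len(patients[p]) for p in pids)
        target = train_fraction * cls_images
        taken = 0
        for j, pid in enumerate(pids):
            last_must_go_val = j == len(pids) - 1 and not val_idx and len(pids) > 1
            if taken < target and not last_must_go_val:
                train_idx.extend(patients[pid])
                taken += len(patients[pid])
            else:
                val_idx.extend(patients[pid])
    if not train_idx or not val_idx:
        raise InputError("split produced an empty partition; dataset too small")
    return manifest.subset(sorted(train_idx)), manifest.subset(sorted(val_idx))


def balance_classes(manifest: DatasetManifest, seed: int) -> DatasetManifest:
    """Randomly undersample the majority class to a 1:1 ratio (seeded)."""
    labels = manifest.labels
    n0, n1 = int((labels == 0).sum()), int((labels == 1).sum())
    if n0 == n1:
        return manifest
    rng = np.random.default_rng(seed)
    minority = 1 if n1 < n0 else 0
    keep = [i for i, l in enumerate(labels) if l == minority]
    majority_idx = np.array([i for i, l in enumerate(labels) if l != minority])
    keep.extend(rng.choice(majority_idx, size=min(n0, n1), replace=False).tolist())
    return manifest.subset(sorted(keep))


# ---------------------------------------------------------------------------
# geometric augmentation
# ---------------------------------------------------------------------------


def apply_geometric(
    image: GrayImage,
    flip: bool,
    angle_deg: float,
    scale: float,
    shift_frac: tuple[float, float],
) -> GrayImage:
    """Apply flip -> rotate -> scale -> translate in one interpolation pass.

    The combined forward map acts about the image center; out-of-frame
    regions are filled with the image minimum; bilinear interpolation;
    output size unchanged.  Identity parameters reproduce the input exactly.
    """
    px = image.pixels.astype(np.float64)
    h, w = px.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    flip_m = np.diag([1.0, -1.0 if flip else 1.0])
    forward = scale * rot @ flip_m
    shift = np.array([shift_frac[0] * h, shift_frac[1] * w])
    inv = np.linalg.inv(forward)
    offset = center - inv @ (center + shift)
    out = ndimage.affine_transform(
        px, inv, offset=offset, order=1, mode="constant", cval=float(px.min())
    )
    if image.depth == "uint8":
        return GrayImage(np.clip(np.round(out), 0, 255).astype(np.uint8), "uint8")
    if image.depth == "unit":
        return GrayImage(np.clip(out, 0.0, 1.0), "unit")
    return GrayImage(out, "standardized")


def augment_geometric(image: GrayImage, rng: np.random.Generator) -> GrayImage:
    """Random mild geometric augmentation (intensity distribution untouched).

    Independent draws: horizontal flip with probability 0.5, rotation uniform
    in [-7, +7] degrees, isotropic scale uniform in [0.9, 1.1], translation
    uniform in [-5%, +5%] of each image dimension.  No brightness, contrast,
    gamma or intensity jitter is ever applied.
    """
    flip = bool(rng.random() < 0.5)
    angle = float(rng.uniform(-7.0, 7.0))
    scale = float(rng.uniform(0.9, 1.1))
    shift = (float(rng.uniform(-0.05, 0.05)), float(rng.uniform(-0.05, 0.05)))
    return apply_geometric(image, flip, angle, scale, shift)


# ---------------------------------------------------------------------------
# normalization-to-model-input plumbing
# ---------------------------------------------------------------------------


def prepare_inputs(
    manifest: DatasetManifest,
    spec: NormalizationSpec,
    config: ExperimentConfig,
    stats: Optional[DatasetStats] = None,
    augment_rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Normalize and resize every image of a manifest into a model-input stack.

    All methods produce float arrays of ``config.input_size``; uint8-valued
    pipelines (adaptive, crop_only, hist_only) are scaled by 1/255 so model
    inputs share a comparable range.  ``stats`` is required for the zscore
    method and must be fitted on the training partition only.
    """
    spec = replace(spec, output_size=config.input_size)
    h, w = config.input_size
    out = np.empty((len(manifest), h, w), dtype=np.float64)
    for i, rec in enumerate(manifest):
        img = rec.load()
        if augment_rng is not None:
            img = augment_geometric(img, augment_rng)
        if spec.method == "scaling":
            arr = resize_bilinear(minmax_scale(img), h, w).pixels
        elif spec.method == "zscore":
            if stats is None:
                raise ContractError("zscore method requires fitted DatasetStats")
            arr = resize_bilinear(zscore_apply(img, stats), h, w).pixels
        elif spec.method == "adaptive":
            arr = adaptive_normalize(img, spec)[0].pixels / 255.0
        elif spec.method in ("crop_only", "hist_only"):
            arr = ablation_variant(img, spec).pixels / 255.0
        else:  # pragma: no cover - NormalizationSpec already validates
            raise ContractError(f"unknown method {spec.method!r}")
        out[i] = arr
    return out


# ---------------------------------------------------------------------------
# runs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RunResult:
    dataset: str
    method: str
    model: str
    seed: int
    accuracy: float
    f1: float  # NaN when undefined
    loss: float
    sensitivity: float
    specificity: float
    failed: bool = False


@dataclass(frozen=True)
class ResultsTable:
    """Long-form results plus seed-averaged pivots shaped like summary tables."""

    results: pd.DataFrame
    configurations: int

    def pivot(self, metric: str) -> pd.DataFrame:
        return self.results.pivot_table(
            index=["dataset", "model"], columns="method", values=metric, aggfunc="mean"
        )

    @property
    def coverage(self) -> float:
        """Fraction of runs that completed without a failure flag."""
        if self.results.empty:
            return 0.0
        return float(1.0 - self.results["failed"].mean())


def _nan(value: Optional[float]) -> float:
    return float("nan") if value is None else float(value)


def train_and_evaluate(
    train: DatasetManifest,
    val: DatasetManifest,
    classifier: ClassifierContract,
    method: NormalizationSpec,
    config: ExperimentConfig,
    seed: int,
    dataset: str = "dataset",
    model: str = "model",
) -> RunResult:
    """One run: fit normalization artifacts on train, train, evaluate on validation.

    Z-score statistics are computed from the training partition only and
    applied identically to both partitions.  Geometric augmentation (when
    enabled) touches the training images only.  A non-finite validation loss
    flags the run as failed instead of propagating NaNs silently.
    """
    rng = np.random.default_rng(seed)
    stats = zscore_fit(train) if method.method == "zscore" else None
    aug_rng = np.random.default_rng(seed + 1) if config.augment else None
    X_train = prepare_inputs(train, method, config, stats, augment_rng=aug_rng)
    X_val = prepare_inputs(val, method, config, stats)
    y_train, y_val = train.labels, val.labels

    classifier.fit(X_train, y_train, config, rng)
    proba = np.asarray(classifier.predict_proba(X_val), dtype=np.float64)
    loss = classifier.loss(X_val, y_val)
    failed = not np.isfinite(loss) or not np.isfinite(proba).all()
    y_pred = (proba >= 0.5).astype(int)
    m = metrics(confusion(y_val, y_pred))
    return RunResult(
        dataset=dataset,
        method=method.method,
        model=model,
        seed=seed,
        accuracy=_nan(m.accuracy),
        f1=_nan(m.f1),
        loss=float(loss),
        sensitivity=_nan(m.sensitivity),
        specificity=_nan(m.specificity),
        failed=failed,
    )


def _as_specs(methods: Sequence[str | NormalizationSpec]) -> list[NormalizationSpec]:
    specs = [
        m if isinstance(m, NormalizationSpec) else NormalizationSpec(method=m)
        for m in methods
    ]
    names = [s.method for s in specs]
    if len(set(names)) != len(names):
        raise ContractError(f"duplicate methods in the run matrix: {names}")
    return specs


def run_matrix(
    datasets: dict[str, DatasetManifest],
    methods: Sequence[str | NormalizationSpec],
    models: dict[str, Callable[[], ClassifierContract]],
    config: ExperimentConfig = ExperimentConfig(),
) -> ResultsTable:
    """Execute the full factorial |datasets| x |methods| x |models| x |seeds| matrix.

    For each (dataset, seed) the patient-level stratified split is computed
    once and reused by every method and model, so all comparisons are paired.
    A failed run is recorded with its failure flag; ``coverage`` reports the
    completed fraction.
    """
    specs = _as_specs(methods)
    if len(set(datasets)) != len(datasets) or len(set(models)) != len(models):
        raise ContractError("dataset and model names must be unique")
    rows = []
    for ds_name, manifest in datasets.items():
        for seed in config.seeds:
            train, val = stratified_group_split(manifest, config.train_fraction, seed)
            for spec in specs:
                for model_name, factory in models.items():
                    try:
                        res = train_and_evaluate(
                            train, val, factory(), spec, config, seed,
                            dataset=ds_name, model=model_name,
                        )
                    except Exception as exc:  # record, don't abort the matrix
                        res = RunResult(
                            dataset=ds_name, method=spec.method, model=model_name,
                            seed=seed, accuracy=float("nan"), f1=float("nan"),
                            loss=float("nan"), sensitivity=float("nan"),
                            specificity=float("nan"), failed=True,
                        )
                    rows.append(res.__dict__)
    df = pd.DataFrame(rows)
    n_config = len(datasets) * len(specs) * len(models)
    return ResultsTable(results=df, configurations=n_config)


#: Ablation conditions: (condition tag, method, uses cropping, uses histogram)
ABLATION_CONDITIONS = (
    ("A", "zscore", False, False),
    ("B", "crop_only", True, False),
    ("C", "hist_only", False, True),
    ("D", "adaptive", True, True),
)


def ablation_matrix(
    dataset: DatasetManifest,
    model_factory: Callable[[], ClassifierContract],
    config: ExperimentConfig = ExperimentConfig(),
    dataset_name: str = "dataset",
    model_name: str = "model",
) -> pd.DataFrame:
    """Four-condition ablation report (A: zscore, B: crop, C: histogram, D: full).

    Returns one row per condition with component indicator columns and the
    seed-averaged F1.
    """
    table = run_matrix(
        {dataset_name: dataset},
        [cond[1] for cond in ABLATION_CONDITIONS],
        {model_name: model_factory},
        config,
    )
    mean_f1 = table.results.groupby("method")["f1"].mean()
    mean_acc = table.results.groupby("method")["accuracy"].mean()
    rows = [
        {
            "condition": tag,
            "method": method,
            "cropping": crop,
            "histogram": hist,
            "f1": float(mean_f1[method]),
            "accuracy": float(mean_acc[method]),
        }
        for tag, method, crop, hist in ABLATION_CONDITIONS
    ]
    return pd.DataFrame(rows)
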