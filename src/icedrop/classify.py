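"""Frozen/liquid droplet classification.

Two classifiers with one output contract (a :class:`Label` per droplet crop):

* **Polarized dual-threshold** — the droplet-disk intensity statistic is
  compared against two calibrated thresholds.  Frozen droplets that glow
  between crossed polarizers exceed the high threshold; frozen droplets that
  appear darker than liquid (unfavourably oriented crystal planes) fall below
  the low threshold.  Recalescent slush sits between the two and is scored
  liquid — a known, reproducible undercounting mode of this method.

* **Trainable image classifier** — a two-class model on fixed texture and
  shape features of the bright-field crop (gradient-boosted trees by default,
  logistic regression as an alternative backend), trained per experiment on
  crops from the warmest (all-liquid) and coldest (all-frozen) videos and
  applied to the intermediate temperatures.

:func:`compare_methods` reports the agreement statistics used to benchmark the
automated methods against a reference labelling (accuracy and the frozen-count
ratio, whose ideal value is 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy import ndimage as ndi
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .exceptions import InseparableClassesError

__all__ = [
    "Label",
    "ThresholdPair",
    "TrainConfig",
    "ClassifierModel",
    "AgreementReport",
    "disk_statistic",
    "calibrate_thresholds",
    "classify_threshold",
    "crop_features",
    "train_classifier",
    "classify_batch",
    "compare_methods",
]

#: Ratio of the crop side to the droplet diameter used when crops were cut.
CROP_FACTOR = 2.5


@dataclass(frozen=True)
class Label:
    """A frozen/liquid call with the classifier's class score."""

    value: str  # "frozen" | "liquid"
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.value not in ("frozen", "liquid"):
            raise ValueError(f"invalid label {self.value!r}")
        if not 0 <= self.confidence <= 1:
            raise ValueError("confidence outside [0, 1]")


@dataclass(frozen=True)
class ThresholdPair:
    """Calibrated intensity thresholds on the droplet-disk statistic.

    ``low == 0`` disables the lower (dark-frozen) test.
    """

    low: float
    high: float
    statistic: str = "mean_disk"

    def __post_init__(self) -> None:
        if not 0 <= self.low <= self.high <= 1:
            raise ValueError("need 0 <= low <= high <= 1")
        if self.statistic not in ("mean_disk", "max_disk"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


def _disk_mask(side: int, crop_factor: float = CROP_FACTOR) -> np.ndarray:
    radius = side / (2.0 * crop_factor)
    ax = np.arange(side) - (side - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    return np.hypot(xx, yy) <= radius


def disk_statistic(crop: np.ndarray, statistic: str = "mean_disk") -> float:
    """Aggregate intensity inside the droplet disk of a centred crop.

    The mask covers only the droplet disk at the crop centre, so the statistic
    is independent of where in the original frame the droplet was.
    """
    mask = _disk_mask(crop.shape[0])
    vals = crop[mask]
    if statistic == "mean_disk":
        return float(vals.mean())
    if statistic == "max_disk":
        return float(vals.max())
    raise ValueError(f"unknown statistic {statistic!r}")


def calibrate_thresholds(
    liquid_crops: Sequence[np.ndarray],
    frozen_bright_crops: Sequence[np.ndarray],
    frozen_dark_crops: Sequence[np.ndarray] | None = None,
    statistic: str = "mean_disk",
    min_refs: int = 20,
    min_accuracy: float = 0.95,
) -> ThresholdPair:
    """Place the two thresholds between the reference intensity distributions.

    The high threshold is the midpoint between the 99th percentile of the
    liquid statistic and the 1st percentile of the bright-frozen statistic;
    the low threshold mirrors this against dark-frozen references (disabled if
    none are given).  Calibration errors out loudly when the distributions
    overlap or when re-classifying the references is less than
    ``min_accuracy`` correct.
    """
    if len(liquid_crops) < min_refs or len(frozen_bright_crops) < min_refs:
        raise ValueError(f"need at least {min_refs} liquid and bright-frozen crops")
    s_liq = np.array([disk_statistic(c, statistic) for c in liquid_crops])
    s_bri = np.array([disk_statistic(c, statistic) for c in frozen_bright_crops])

    liq_hi = float(np.percentile(s_liq, 99))
    bri_lo = float(np.percentile(s_bri, 1))
    if bri_lo <= liq_hi:
        raise InseparableClassesError(
            "liquid and bright-frozen intensity distributions overlap"
        )
    high = 0.5 * (liq_hi + bri_lo)

    low = 0.0
    if frozen_dark_crops is not None and len(frozen_dark_crops) > 0:
        s_dark = np.array([disk_statistic(c, statistic) for c in frozen_dark_crops])
        liq_lo = float(np.percentile(s_liq, 1))
        dark_hi = float(np.percentile(s_dark, 99))
        if dark_hi >= liq_lo:
            raise InseparableClassesError(
                "liquid and dark-frozen intensity distributions overlap"
            )
        low = 0.5 * (liq_lo + dark_hi)

    pair = ThresholdPair(low=low, high=high, statistic=statistic)
    # self-check on the calibration sets
    n_ok = sum(classify_threshold(c, pair).value == "liquid" for c in liquid_crops)
    n_ok += sum(classify_threshold(c, pair).value == "frozen" for c in frozen_bright_crops)
    n_tot = len(liquid_crops) + len(frozen_bright_crops)
    if frozen_dark_crops is not None and len(frozen_dark_crops) > 0:
        n_ok += sum(
            classify_threshold(c, pair).value == "frozen" for c in frozen_dark_crops
        )
        n_tot += len(frozen_dark_crops)
    if n_ok / n_tot < min_accuracy:
        raise InseparableClassesError(
            f"calibration self-check accuracy {n_ok / n_tot:.3f} below {min_accuracy}"
        )
    return pair


def classify_threshold(crop: np.ndarray, thresholds: ThresholdPair) -> Label:
    """Frozen iff the disk statistic strictly exceeds the high threshold or
    falls strictly below the enabled low threshold; ties are scored liquid."""
    s = disk_statistic(crop, thresholds.statistic)
    frozen = s > thresholds.high or (thresholds.low > 0 and s < thresholds.low)
    return Label("frozen" if frozen else "liquid", 1.0)


# ---------------------------------------------------------------------------
# Trainable classifier
# ---------------------------------------------------------------------------


def crop_features(crop: np.ndarray) -> np.ndarray:
    """Fixed texture/shape feature vector of a normalized droplet crop.

    Captures the cues separating liquid from frozen droplets in bright field:
    smooth bright interior vs speckled texture, regular dark rim vs irregular
    boundary.  All features are computed relative to crop geometry, so they are
    position-independent by construction.
    """
    side = crop.shape[0]
    radius = side / (2.0 * CROP_FACTOR)
    ax = np.arange(side) - (side - 1) / 2.0
    xx, yy = np.meshgrid(ax, ax)
    r = np.hypot(xx, yy)
    disk = r <= radius
    interior = r <= 0.6 * radius
    annulus = (r > 0.75 * radius) & (r <= 1.1 * radius)
    bg = r > 1.8 * radius

    smooth = ndi.uniform_filter(crop, size=3)
    highfreq = np.abs(crop - smooth)

    d = crop[disk]
    i = crop[interior]
    a = crop[annulus]
    b = crop[bg]
    return np.array(
        [
            d.mean(),
            d.std(),
            i.mean(),
            i.std(),
            a.mean(),
            float(np.percentile(d, 90) - np.percentile(d, 10)),
            i.mean() - a.mean(),
            d.mean() - b.mean(),
            highfreq[disk].mean(),
            highfreq[disk].std(),
            highfreq[bg].mean(),
        ],
        dtype=np.float64,
    )


@dataclass
class TrainConfig:
    """Training configuration for the per-experiment classifier.

    The default backend is a regularized logistic regression on standardized
    features: with a few hundred well-separated training crops it weighs every
    texture/contrast cue instead of keying on whichever single feature happens
    to split the training set, which makes it markedly more robust to the
    small crop-scale variation introduced by detection radius errors.
    Gradient-boosted trees are available as ``backend="gbm"``.
    """

    backend: str = "logreg"  # "logreg" | "gbm"
    min_raw_per_class: int = 10
    target_per_class: int = 150  # augmented up to this many per class
    holdout_fraction: float = 0.2
    augment: bool = True


@dataclass
class ClassifierModel:
    """A trained two-class droplet classifier plus its training metadata."""

    estimator: object
    input_side: int
    metadata: dict = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump({"estimator": self.estimator, "input_side": self.input_side}, path)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(self.metadata, indent=2)
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        path = Path(path)
        blob = joblib.load(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        return cls(estimator=blob["estimator"], input_side=blob["input_side"], metadata=meta)


def _augment(
    crops: list[np.ndarray], target: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Flips along the flow axis, small shifts, scale and intensity jitter.

    The scale jitter (±8 %) mimics the crop-side variation caused by droplet
    radius estimation errors during detection, so the classifier cannot rely
    on an exact droplet-to-crop size ratio.
    """
    out = list(crops)
    while len(out) < target:
        base = crops[int(rng.integers(len(crops)))]
        aug = base[:, ::-1] if rng.random() < 0.5 else base
        side = aug.shape[0]
        zoom = rng.uniform(0.92, 1.08)
        center = (side - 1) / 2.0
        matrix = np.array([[1.0 / zoom, 0.0], [0.0, 1.0 / zoom]])
        offset = center - matrix @ np.array([center, center])
        aug = ndi.affine_transform(
            aug, matrix, offset=offset, order=1, mode="nearest"
        )
        shift = rng.integers(-2, 3, size=2)
        aug = ndi.shift(aug, shift, mode="nearest", order=1)
        aug = aug * rng.uniform(0.95, 1.05) + rng.uniform(-0.02, 0.02)
        out.append(np.clip(aug, 0.0, 1.0).astype(np.float32))
    return out


def train_classifier(
    liquid_crops: Sequence[np.ndarray],
    frozen_crops: Sequence[np.ndarray],
    seed: int = 0,
    config: TrainConfig | None = None,
) -> ClassifierModel:
    """Train the per-experiment frozen/liquid classifier.

    Training crops must come from videos recorded far from the transition
    (expected frozen fraction 0 or 1), so that video-level temperature implies
    the crop label.  Augmentation (flips, shifts, jitter) balances and pads
    each class up to ``target_per_class``.  A stratified 20 % held-out split's
    accuracy is stored in the model metadata.  Deterministic for a given seed.
    """
    cfg = config or TrainConfig()
    if len(liquid_crops) == 0 or len(frozen_crops) == 0:
        raise ValueError("both classes must be represented in the training crops")
    if (
        len(liquid_crops) < cfg.min_raw_per_class
        or len(frozen_crops) < cfg.min_raw_per_class
    ):
        raise ValueError(
            f"need at least {cfg.min_raw_per_class} raw crops per class"
        )
    side = liquid_crops[0].shape[0]
    rng = np.random.default_rng(seed)
    liq = list(liquid_crops)
    fro = list(frozen_crops)
    if cfg.augment:
        # at least half of each training class consists of jittered variants
        liq = _augment(liq, max(cfg.target_per_class, 2 * len(liq)), rng)
        fro = _augment(fro, max(cfg.target_per_class, 2 * len(fro)), rng)
    elif len(liq) < 100 or len(fro) < 100:
        raise ValueError("need >= 100 crops per class when augmentation is off")

    x = np.array([crop_features(c) for c in liq + fro])
    y = np.array([0] * len(liq) + [1] * len(fro))  # 1 = frozen
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=cfg.holdout_fraction, stratify=y, random_state=seed % 2**31
    )
    if cfg.backend == "gbm":
        est = HistGradientBoostingClassifier(random_state=seed % 2**31)
    elif cfg.backend == "logreg":
        est = make_pipeline(StandardScaler(), LogisticRegression(max_iter=1000))
    else:
        raise ValueError(f"unknown backend {cfg.backend!r}")
    est.fit(x_tr, y_tr)
    acc = float((est.predict(x_te) == y_te).mean())
    meta = {
        "seed": int(seed),
        "backend": cfg.backend,
        "n_train_liquid": int(len(liq)),
        "n_train_frozen": int(len(fro)),
        "n_raw_liquid": int(len(liquid_crops)),
        "n_raw_frozen": int(len(frozen_crops)),
        "holdout_accuracy": acc,
        "input_side": int(side),
    }
    return ClassifierModel(estimator=est, input_side=side, metadata=meta)


def classify_batch(
    model: ClassifierModel, crops: Sequence[np.ndarray]
) -> list[Label]:
    """Score a batch of crops; confidence is the winning-class probability."""
    if len(crops) == 0:
        return []
    for c in crops:
        if c.shape != (model.input_side, model.input_side):
            raise ValueError(
                f"crop shape {c.shape} does not match model input side {model.input_side}"
            )
    x = np.array([crop_features(c) for c in crops])
    proba = model.estimator.predict_proba(x)
    out = []
    for p in proba:
        frozen = p[1] > 0.5
        out.append(
            Label("frozen" if frozen else "liquid", float(p[1] if frozen else p[0]))
        )
    return out


# ---------------------------------------------------------------------------
# Method agreement
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of a detection method against a reference labelling."""

    accuracy: float
    frozen_count_ratio: float  # predicted frozen / reference frozen; ideal 1
    n: int
    tp: int  # frozen called frozen
    fp: int  # liquid called frozen
    fn: int  # frozen called liquid
    tn: int  # liquid called liquid

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "frozen_count_ratio": self.frozen_count_ratio,
            "n": self.n,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
        }


def _values(labels: Sequence) -> list[str]:
    return [l.value if isinstance(l, Label) else str(l) for l in labels]


def compare_methods(pred: Sequence, ref: Sequence) -> AgreementReport:
    """Accuracy, confusion counts and the frozen-count ratio of two label sets.

    Inputs must be aligned droplet-by-droplet.  The ratio is undefined (NaN)
    when the reference contains no frozen droplets.
    """
    p = _values(pred)
    r = _values(ref)
    if len(p) != len(r):
        raise ValueError(f"length mismatch: {len(p)} predictions vs {len(r)} references")
    if len(p) == 0:
        raise ValueError("empty label sets")
    tp = sum(a == "frozen" and b == "frozen" for a, b in zip(p, r))
    fp = sum(a == "frozen" and b == "liquid" for a, b in zip(p, r))
    fn = sum(a == "liquid" and b == "frozen" for a, b in zip(p, r))
    tn = sum(a == "liquid" and b == "liquid" for a, b in zip(p, r))
    n = len(p)
    ref_frozen = tp + fn
    ratio = (tp + fp) / ref_frozen if ref_frozen > 0 else math.nan
    return AgreementReport(
        accuracy=(tp + tn) / n,
        frozen_count_ratio=ratio,
        n=n,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
    )
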