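"""End-to-end experiment orchestration: simulate/load → detect → classify → curve.

An :class:`ExperimentConfig` describes a freezing-curve experiment: the
temperature list, where each temperature's video comes from (a multi-page TIFF
path or the built-in simulator), the classification method, droplet volume and
INP concentration, and the seeds.  :func:`run_experiment` executes every stage,
returns the assembled results and writes CSV/JSON/PNG outputs plus a manifest
that reconciles per-stage counts, so a rerun with an identical config is
byte-identical.

The trainable classifier is retrained per experiment from the two extreme
temperature videos (expected frozen fraction 0 and 1); the threshold method is
calibrated per experiment from reference crops taken from the same two videos.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analyze, classify, detect, inpmodel, synthdrop
from .classify import ClassifierModel, Label, ThresholdPair
from .detect import DetectParams
from .exceptions import ConfigError
from .inpmodel import INPPopulation, expected_frozen_fraction, population_nm
from .synthdrop import FrameStack

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_experiment",
    "import_manual_labels",
    "compare_curves",
    "label_stack",
    "reference_crops_from_extremes",
]

log = logging.getLogger("icedrop")


@dataclass
class ExperimentConfig:
    """Configuration of one freezing-curve experiment."""

    temperatures: list[float]
    n_droplets: int = 500
    method: str = "ml"  # "ml" | "threshold"
    mode: str | None = None  # default: brightfield for ml, polarized for threshold
    analyzer_angle: float = 60.0
    train_warm_c: float = -2.0
    train_cold_c: float = -11.0
    train_n_droplets: int = 300
    population: INPPopulation | None = None  # default Snomax-like A/B/C model
    treatment: str | None = None  # preset name applied to the population
    diameter_um: float = 75.0
    cm_mg_per_ml: float = 1.0
    fps: float = 150.0
    velocity_um_s: float = 12000.0
    noise_sd: float = 2.5
    subtype_mix: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    out_dir: str | None = None
    videos: dict[float, str] = field(default_factory=dict)  # T -> TIFF path

    def __post_init__(self) -> None:
        if not self.temperatures:
            raise ConfigError("no temperatures configured")
        if len(set(self.temperatures)) != len(self.temperatures):
            raise ConfigError("temperatures must be distinct")
        if self.method not in ("ml", "threshold"):
            raise ConfigError(f"unknown method {self.method!r}")
        if self.mode is None:
            self.mode = "brightfield" if self.method == "ml" else "polarized"
        if self.mode not in ("brightfield", "polarized"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.population is None:
            self.population = inpmodel.default_population()
        for t, path in self.videos.items():
            if not Path(path).exists():
                raise ConfigError(f"video for T={t} not found: {path}")

    @property
    def v_ml(self) -> float:
        return inpmodel.sphere_volume_ml(self.diameter_um)

    def effective_population(self) -> INPPopulation:
        pop = self.population
        if self.treatment is not None:
            pop = inpmodel.apply_treatment(pop, inpmodel.treatment_preset(self.treatment))
        return pop

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "population" in raw and isinstance(raw["population"], dict):
            raw["population"] = INPPopulation.from_dict(raw["population"])
        if "subtype_mix" in raw:
            raw["subtype_mix"] = tuple(raw["subtype_mix"])
        if "videos" in raw:
            raw["videos"] = {float(k): v for k, v in raw["videos"].items()}
        return cls(**raw)

    def to_manifest_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"] = self.population.to_dict()
        return d


@dataclass
class ExperimentResult:
    curve: inpmodel.FreezingCurve
    spectrum: pd.DataFrame
    onset_c: float | None
    labels: pd.DataFrame  # per droplet: temperature, track id, label, confidence
    manifest: dict


def _simulate(config: ExperimentConfig, t: float, n: int, seed: int, p_frozen=None):
    return synthdrop.simulate_video(
        t,
        n,
        config.mode,
        p_frozen=p_frozen,
        population=None if p_frozen is not None else config.effective_population(),
        analyzer_angle=config.analyzer_angle,
        fps=config.fps,
        velocity_um_s=config.velocity_um_s,
        noise_sd=config.noise_sd,
        seed=seed,
        subtype_mix=config.subtype_mix,
        nominal_diameter_um=config.diameter_um,
        cm_mg_per_ml=config.cm_mg_per_ml,
    )


def reference_crops_from_extremes(
    warm_crops: list[np.ndarray], cold_crops: list[np.ndarray]
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Sort extreme-temperature crops into threshold-calibration references.

    The warm (all-liquid) video supplies liquid references.  Crops from the
    cold (all-frozen) video are split by their disk statistic relative to the
    liquid distribution: clearly brighter → bright-frozen references, clearly
    darker → dark-frozen references.  Ambiguous crops (weakly birefringent
    slush) are discarded, mimicking how a user would curate reference images.
    """
    s_liq = np.array([classify.disk_statistic(c) for c in warm_crops])
    liq_hi, liq_lo = np.percentile(s_liq, [99, 1])
    margin = max(0.02, 2.0 * s_liq.std())
    bright, dark = [], []
    for c in cold_crops:
        s = classify.disk_statistic(c)
        if s > liq_hi + margin:
            bright.append(c)
        elif s < liq_lo - margin / 2.0:
            dark.append(c)
    return list(warm_crops), bright, dark


def label_stack(
    stack: FrameStack,
    method: str,
    model: ClassifierModel | None = None,
    thresholds: ThresholdPair | None = None,
    params: DetectParams | None = None,
):
    """Detect, track and classify one stack; returns (tracks, crops, labels)."""
    tracks, crops = detect.process_stack(stack, params)
    if method == "ml":
        if model is None:
            raise ConfigError("method 'ml' needs a trained model")
        labels = classify.classify_batch(model, crops)
    else:
        if thresholds is None:
            raise ConfigError("method 'threshold' needs calibrated thresholds")
        labels = [classify.classify_threshold(c, thresholds) for c in crops]
    return tracks, crops, labels


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Execute the full pipeline for every configured temperature."""
    params = DetectParams(velocity_um_s=config.velocity_um_s)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    pop = config.effective_population()
    v_ml = config.v_ml

    def next_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    # --- training / calibration stage ---------------------------------------
    f_warm = expected_frozen_fraction(
        population_nm(pop, config.train_warm_c), v_ml, config.cm_mg_per_ml
    )
    f_cold = expected_frozen_fraction(
        population_nm(pop, config.train_cold_c), v_ml, config.cm_mg_per_ml
    )
    if f_warm > 0.01 or f_cold < 0.99:
        raise ConfigError(
            "training temperatures must have expected frozen fraction 0 and 1 "
            f"(got f({config.train_warm_c})={f_warm:.3f}, "
            f"f({config.train_cold_c})={f_cold:.3f})"
        )
    seed_warm, seed_cold = next_seed(), next_seed()
    warm_stack, _ = _simulate(config, config.train_warm_c, config.train_n_droplets, seed_warm, p_frozen=0.0)
    cold_stack, _ = _simulate(config, config.train_cold_c, config.train_n_droplets, seed_cold, p_frozen=1.0)
    _, warm_crops = detect.process_stack(warm_stack, params)
    _, cold_crops = detect.process_stack(cold_stack, params)
    log.info(
        "training videos: %d liquid crops (T=%.1f), %d frozen crops (T=%.1f)",
        len(warm_crops), config.train_warm_c, len(cold_crops), config.train_cold_c,
    )

    model: ClassifierModel | None = None
    thresholds: ThresholdPair | None = None
    seed_train = next_seed()
    if config.method == "ml":
        model = classify.train_classifier(warm_crops, cold_crops, seed=seed_train)
        log.info("classifier held-out accuracy: %.4f", model.metadata["holdout_accuracy"])
    else:
        liq_ref, bright_ref, dark_ref = reference_crops_from_extremes(
            warm_crops, cold_crops
        )
        thresholds = classify.calibrate_thresholds(
            liq_ref, bright_ref, dark_ref if dark_ref else None
        )
        log.info("thresholds: low=%.3f high=%.3f", thresholds.low, thresholds.high)

    # --- per-temperature stage -----------------------------------------------
    points: list[inpmodel.TemperaturePoint] = []
    label_rows = []
    stage_counts = {}
    temp_seeds = {}
    for t in config.temperatures:
        seed_t = next_seed()
        temp_seeds[t] = seed_t
        if t in config.videos:
            stack = FrameStack.load_tiff(config.videos[t])
        else:
            stack, _ = _simulate(config, t, config.n_droplets, seed_t)
        tracks, crops, labels = label_stack(
            stack, config.method, model=model, thresholds=thresholds, params=params
        )
        for tr, lab in zip(tracks, labels):
            label_rows.append(
                {
                    "temperature_c": t,
                    "droplet_id": tr.track_id,
                    "label": lab.value,
                    "confidence": lab.confidence,
                    "method": config.method,
                }
            )
        pt = analyze.temperature_point(labels, t)
        points.append(pt)
        stage_counts[str(t)] = {
            "frames": stack.n_frames,
            "tracks": len(tracks),
            "classified": len(labels),
            "frozen": pt.nf,
        }
        log.info("T=%.2f C: %d droplets, %d frozen (f=%.3f)", t, pt.n, pt.nf, pt.f)

    curve = analyze.build_curve(points, v_ml, config.cm_mg_per_ml)
    spectrum = analyze.nm_spectrum(curve)
    try:
        onset = analyze.onset_temperature(curve)
    except Exception:
        onset = None

    labels_df = pd.DataFrame(
        label_rows,
        columns=["temperature_c", "droplet_id", "label", "confidence", "method"],
    )
    manifest = {
        "config": config.to_manifest_dict(),
        "derived_seeds": {
            "train_warm": seed_warm,
            "train_cold": seed_cold,
            "train": seed_train,
            "temperatures": {str(t): s for t, s in temp_seeds.items()},
        },
        "stage_counts": stage_counts,
        "onset_c": onset,
    }
    if config.method == "ml":
        manifest["classifier"] = model.metadata
    else:
        manifest["thresholds"] = {"low": thresholds.low, "high": thresholds.high}

    result = ExperimentResult(
        curve=curve, spectrum=spectrum, onset_c=onset, labels=labels_df, manifest=manifest
    )
    if config.out_dir is not None:
        _write_outputs(config, result)
    return result


def _write_outputs(config: ExperimentConfig, result: ExperimentResult) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve_csv = out / "curve.csv"
    result.curve.to_csv(curve_csv)
    result.spectrum.to_csv(out / "nm_spectrum.csv", index=False)
    result.labels.to_csv(out / "labels.csv", index=False)
    analyze.plot_freezing_curves({"experiment": result.curve}, out / "freezing_curve.png")
    analyze.plot_nm_spectra({"experiment": result.curve}, out / "nm_spectrum.png")
    result.manifest["curve_csv_sha256"] = hashlib.sha256(
        curve_csv.read_bytes()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2))


def import_manual_labels(path: str | Path, track_ids: list[int]) -> list[Label]:
    """Read a droplet_id,label CSV and align it to the given track ids.

    Used to bring manually counted reference labels into
    :func:`icedrop.classify.compare_methods`.
    """
    df = pd.read_csv(path)
    if not {"droplet_id", "label"} <= set(df.columns):
        raise ValueError("manual label CSV needs droplet_id and label columns")
    bad = sorted(set(df.label) - {"frozen", "liquid"})
    if bad:
        raise ValueError(f"malformed labels: {bad}")
    by_id = dict(zip(df.droplet_id.astype(int), df.label))
    unknown = sorted(set(by_id) - set(track_ids))
    missing = sorted(set(track_ids) - set(by_id))
    if unknown or missing:
        raise ValueError(
            f"label/track id mismatch; unknown ids {unknown[:10]}, missing ids {missing[:10]}"
        )
    return [Label(by_id[t], 1.0) for t in track_ids]


def compare_curves(
    curve_a: inpmodel.FreezingCurve,
    curve_b: inpmodel.FreezingCurve,
    f_match: float = 0.5,
    f_on: float = 0.05,
) -> dict:
    """Onsets of two curves and their temperature shift at a matched fraction."""
    report = {
        "onset_a_c": analyze.onset_temperature(curve_a, f_on),
        "onset_b_c": analyze.onset_temperature(curve_b, f_on),
        "f_match": f_match,
        "shift_c": analyze.curve_shift(curve_a, curve_b, f_match),
    }
    report["onset_decrease_c"] = report["onset_a_c"] - report["onset_b_c"]
    return report
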