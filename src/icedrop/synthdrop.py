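"""Synthetic bright-field and polarized freezing videos with per-droplet ground truth.

The generator emulates a flow-through droplet freezing assay as seen by a
high-speed camera: a 128 x 256 px region of interest over the flow channel,
monodisperse 70-85 um droplets (~36-44 px at the default 1.953 um/px scale)
advected at near-constant velocity along the channel axis, and a static
background with a mild illumination gradient and an off-center sensor-trace
stripe.

Droplet appearance follows the morphologies seen in such assays:

* bright field, liquid   — smooth disk, bright center, dark rim;
* bright field, frozen   — speckle-textured interior, irregular rim (all
  frozen subtypes are plainly textured in bright field);
* polarized, liquid      — lensing contrast that scales with how far the
  analyzer is rotated away from full extinction (invisible at 90 deg);
* polarized, frozen      — three subtypes: ``frozen_bright`` (birefringence
  makes the disk glow, with a random per-droplet gain), ``frozen_dark``
  (crystal planes oriented so the polarization is not rotated; the droplet
  stays at or below background) and ``recalescent`` (ice-water slush that is
  almost indistinguishable from liquid between polarizers).

The latter two subtypes exist so that the known undercounting failure mode of
polarized intensity thresholding is reproducible on synthetic data.

Desk-scale defaults (hundreds of droplets per video, ~150 fps-equivalent
sampling) keep simulation and detection fast; full-scale acquisition (3000 fps,
thousands of droplets per video) is reachable through the same parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import inpmodel
from .inpmodel import INPPopulation, expected_frozen_fraction, population_nm

__all__ = [
    "FrameStack",
    "TruthDroplet",
    "SceneTruth",
    "RenderParams",
    "render_droplet",
    "simulate_video",
    "export_truth",
    "write_truth_jsonl",
    "read_truth_jsonl",
    "DROPLET_STATES",
    "FROZEN_STATES",
]

DROPLET_STATES = ("liquid", "frozen_bright", "frozen_dark", "recalescent")
FROZEN_STATES = ("frozen_bright", "frozen_dark", "recalescent")

#: Default camera scale: 250 um ROI height over 128 px.
DEFAULT_SCALE_UM_PER_PX = 250.0 / 128.0


@dataclass
class RenderParams:
    """Intensity palette of the renderer (8-bit scale).

    Bright-field levels place the liquid interior well above the background and
    the rim well below it; frozen interiors carry speckle with a standard
    deviation many times the liquid interior's, which is the texture cue the
    trainable classifier exploits.  ``class_contrast`` in [0, 1] blends frozen
    renderings toward the liquid appearance (1 = nominal, 0 = frozen droplets
    look exactly like liquid ones) and exists for classifier stress tests.
    """

    # bright-field background and droplets
    bf_background: float = 120.0
    bf_liquid_center: float = 185.0
    bf_liquid_falloff: float = 35.0
    bf_rim_level: float = 45.0
    bf_frozen_interior: float = 140.0
    bf_frozen_rim: float = 60.0
    bf_speckle_sd: float = 35.0
    bf_recalescent_speckle_sd: float = 25.0
    rim_start: float = 0.78  # rim begins at this fraction of the radius
    boundary_roughness: float = 0.05  # angular modulation of frozen rims
    # polarized background and droplets
    pol_background_open: float = 20.0  # analyzer rotated away from extinction
    pol_background_extinct: float = 4.0  # analyzer at 90 deg
    pol_vis_ramp_deg: float = 5.0  # degrees below 90 over which liquid fades in
    pol_liquid_gain: float = 0.55  # lensing contrast relative to background
    pol_gain_range: tuple[float, float] = (110.0, 210.0)  # birefringence gain
    pol_bright_speckle_sd: float = 8.0
    pol_dark_factor: float = 0.6  # dark-frozen dimming relative to background
    pol_recalescent_speckle_sd: float = 5.0
    class_contrast: float = 1.0

    def pol_background(self, analyzer_angle: float) -> float:
        vis = self.liquid_visibility(analyzer_angle)
        return self.pol_background_extinct + vis * (
            self.pol_background_open - self.pol_background_extinct
        )

    def liquid_visibility(self, analyzer_angle: float) -> float:
        """0 at full extinction (90 deg), 1 once the analyzer is backed off."""
        return float(np.clip((90.0 - analyzer_angle) / self.pol_vis_ramp_deg, 0.0, 1.0))


@dataclass
class FrameStack:
    """An ordered grayscale frame sequence with acquisition metadata."""

    frames: np.ndarray  # (n_frames, height, width) uint8
    mode: str  # "brightfield" | "polarized"
    analyzer_angle: float  # degrees, meaningful in polarized mode
    fps: float
    scale_um_per_px: float
    temperature_c: float
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be (n, h, w)")
        if self.mode not in ("brightfield", "polarized"):
            raise ValueError(f"unknown imaging mode {self.mode!r}")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if not 0 <= self.analyzer_angle <= 90:
            raise ValueError("analyzer angle must lie in [0, 90] degrees")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def save_tiff(self, path: str | Path) -> None:
        meta = {
            "mode": self.mode,
            "analyzer_angle": self.analyzer_angle,
            "fps": self.fps,
            "scale_um_per_px": self.scale_um_per_px,
            "temperature_c": self.temperature_c,
            "seed": self.seed,
        }
        tifffile.imwrite(str(path), self.frames, description=json.dumps(meta))

    @classmethod
    def load_tiff(cls, path: str | Path) -> "FrameStack":
        with tifffile.TiffFile(str(path)) as tif:
            frames = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if frames.ndim == 2:
            frames = frames[None]
        return cls(frames=frames, **meta)


@dataclass
class TruthDroplet:
    """Ground truth for one droplet traversing the ROI at constant velocity."""

    droplet_id: int
    state: str  # one of DROPLET_STATES
    diameter_px: float
    x0: float  # centroid x at frame 0 (flow axis, px)
    y: float  # centroid y, constant (px)
    step_px: float  # displacement per frame along the flow axis
    entry_frame: int
    exit_frame: int

    @property
    def label(self) -> str:
        """Binary ground-truth label: every frozen subtype counts as frozen."""
        return "frozen" if self.state in FROZEN_STATES else "liquid"

    def centroid_at(self, frame: int) -> tuple[float, float]:
        return (self.x0 + frame * self.step_px, self.y)


@dataclass
class SceneTruth:
    """All ground truth of one simulated video."""

    droplets: list[TruthDroplet]
    background: np.ndarray  # noiseless static background (float32)
    frame_shape: tuple[int, int]
    n_frames: int

    def labels(self) -> pd.DataFrame:
        return export_truth(self)

    def frozen_fraction(self) -> float:
        if not self.droplets:
            raise ZeroDivisionError("empty scene")
        return sum(d.label == "frozen" for d in self.droplets) / len(self.droplets)


def export_truth(truth: SceneTruth) -> pd.DataFrame:
    """One row per droplet: id, morphological state and binary label."""
    return pd.DataFrame(
        [
            {
                "droplet_id": d.droplet_id,
                "state": d.state,
                "label": d.label,
                "diameter_px": d.diameter_px,
                "entry_frame": d.entry_frame,
            }
            for d in truth.droplets
        ],
        columns=["droplet_id", "state", "label", "diameter_px", "entry_frame"],
    )


def write_truth_jsonl(truth: SceneTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d in truth.droplets:
            fh.write(json.dumps(asdict(d)) + "\n")


def read_truth_jsonl(path: str | Path) -> list[TruthDroplet]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(TruthDroplet(**json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _grids(diameter_px: float, roughness: float):
    """Radial/angular grids for a patch comfortably containing the droplet."""
    half = int(math.ceil(diameter_px / 2.0 * (1.0 + 3.0 * roughness))) + 1
    ax = np.arange(-half, half + 1, dtype=np.float32)
    xx, yy = np.meshgrid(ax, ax)
    r = np.hypot(xx, yy) / (diameter_px / 2.0)
    theta = np.arctan2(yy, xx)
    return r, theta


def _angular_modulation(theta: np.ndarray, rng: np.random.Generator, amp: float) -> np.ndarray:
    """Smooth random radial modulation giving frozen droplets irregular rims."""
    w = np.zeros_like(theta)
    for k in range(2, 6):
        a = rng.normal(0.0, amp)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        w += a * np.cos(k * theta + phi)
    return w


def _liquid_profile_bf(r: np.ndarray, p: RenderParams) -> np.ndarray:
    interior = p.bf_liquid_center - p.bf_liquid_falloff * (r / p.rim_start) ** 2
    rim = p.bf_rim_level + 10.0 * r
    return np.where(r < p.rim_start, interior, rim).astype(np.float32)


def _liquid_profile_pol(r: np.ndarray, bg: float, vis: float, p: RenderParams) -> np.ndarray:
    gain = p.pol_liquid_gain * vis
    interior = bg * (1.0 + gain * (1.0 - 0.6 * (r / p.rim_start) ** 2))
    rim = bg * (1.0 - gain)
    return np.where(r < p.rim_start, interior, rim).astype(np.float32)


def render_droplet(
    state: str,
    mode: str,
    analyzer_angle: float,
    diameter_px: float,
    rng: np.random.Generator,
    params: RenderParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one droplet as an absolute-intensity patch plus its pixel mask.

    Returns ``(patch, mask)``; the caller composites ``patch[mask]`` onto the
    background.  Patch values are on the 8-bit scale but unclipped floats.
    """
    p = params or RenderParams()
    if state not in DROPLET_STATES:
        raise ValueError(f"unknown droplet state {state!r}")
    if mode not in ("brightfield", "polarized"):
        raise ValueError(f"unknown imaging mode {mode!r}")
    if diameter_px < 8:
        raise ValueError("diameter below 8 px cannot be rendered meaningfully")

    c = float(np.clip(p.class_contrast, 0.0, 1.0))
    r, theta = _grids(diameter_px, p.boundary_roughness)

    if mode == "brightfield":
        liquid = _liquid_profile_bf(r, p)
        if state == "liquid":
            patch, mask = liquid, r <= 1.0
        else:
            w = _angular_modulation(theta, rng, p.boundary_roughness) * c
            r_eff = r * (1.0 + w)
            sd = (
                p.bf_recalescent_speckle_sd
                if state == "recalescent"
                else p.bf_speckle_sd
            )
            base_interior = {
                "frozen_bright": p.bf_frozen_interior + 12.0,
                "frozen_dark": p.bf_frozen_interior - 22.0,
                "recalescent": p.bf_frozen_interior,
            }[state]
            frozen = np.where(
                r_eff < p.rim_start,
                base_interior + rng.normal(0.0, sd, r.shape),
                p.bf_frozen_rim + rng.normal(0.0, 20.0, r.shape),
            ).astype(np.float32)
            patch = c * frozen + (1.0 - c) * liquid
            mask = r_eff <= 1.0
        return patch, mask

    # polarized
    vis = p.liquid_visibility(analyzer_angle)
    bg = p.pol_background(analyzer_angle)
    liquid = _liquid_profile_pol(r, bg, vis, p)
    if state == "liquid":
        return liquid, r <= 1.0
    w = _angular_modulation(theta, rng, p.boundary_roughness) * c
    r_eff = r * (1.0 + w)
    if state == "frozen_bright":
        gain = rng.uniform(*p.pol_gain_range)
        frozen = (
            bg
            + gain * (0.8 + 0.2 * np.clip(1.0 - r**2, 0.0, 1.0))
            + rng.normal(0.0, p.pol_bright_speckle_sd, r.shape)
        ).astype(np.float32)
    elif state == "frozen_dark":
        frozen = (
            bg * (1.0 - p.pol_dark_factor * vis)
            + rng.normal(0.0, 1.5, r.shape)
        ).astype(np.float32)
    else:  # recalescent: slush, barely birefringent — looks like a liquid drop
        frozen = liquid + vis * np.abs(
            rng.normal(0.0, p.pol_recalescent_speckle_sd, r.shape)
        ).astype(np.float32)
    patch = c * frozen + (1.0 - c) * liquid
    return patch, r_eff <= 1.0


# ---------------------------------------------------------------------------
# Video simulation
# ---------------------------------------------------------------------------


def _static_background(
    shape: tuple[int, int],
    mode: str,
    analyzer_angle: float,
    p: RenderParams,
    gradient: bool,
    stripe: bool,
) -> np.ndarray:
    h, width = shape
    if mode == "brightfield":
        base = np.full(shape, p.bf_background, dtype=np.float32)
        if gradient:
            base += np.linspace(-6.0, 6.0, width, dtype=np.float32)[None, :]
        if stripe:
            # off-center trace of the thin-film temperature sensor under the channel
            r0 = int(0.67 * h)
            base[r0 : r0 + max(4, h // 8), :] += 18.0
    else:
        bg = p.pol_background(analyzer_angle)
        base = np.full(shape, bg, dtype=np.float32)
        if gradient:
            base += np.linspace(-0.05 * bg, 0.05 * bg, width, dtype=np.float32)[None, :]
    return base


def simulate_video(
    temperature_c: float,
    n_droplets: int,
    mode: str = "brightfield",
    *,
    p_frozen: float | None = None,
    population: INPPopulation | None = None,
    analyzer_angle: float = 60.0,
    fps: float = 150.0,
    velocity_um_s: float = 12000.0,
    noise_sd: float = 2.5,
    seed: int = 0,
    frame_shape: tuple[int, int] = (128, 256),
    scale_um_per_px: float = DEFAULT_SCALE_UM_PER_PX,
    diameter_um_range: tuple[float, float] = (70.0, 85.0),
    pitch_px: float = 100.0,
    pitch_jitter_px: float = 12.0,
    subtype_mix: tuple[float, float, float] = (0.70, 0.15, 0.15),
    nominal_diameter_um: float = 75.0,
    cm_mg_per_ml: float = 1.0,
    params: RenderParams | None = None,
    background_gradient: bool = True,
    sensor_stripe: bool = True,
    redraw_frozen_gain: bool = False,
) -> tuple[FrameStack, SceneTruth]:
    """Simulate one video at a fixed channel temperature.

    Each droplet's frozen/liquid truth is Bernoulli(p); ``p`` is either given
    directly (``p_frozen``) or computed from an :class:`INPPopulation` at the
    video temperature for the nominal droplet volume and concentration.  Frozen
    droplets are split among the bright/dark/recalescent subtypes according to
    ``subtype_mix``.  Fully reproducible for a given seed; the droplet layout
    and truth stream is separate from the rendering/noise streams, so the same
    seed produces the same droplets (and truth labels) in bright-field and
    polarized mode — matched-mode comparisons rely on this.
    """
    p = params or RenderParams()
    if n_droplets < 0:
        raise ValueError("n_droplets must be non-negative")
    if p_frozen is None:
        if population is None:
            p_frozen = 0.0
        else:
            v_ml = inpmodel.sphere_volume_ml(nominal_diameter_um)
            p_frozen = expected_frozen_fraction(
                population_nm(population, temperature_c), v_ml, cm_mg_per_ml
            )
    if not 0 <= p_frozen <= 1:
        raise ValueError("p_frozen outside [0, 1]")
    mix = np.asarray(subtype_mix, dtype=float)
    if mix.min() < 0 or not math.isclose(mix.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("subtype_mix must be a length-3 simplex")

    d_max_px = diameter_um_range[1] / scale_um_per_px
    if pitch_px <= d_max_px + 1.0:
        raise ValueError(
            f"pitch {pitch_px} px would overlap droplets of up to {d_max_px:.1f} px"
        )

    ss_layout, ss_render, ss_noise = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(ss_layout)  # droplet layout + truth labels
    rng_render = np.random.default_rng(ss_render)
    rng_noise = np.random.default_rng(ss_noise)
    step_px = velocity_um_s / (fps * scale_um_per_px)
    h, width = frame_shape
    background = _static_background(
        frame_shape, mode, analyzer_angle, p, background_gradient, sensor_stripe
    )

    # --- per-droplet truth ---------------------------------------------------
    droplets: list[TruthDroplet] = []
    patches: list[tuple[np.ndarray, np.ndarray]] = []
    offset = 0.0
    for i in range(n_droplets):
        diameter_px = rng.uniform(*diameter_um_range) / scale_um_per_px
        y = h / 2.0 + rng.uniform(-5.0, 5.0)
        if i > 0:
            offset += pitch_px + rng.uniform(0.0, pitch_jitter_px)
        frozen = rng.random() < p_frozen
        state = (
            FROZEN_STATES[rng.choice(3, p=mix)] if frozen else "liquid"
        )
        radius = diameter_px / 2.0
        x0 = -radius - offset
        entry = max(0, int(math.ceil((-radius - x0) / step_px)))
        exit_f = int(math.ceil((width + radius - x0) / step_px))
        droplets.append(
            TruthDroplet(
                droplet_id=i,
                state=state,
                diameter_px=diameter_px,
                x0=x0,
                y=y,
                step_px=step_px,
                entry_frame=entry,
                exit_frame=exit_f,
            )
        )
        patches.append(
            render_droplet(state, mode, analyzer_angle, diameter_px, rng_render, p)
        )

    n_frames = (
        max(d.exit_frame for d in droplets) + 1 if droplets else 12
    )

    # --- frame compositing ---------------------------------------------------
    x0_arr = np.array([d.x0 for d in droplets], dtype=float)
    half_arr = np.array([patch.shape[0] // 2 for patch, _ in patches], dtype=float)
    frames = np.empty((n_frames, h, width), dtype=np.uint8)
    for k in range(n_frames):
        frame = background.copy()
        if droplets:
            xs = x0_arr + k * step_px
            visible = np.nonzero((xs + half_arr >= 0) & (xs - half_arr < width))[0]
        else:
            visible = ()
        for i in visible:
            d = droplets[i]
            patch, mask = patches[i]
            x, y = xs[i], d.y
            half = patch.shape[0] // 2
            if redraw_frozen_gain and d.state == "frozen_bright":
                patch, mask = render_droplet(
                    d.state, mode, analyzer_angle, d.diameter_px, rng_render, p
                )
            cx, cy = int(round(x)), int(round(y))
            x_lo, x_hi = cx - half, cx + half + 1
            y_lo, y_hi = cy - half, cy + half + 1
            fx_lo, fx_hi = max(0, x_lo), min(width, x_hi)
            fy_lo, fy_hi = max(0, y_lo), min(h, y_hi)
            if fx_lo >= fx_hi or fy_lo >= fy_hi:
                continue
            px_lo, px_hi = fx_lo - x_lo, fx_hi - x_lo
            py_lo, py_hi = fy_lo - y_lo, fy_hi - y_lo
            sub_mask = mask[py_lo:py_hi, px_lo:px_hi]
            target = frame[fy_lo:fy_hi, fx_lo:fx_hi]
            target[sub_mask] = patch[py_lo:py_hi, px_lo:px_hi][sub_mask]
        if noise_sd > 0:
            frame = frame + rng_noise.normal(0.0, noise_sd, frame.shape)
        frames[k] = np.clip(frame, 0, 255).astype(np.uint8)

    stack = FrameStack(
        frames=frames,
        mode=mode,
        analyzer_angle=analyzer_angle if mode == "polarized" else 0.0,
        fps=fps,
        scale_um_per_px=scale_um_per_px,
        temperature_c=temperature_c,
        seed=seed,
    )
    truth = SceneTruth(
        droplets=droplets,
        background=background,
        frame_shape=frame_shape,
        n_frames=n_frames,
    )
    return stack, truth
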