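"""Droplet detection, tracking and crop extraction from freezing-assay videos.

The goal is bookkeeping, not segmentation finesse: every droplet that fully
traverses the region of interest must be counted exactly once.  The pipeline is

1. :func:`estimate_background` — per-pixel median over a frame subsample;
2. :func:`detect_droplets` — absolute background difference, threshold,
   morphological cleanup, connected components filtered by size and
   circularity; components touching the upstream/downstream edges are flagged
   partial and excluded from counting;
3. :func:`link_tracks` — nearest-neighbour frame-to-frame assignment inside a
   gate centred on the predicted displacement (constant-velocity prior along
   the flow axis), with short gap bridging;
4. :func:`representative_crop` — a fixed-size normalized patch per track, taken
   where the droplet is closest to the ROI centre, for the classifiers.

In polarized mode with the analyzer at full extinction (90 deg) liquid droplets
provide no background contrast and are not detected; this is an inherent limit
of that imaging mode, not of the detector.  At 60-85 deg the residual lensing
contrast keeps liquid droplets detectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology, transform

from .synthdrop import FrameStack, SceneTruth

__all__ = [
    "DetectParams",
    "Region",
    "DropletTrack",
    "estimate_background",
    "detect_droplets",
    "link_tracks",
    "representative_crop",
    "process_stack",
    "match_tracks_to_truth",
    "tracks_table",
]


@dataclass
class DetectParams:
    """Tunables of the detection/tracking pipeline (pixel units)."""

    threshold: float = 8.0  # |frame - background| level
    min_diameter_px: float = 25.0
    max_diameter_px: float = 55.0
    min_circularity: float = 0.6  # 4*pi*A / P^2
    closing_radius: int = 3
    min_area_px: int = 80
    velocity_um_s: float = 12000.0  # constant-velocity prior for linking
    nominal_diameter_px: float = 40.0
    gate_fraction: float = 0.5  # gate = fraction * nominal diameter
    max_gap: int = 2  # frames a track may go undetected
    min_track_length: int = 3  # completed track needs this many detections
    background_max_frames: int = 200
    crop_factor: float = 2.5  # crop side = factor * droplet diameter
    crop_side: int = 64  # resampled square side fed to classifiers


@dataclass(frozen=True)
class Region:
    """One connected component in one frame."""

    frame: int
    cx: float
    cy: float
    radius: float
    area: int
    circularity: float
    partial: bool  # touches an upstream/downstream ROI edge


@dataclass
class DropletTrack:
    """A droplet followed across frames."""

    track_id: int
    records: list[Region] = field(default_factory=list)

    @property
    def n_obs(self) -> int:
        return len(self.records)

    @property
    def radius_px(self) -> float:
        return float(np.median([r.radius for r in self.records]))

    @property
    def frames(self) -> list[int]:
        return [r.frame for r in self.records]

    def record_nearest_center(self, width: int) -> Region:
        return min(self.records, key=lambda r: abs(r.cx - width / 2.0))


def _mode_background(sample: np.ndarray) -> np.ndarray:
    """Smoothed per-pixel temporal mode of a uint8 frame sample."""
    ns, h, w = sample.shape
    npix = h * w
    flat = sample.reshape(ns, npix).astype(np.int64)
    codes = flat + (np.arange(npix, dtype=np.int64) * 256)[None, :]
    counts = np.bincount(codes.ravel(), minlength=npix * 256).reshape(npix, 256)
    # smooth over neighbouring intensity levels so sensor noise pools votes
    smooth = ndi.uniform_filter1d(counts.astype(np.float32), size=5, axis=1)
    return np.argmax(smooth, axis=1).reshape(h, w).astype(np.float32)


def estimate_background(
    stack: FrameStack, params: DetectParams | None = None, method: str = "median"
) -> np.ndarray:
    """Static background from an evenly spaced frame subsample.

    The default per-pixel median is exact (to within sensor noise) whenever
    droplets cover each pixel less than half of the time, which the simulator's
    default arrival pitch guarantees.  For densely pitched trains the
    ``"masked"`` two-pass estimator is available instead: a smoothed per-pixel
    temporal mode gives a coarse background, droplets are detected against it
    in each sampled frame, a dilated disk around every detection is masked
    out, and the remaining droplet-free samples are averaged per pixel.

    Requires >= 5 frames.
    """
    params = params or DetectParams()
    n = stack.n_frames
    if n < 5:
        raise ValueError("background estimation needs at least 5 frames")
    idx = np.linspace(0, n - 1, min(n, params.background_max_frames)).astype(int)
    sample = stack.frames[idx]
    if method == "median" or sample.dtype != np.uint8:
        return np.median(sample.astype(np.float32), axis=0)
    bg = _mode_background(sample)
    if method == "mode":
        return bg
    h, w = bg.shape
    rr, cc = np.ogrid[:h, :w]
    sums = np.zeros((h, w), dtype=np.float64)
    counts = np.zeros((h, w), dtype=np.int32)
    min_rad = params.nominal_diameter_px / 2.0
    for k, frame in zip(idx, sample):
        mask = np.zeros((h, w), dtype=bool)
        for reg in detect_droplets(frame, bg, params, frame_index=int(k)):
            rad = 1.2 * max(reg.radius, min_rad)
            mask |= (rr - reg.cy) ** 2 + (cc - reg.cx) ** 2 <= rad**2
        free = ~mask
        sums[free] += frame[free]
        counts[free] += 1
    refined = np.where(counts >= 3, sums / np.maximum(counts, 1), bg)
    return refined.astype(np.float32)


def detect_droplets(
    frame: np.ndarray,
    background: np.ndarray,
    params: DetectParams | None = None,
    frame_index: int = 0,
) -> list[Region]:
    """Segment droplet-sized blobs in one frame by background difference."""
    params = params or DetectParams()
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = np.abs(frame.astype(np.float32) - background)
    binary = diff > params.threshold
    # pad before closing so droplets straddling the ROI edge are not eroded
    # away from the border (they must keep touching it to be flagged partial)
    r = params.closing_radius
    padded = np.pad(binary, r, mode="edge")
    padded = ndi.binary_closing(padded, structure=morphology.disk(r))
    binary = padded[r:-r, r:-r]
    binary = ndi.binary_fill_holes(binary)

    labels = measure.label(binary)
    width = frame.shape[1]
    out: list[Region] = []
    for rp in measure.regionprops(labels):
        if rp.area < params.min_area_px:
            continue
        minr, minc, maxr, maxc = rp.bbox
        partial = minc == 0 or maxc == width
        diameter = rp.equivalent_diameter_area
        perim = rp.perimeter
        circ = 4.0 * math.pi * rp.area / perim**2 if perim > 0 else 0.0
        if not partial:
            if not (params.min_diameter_px <= diameter <= params.max_diameter_px):
                continue
            if circ < params.min_circularity:
                continue
        cy, cx = rp.centroid
        out.append(
            Region(
                frame=frame_index,
                cx=float(cx),
                cy=float(cy),
                radius=float(diameter / 2.0),
                area=int(rp.area),
                circularity=float(circ),
                partial=bool(partial),
            )
        )
    return out


def link_tracks(
    regions_by_frame: Sequence[Sequence[Region]],
    step_px: float,
    params: DetectParams | None = None,
) -> list[DropletTrack]:
    """Greedy nearest-neighbour linking under a constant-velocity prior.

    ``step_px`` is the expected per-frame displacement along the flow axis.
    Partial (edge-touching) regions never join tracks, so only the fully
    visible part of a droplet's transit is recorded; a droplet that fully
    traverses the ROI therefore yields one track with several observations.
    Tracks shorter than ``min_track_length`` are discarded.
    """
    params = params or DetectParams()
    gate = params.gate_fraction * params.nominal_diameter_px

    active: list[DropletTrack] = []
    done: list[DropletTrack] = []
    next_id = 0
    for k, regions in enumerate(regions_by_frame):
        candidates = [r for r in regions if not r.partial]
        # retire tracks that have been unseen too long
        still = []
        for tr in active:
            if k - tr.records[-1].frame > params.max_gap + 1:
                done.append(tr)
            else:
                still.append(tr)
        active = still

        pairs = []
        for ti, tr in enumerate(active):
            last = tr.records[-1]
            dt = k - last.frame
            px, py = last.cx + step_px * dt, last.cy
            for ri, reg in enumerate(candidates):
                d = math.hypot(reg.cx - px, reg.cy - py)
                if d <= gate:
                    pairs.append((d, ti, ri))
        pairs.sort()
        used_t: set[int] = set()
        used_r: set[int] = set()
        for d, ti, ri in pairs:
            if ti in used_t or ri in used_r:
                continue
            active[ti].records.append(candidates[ri])
            used_t.add(ti)
            used_r.add(ri)
        for ri, reg in enumerate(candidates):
            if ri not in used_r:
                active.append(DropletTrack(track_id=next_id, records=[reg]))
                next_id += 1
    done.extend(active)
    done = [t for t in done if t.n_obs >= params.min_track_length]
    done.sort(key=lambda t: t.records[0].frame)
    for i, t in enumerate(done):
        t.track_id = i
    return done


def representative_crop(
    track: DropletTrack,
    stack: FrameStack,
    params: DetectParams | None = None,
    pad_value: float | None = None,
) -> np.ndarray:
    """A square, [0, 1]-normalized, fixed-side crop centred on the droplet.

    Taken at the observation closest to the ROI centre along the flow axis;
    the patch side is ``crop_factor`` times the droplet diameter so rim context
    is preserved, then resampled to ``crop_side``.  Out-of-frame pixels are
    padded with the frame's median (background) intensity.
    """
    params = params or DetectParams()
    if not track.records:
        raise ValueError("empty track")
    h, width = stack.shape
    rec = track.record_nearest_center(width)
    frame = stack.frames[rec.frame].astype(np.float32)
    side = max(8, int(round(params.crop_factor * 2.0 * track.radius_px)))
    half = side // 2
    cx, cy = int(round(rec.cx)), int(round(rec.cy))
    pad_val = float(np.median(frame)) if pad_value is None else float(pad_value)
    patch = np.full((side, side), pad_val, dtype=np.float32)
    x_lo, x_hi = cx - half, cx - half + side
    y_lo, y_hi = cy - half, cy - half + side
    fx_lo, fx_hi = max(0, x_lo), min(width, x_hi)
    fy_lo, fy_hi = max(0, y_lo), min(h, y_hi)
    patch[fy_lo - y_lo : fy_hi - y_lo, fx_lo - x_lo : fx_hi - x_lo] = frame[
        fy_lo:fy_hi, fx_lo:fx_hi
    ]
    patch /= 255.0
    out = transform.resize(
        patch, (params.crop_side, params.crop_side), anti_aliasing=True
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def process_stack(
    stack: FrameStack, params: DetectParams | None = None
) -> tuple[list[DropletTrack], list[np.ndarray]]:
    """Full detection pass: background, per-frame regions, linking, crops.

    Returns the completed tracks (each counted droplet) and one representative
    crop per track, index-aligned.
    """
    params = params or DetectParams()
    background = estimate_background(stack, params)
    regions = [
        detect_droplets(stack.frames[k], background, params, frame_index=k)
        for k in range(stack.n_frames)
    ]
    step_px = params.velocity_um_s / (stack.fps * stack.scale_um_per_px)
    tracks = link_tracks(regions, step_px, params)
    pad = float(np.median(background))
    crops = [representative_crop(t, stack, params, pad_value=pad) for t in tracks]
    return tracks, crops


def match_tracks_to_truth(
    tracks: Sequence[DropletTrack],
    truth: SceneTruth,
    max_dist_px: float = 20.0,
) -> dict[int, int]:
    """Associate detected tracks with ground-truth droplets by position.

    Greedy one-to-one matching on centroid distance at each track's middle
    observation.  Returns ``{track_id: droplet_id}``; unmatched tracks are
    absent from the mapping.
    """
    pairs = []
    for tr in tracks:
        rec = tr.records[len(tr.records) // 2]
        for d in truth.droplets:
            tx, ty = d.centroid_at(rec.frame)
            dist = math.hypot(rec.cx - tx, rec.cy - ty)
            if dist <= max_dist_px:
                pairs.append((dist, tr.track_id, d.droplet_id))
    pairs.sort()
    used_t: set[int] = set()
    used_d: set[int] = set()
    mapping: dict[int, int] = {}
    for dist, tid, did in pairs:
        if tid in used_t or did in used_d:
            continue
        mapping[tid] = did
        used_t.add(tid)
        used_d.add(did)
    return mapping


def tracks_table(tracks: Sequence[DropletTrack]) -> pd.DataFrame:
    """Summary table of completed tracks (one row per droplet counted)."""
    rows = []
    for t in tracks:
        first, last = t.records[0], t.records[-1]
        rows.append(
            {
                "track_id": t.track_id,
                "n_obs": t.n_obs,
                "first_frame": first.frame,
                "last_frame": last.frame,
                "radius_px": t.radius_px,
                "mean_circularity": float(np.mean([r.circularity for r in t.records])),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "n_obs",
            "first_frame",
            "last_frame",
            "radius_px",
            "mean_circularity",
        ],
    )
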