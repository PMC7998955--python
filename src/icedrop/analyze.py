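"""Assemble per-temperature labels into freezing curves and derived statistics.

Raw classifier output (one frozen/liquid label per counted droplet per video)
is reduced to :class:`~icedrop.inpmodel.TemperaturePoint` records, collected
into a :class:`~icedrop.inpmodel.FreezingCurve`, and turned into the standard
readouts of a droplet freezing assay:

* the active-site density spectrum nm(T), with Wilson-interval error
  propagation and censoring of fully frozen (f = 1) points;
* the freezing onset temperature (warmest temperature where the interpolated
  frozen fraction reaches a configurable threshold, default 0.05 — the
  literature uses "onset" loosely, so the threshold is explicit here);
* temperature shifts between two curves at a matched frozen fraction, the
  quantity used to express treatment-induced deactivation.

Frozen-fraction curves are reported raw; expected curves are monotone but
observed ones may wiggle within binomial noise.  Violations beyond noise are
flagged, never corrected, unless isotonic smoothing is explicitly requested.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .classify import Label
from .exceptions import EmptySampleError, UndefinedOnsetError
from .inpmodel import (
    FreezingCurve,
    TemperaturePoint,
    active_site_density,
)

__all__ = [
    "temperature_point",
    "build_curve",
    "nm_spectrum",
    "onset_temperature",
    "curve_shift",
    "temperature_at_fraction",
    "flag_nonmonotonic",
    "isotonic_fractions",
    "plot_freezing_curves",
    "plot_nm_spectra",
]


def _label_values(labels: Sequence) -> list[str]:
    return [l.value if isinstance(l, Label) else str(l) for l in labels]


def temperature_point(labels: Sequence, temperature_c: float) -> TemperaturePoint:
    """Reduce one video's labels to counts, frozen fraction and Wilson 95 % CI."""
    vals = _label_values(labels)
    if not vals:
        raise EmptySampleError("no labels for this temperature")
    bad = sorted({v for v in vals if v not in ("frozen", "liquid")})
    if bad:
        raise ValueError(f"unknown labels {bad}")
    return TemperaturePoint(temperature_c, n=len(vals), nf=vals.count("frozen"))


def build_curve(
    points: Sequence[TemperaturePoint], v_ml: float, cm_mg_per_ml: float
) -> FreezingCurve:
    """Sort points warm-to-cold and pool replicates at identical temperatures.

    Pooling sums counts, so the pooled frozen fraction is the droplet-weighted
    mean of the replicates.
    """
    if not points:
        raise ValueError("no temperature points")
    pooled: dict[float, tuple[int, int]] = {}
    for p in points:
        n, nf = pooled.get(p.temperature_c, (0, 0))
        pooled[p.temperature_c] = (n + p.n, nf + p.nf)
    if len(pooled) < 2:
        raise ValueError("need at least 2 distinct temperatures")
    pts = tuple(
        TemperaturePoint(t, n, nf)
        for t, (n, nf) in sorted(pooled.items(), reverse=True)
    )
    return FreezingCurve(pts, v_ml, cm_mg_per_ml)


def nm_spectrum(curve: FreezingCurve) -> pd.DataFrame:
    """Active-site density at each point, with Wilson-propagated bounds.

    Columns: T_C, nm_per_mg, nm_lo, nm_hi, censored.  Points with f = 1 are
    censored (nm diverges) and carry NaN densities; f = 0 points report 0.
    """
    rows = []
    vc = (curve.v_ml, curve.cm_mg_per_ml)
    for p in curve.points:
        censored = p.f == 1
        rows.append(
            {
                "T_C": p.temperature_c,
                "nm_per_mg": math.nan if censored else active_site_density(p.f, *vc),
                "nm_lo": math.nan if censored else active_site_density(p.f_lo, *vc),
                "nm_hi": math.nan
                if censored or p.f_hi == 1
                else active_site_density(p.f_hi, *vc),
                "censored": censored,
            }
        )
    return pd.DataFrame(rows, columns=["T_C", "nm_per_mg", "nm_lo", "nm_hi", "censored"])


def temperature_at_fraction(
    curve: FreezingCurve, f_target: float, method: str = "pchip"
) -> float:
    """Warmest temperature where interpolated f(T) reaches f_target.

    Scans warm-to-cold for the first bracketing pair of points and solves for
    the crossing inside it.  The default monotone cubic (PCHIP) interpolant
    through all points removes most of the chord bias a piecewise-linear
    interpolation would have on a curved freezing curve; with only two points
    both methods coincide.  ``f_target = 0`` degenerates to the warmest
    temperature with any frozen droplet.
    """
    pts = curve.points
    if f_target == 0:
        for p in pts:
            if p.nf > 0:
                return p.temperature_c
        raise UndefinedOnsetError("no frozen droplets anywhere on the curve")
    if not 0 <= f_target <= 1:
        raise ValueError("f_target outside [0, 1]")
    if pts[0].f >= f_target:
        raise UndefinedOnsetError(
            f"curve starts at f={pts[0].f:.3f} >= target {f_target}; "
            "no warm-side bracket"
        )
    for i, (a, b) in enumerate(zip(pts, pts[1:])):
        if a.f < f_target <= b.f:
            if method == "linear" or len(pts) < 3:
                frac = (f_target - a.f) / (b.f - a.f)
                return a.temperature_c + frac * (b.temperature_c - a.temperature_c)
            # monotone cubic through the neighbourhood of the crossing
            from scipy.interpolate import PchipInterpolator
            from scipy.optimize import brentq

            lo = max(0, i - 2)
            hi = min(len(pts), i + 4)
            x = np.array([-p.temperature_c for p in pts[lo:hi]])  # ascending
            y = np.array([p.f for p in pts[lo:hi]])
            y = np.maximum.accumulate(y)  # enforce monotone input for PCHIP
            interp = PchipInterpolator(x, y)
            xa, xb = -a.temperature_c, -b.temperature_c
            try:
                root = brentq(lambda t: float(interp(t)) - f_target, xa, xb)
            except ValueError:  # accumulate() flattened a bracket endpoint
                frac = (f_target - a.f) / (b.f - a.f)
                return a.temperature_c + frac * (b.temperature_c - a.temperature_c)
            return -root
    raise UndefinedOnsetError(f"curve never reaches f = {f_target}")


def onset_temperature(curve: FreezingCurve, f_on: float = 0.05) -> float:
    """Freezing onset: warmest temperature where f(T) first reaches ``f_on``."""
    return temperature_at_fraction(curve, f_on)


def curve_shift(
    curve_a: FreezingCurve, curve_b: FreezingCurve, f_match: float = 0.5
) -> float:
    """Temperature offset between two curves at a matched frozen fraction.

    Returns T_a(f_match) - T_b(f_match): positive when curve_b freezes at
    colder temperatures (e.g. after a deactivating treatment).
    """
    return temperature_at_fraction(curve_a, f_match) - temperature_at_fraction(
        curve_b, f_match
    )


def flag_nonmonotonic(curve: FreezingCurve, n_sigma: float = 3.0) -> list[int]:
    """Indices (warm-to-cold order) where f decreases on cooling beyond noise.

    Expected frozen fractions are non-decreasing on cooling; an observed drop
    larger than ``n_sigma`` combined binomial standard errors is flagged for
    inspection.  Nothing is altered.
    """
    flagged = []
    pts = curve.points
    for i, (a, b) in enumerate(zip(pts, pts[1:])):
        se = math.sqrt(
            a.f * (1 - a.f) / a.n + b.f * (1 - b.f) / b.n
        )
        if b.f < a.f - n_sigma * max(se, 1e-12):
            flagged.append(i + 1)
    return flagged


def isotonic_fractions(curve: FreezingCurve) -> np.ndarray:
    """Optional isotonic fit of f against decreasing temperature (count-weighted).

    Off by default everywhere; raw fractions are what gets reported.
    """
    t = curve.temperatures
    f = curve.fractions
    w = np.array([p.n for p in curve.points], dtype=float)
    iso = IsotonicRegression(increasing=True, y_min=0.0, y_max=1.0)
    return iso.fit_transform(-t, f, sample_weight=w)


# ---------------------------------------------------------------------------
# Plots
# ---------------------------------------------------------------------------


def _get_axes(ax):
    if ax is not None:
        return ax, None
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    return ax, fig


def plot_freezing_curves(curves: dict[str, FreezingCurve], path=None, ax=None):
    """Frozen fraction vs temperature with Wilson error bars, one line per curve."""
    ax, fig = _get_axes(ax)
    for name, curve in curves.items():
        t = curve.temperatures
        f = curve.fractions
        lo = f - np.array([p.f_lo for p in curve.points])
        hi = np.array([p.f_hi for p in curve.points]) - f
        ax.errorbar(t, f, yerr=[lo, hi], marker="o", ms=3, capsize=2, label=name)
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("frozen fraction f")
    ax.invert_xaxis()
    ax.legend(fontsize=8)
    if fig is not None and path is not None:
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax


def plot_nm_spectra(curves: dict[str, FreezingCurve], path=None, ax=None):
    """Active-site density nm(T) on a log scale, censored points omitted."""
    ax, fig = _get_axes(ax)
    for name, curve in curves.items():
        spec = nm_spectrum(curve)
        ok = (~spec.censored) & (spec.nm_per_mg > 0)
        ax.errorbar(
            spec.T_C[ok],
            spec.nm_per_mg[ok],
            yerr=[
                (spec.nm_per_mg - spec.nm_lo)[ok],
                (spec.nm_hi - spec.nm_per_mg)[ok],
            ],
            marker="s",
            ms=3,
            ls="none",
            capsize=2,
            label=name,
        )
    ax.set_yscale("log")
    ax.set_xlabel("temperature (°C)")
    ax.set_ylabel("n$_m$(T) (mg$^{-1}$)")
    ax.invert_xaxis()
    ax.legend(fontsize=8)
    if fig is not None and path is not None:
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        import matplotlib.pyplot as plt

        plt.close(fig)
    return ax
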