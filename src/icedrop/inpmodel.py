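"""Deterministic ice-nucleation statistics and the class-resolved INP population model.

The module implements the singular-description (time-independent) framework for
droplet freezing assays: the frozen fraction

    f(T) = Nf / N

and the cumulative ice-nucleation active-site density per unit INP mass

    nm(T) = -ln(1 - f(T)) / (V * Cm)

where ``V`` is the droplet volume in mL and ``Cm`` the INP mass concentration in
mg/mL.  An :class:`INPPopulation` models the sample as a sum of INP classes, each
with a site density (sites per mg) and an activation-temperature distribution;
class presets A/B/C follow the standard Snomax(R) subpopulation windows (A active
above -4.5 C, B between -6.5 and -4.5 C, C below -7.5 C).  Heat-treatment and
aging effects are expressed as :class:`TreatmentTransform` objects that shift
activation temperatures and deplete class densities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .exceptions import (
    CensoredPointError,
    EmptySampleError,
    InconsistentCountsError,
)

__all__ = [
    "TemperaturePoint",
    "FreezingCurve",
    "ActivationDistribution",
    "INPClassSpec",
    "INPPopulation",
    "TreatmentTransform",
    "frozen_fraction",
    "active_site_density",
    "expected_frozen_fraction",
    "population_nm",
    "apply_treatment",
    "simulate_counts",
    "simulate_curve",
    "sphere_volume_ml",
    "wilson_interval",
    "default_population",
    "treatment_preset",
    "CLASS_WINDOWS",
]

#: Activation-temperature windows (degC) of the canonical INP classes.
CLASS_WINDOWS: dict[str, tuple[float, float]] = {
    "A": (-4.5, 0.0),
    "B": (-6.5, -4.5),
    "C": (-math.inf, -7.5),
}


def sphere_volume_ml(diameter_um: float) -> float:
    """Volume of a spherical droplet of the given diameter, in mL.

    Droplets of 70-85 um are smaller than the flow-channel cross section, so an
    unconfined sphere V = (pi/6) d^3 is assumed.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    d_cm = diameter_um * 1e-4
    return math.pi / 6.0 * d_cm**3


def frozen_fraction(nf: int, n: int) -> float:
    """Frozen fraction f = Nf / N of a droplet ensemble at one temperature."""
    if n == 0:
        raise EmptySampleError("frozen fraction undefined for N = 0")
    if n < 0 or nf < 0 or nf > n:
        raise InconsistentCountsError(f"invalid counts Nf={nf}, N={n}")
    return nf / n


def active_site_density(f: float, v_ml: float, cm_mg_per_ml: float) -> float:
    """Cumulative active-site density nm = -ln(1-f) / (V Cm), sites per mg.

    ``f = 1`` diverges; such points must be censored upstream and requesting
    them here raises :class:`CensoredPointError` rather than returning inf.
    """
    if v_ml <= 0 or cm_mg_per_ml <= 0:
        raise ValueError("V and Cm must be positive")
    if f == 1:
        raise CensoredPointError("nm diverges at f = 1; censor the point")
    if not 0 <= f < 1:
        raise ValueError(f"frozen fraction {f} outside [0, 1)")
    return -math.log1p(-f) / (v_ml * cm_mg_per_ml)


def expected_frozen_fraction(nm: float, v_ml: float, cm_mg_per_ml: float) -> float:
    """Invert the active-site density: f = 1 - exp(-nm V Cm).

    Exact inverse of :func:`active_site_density` for f in [0, 1).
    """
    if nm < 0:
        raise ValueError("nm must be non-negative")
    if v_ml <= 0 or cm_mg_per_ml <= 0:
        raise ValueError("V and Cm must be positive")
    return -math.expm1(-nm * v_ml * cm_mg_per_ml)


def wilson_interval(nf: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion; well behaved near 0/1."""
    lo, hi = proportion_confint(nf, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class TemperaturePoint:
    """Counts and frozen fraction of one temperature point of a freezing assay."""

    temperature_c: float
    n: int
    nf: int
    f: float = field(init=False)
    f_lo: float = field(init=False)
    f_hi: float = field(init=False)

    def __post_init__(self) -> None:
        f = frozen_fraction(self.nf, self.n)
        lo, hi = wilson_interval(self.nf, self.n)
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "f_lo", lo)
        object.__setattr__(self, "f_hi", hi)


@dataclass(frozen=True)
class FreezingCurve:
    """An ordered set of temperature points plus droplet volume and concentration.

    Points are stored sorted by descending temperature (warm to cold); duplicate
    temperatures must be pooled before construction (see ``analyze.build_curve``).
    """

    points: tuple[TemperaturePoint, ...]
    v_ml: float
    cm_mg_per_ml: float

    def __post_init__(self) -> None:
        if self.v_ml <= 0 or self.cm_mg_per_ml <= 0:
            raise ValueError("V and Cm must be positive")
        temps = [p.temperature_c for p in self.points]
        if any(b >= a for a, b in zip(temps, temps[1:])):
            raise ValueError("points must be strictly decreasing in temperature")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([p.temperature_c for p in self.points])

    @property
    def fractions(self) -> np.ndarray:
        return np.array([p.f for p in self.points])

    def to_frame(self) -> pd.DataFrame:
        """Tabulate the curve; nm is empty (NaN) at censored (f = 1) points."""
        rows = []
        for p in self.points:
            nm = (
                math.nan
                if p.f == 1
                else active_site_density(p.f, self.v_ml, self.cm_mg_per_ml)
            )
            rows.append(
                {
                    "T_C": p.temperature_c,
                    "N": p.n,
                    "Nf": p.nf,
                    "f": p.f,
                    "f_lo": p.f_lo,
                    "f_hi": p.f_hi,
                    "nm_per_mg": nm,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, v_ml: float, cm_mg_per_ml: float) -> "FreezingCurve":
        df = pd.read_csv(path)
        pts = tuple(
            TemperaturePoint(row.T_C, int(row.N), int(row.Nf))
            for row in df.itertuples()
        )
        return cls(pts, v_ml, cm_mg_per_ml)


# ---------------------------------------------------------------------------
# Activation-temperature distributions and the class-resolved population model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActivationDistribution:
    """Distribution of the activation temperature of a single INP class.

    families
        ``truncnorm`` — normal(mean, sd) truncated to [lower, upper]
        ``uniform``   — uniform on [lower, upper]

    ``survival(T)`` returns Pr(T_act >= T): the fraction of the class's sites
    already active once the sample has been cooled to T.
    """

    family: str
    mean: float = 0.0
    sd: float = 1.0
    lower: float = -math.inf
    upper: float = math.inf

    def __post_init__(self) -> None:
        if self.family not in ("truncnorm", "uniform"):
            raise ValueError(f"unknown distribution family {self.family!r}")
        if self.family == "truncnorm" and self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")
        if self.family == "uniform" and not (
            math.isfinite(self.lower) and math.isfinite(self.upper)
        ):
            raise ValueError("uniform family needs finite bounds")

    def _frozen_dist(self):
        if self.family == "uniform":
            return stats.uniform(loc=self.lower, scale=self.upper - self.lower)
        a = (self.lower - self.mean) / self.sd
        b = (self.upper - self.mean) / self.sd
        return stats.truncnorm(a, b, loc=self.mean, scale=self.sd)

    def survival(self, t: float | np.ndarray) -> float | np.ndarray:
        return self._frozen_dist().sf(t)

    def shifted(self, delta: float) -> "ActivationDistribution":
        """Translate the whole distribution by ``delta`` degC."""
        return replace(
            self,
            mean=self.mean + delta,
            lower=self.lower + delta if math.isfinite(self.lower) else self.lower,
            upper=self.upper + delta if math.isfinite(self.upper) else self.upper,
        )

    def to_dict(self) -> dict:
        d = {"family": self.family, "lower": self.lower, "upper": self.upper}
        if self.family == "truncnorm":
            d.update(mean=self.mean, sd=self.sd)
        return {
            k: (str(v) if isinstance(v, float) and math.isinf(v) else v)
            for k, v in d.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ActivationDistribution":
        dd = dict(d)
        for key in ("lower", "upper"):
            if key in dd and isinstance(dd[key], str):
                dd[key] = float(dd[key])
        return cls(**dd)


@dataclass(frozen=True)
class INPClassSpec:
    """One INP class: a site density (per mg) and an activation distribution."""

    name: str
    density_per_mg: float
    act_dist: ActivationDistribution

    def __post_init__(self) -> None:
        if self.density_per_mg < 0:
            raise ValueError("density must be non-negative")
        if self.name in CLASS_WINDOWS:
            lo, hi = CLASS_WINDOWS[self.name]
            if self.act_dist.lower < lo - 1e-9 or self.act_dist.upper > hi + 1e-9:
                raise ValueError(
                    f"class {self.name} activation support "
                    f"[{self.act_dist.lower}, {self.act_dist.upper}] outside its "
                    f"window [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class INPPopulation:
    """A sample modeled as a sum of INP classes."""

    classes: tuple[INPClassSpec, ...]

    @property
    def total_density(self) -> float:
        return sum(c.density_per_mg for c in self.classes)

    def nm(self, t: float | np.ndarray) -> float | np.ndarray:
        return population_nm(self, t)

    def to_dict(self) -> dict:
        return {
            "classes": [
                {
                    "name": c.name,
                    "density_per_mg": c.density_per_mg,
                    "act_dist": c.act_dist.to_dict(),
                }
                for c in self.classes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "INPPopulation":
        return cls(
            tuple(
                INPClassSpec(
                    name=c["name"],
                    density_per_mg=float(c["density_per_mg"]),
                    act_dist=ActivationDistribution.from_dict(c["act_dist"]),
                )
                for c in d["classes"]
            )
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "INPPopulation":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(d)


def population_nm(pop: INPPopulation, t: float | np.ndarray) -> float | np.ndarray:
    """Active-site density of a population at temperature ``t``.

    nm(T) = sum_c density_c * Pr(T_act,c >= T).  Non-increasing in T, tending to
    the total density as T -> -inf and to 0 above all class supports.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    for c in pop.classes:
        out = out + c.density_per_mg * c.act_dist.survival(t)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class TreatmentTransform:
    """Shift activation temperatures and deplete class densities.

    ``shift`` is a temperature offset in degC (<= 0 for deactivating treatments);
    ``depletion`` maps class names to multiplicative density factors in [0, 1]
    (classes not listed are untouched).
    """

    shift: float = 0.0
    depletion: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, fac in self.depletion.items():
            if not 0 <= fac <= 1:
                raise ValueError(f"depletion factor for {name} outside [0, 1]")


def apply_treatment(pop: INPPopulation, tr: TreatmentTransform) -> INPPopulation:
    """Return the treated population; the original is left untouched.

    Shifted class distributions may leave their preset window, so treated
    classes are renamed ``<name>*`` to drop the window constraint.
    """
    new = []
    for c in pop.classes:
        density = c.density_per_mg * tr.depletion.get(c.name, 1.0)
        dist = c.act_dist.shifted(tr.shift) if tr.shift != 0 else c.act_dist
        name = c.name if tr.shift == 0 else f"{c.name}*"
        new.append(INPClassSpec(name=name, density_per_mg=density, act_dist=dist))
    return INPPopulation(tuple(new))


#: Treatment presets.  "heat55" reproduces mild heat damage: the whole freezing
#: curve translates ~1.3 degC colder with no class loss.  "heat95" reproduces
#: severe thermal degradation: the warm class A is destroyed outright, the rest
#: of the sites are pushed 7 degC colder and thinned, flattening the curve and
#: lowering the onset by more than 7 degC.
_TREATMENT_PRESETS: dict[str, TreatmentTransform] = {
    "heat55": TreatmentTransform(shift=-1.3),
    "heat95": TreatmentTransform(
        shift=-7.0, depletion={"A": 0.0, "B": 0.3, "C": 0.8}
    ),
}


def treatment_preset(name: str) -> TreatmentTransform:
    try:
        return _TREATMENT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown treatment preset {name!r}; known: {sorted(_TREATMENT_PRESETS)}"
        ) from None


def default_population() -> INPPopulation:
    """Illustrative A/B/C population used as the simulator default.

    Densities are chosen so that, for a 75 um droplet at Cm = 1 mg/mL, the
    expected frozen-fraction curve rises from ~0 at -4 degC to ~1 by about
    -8 degC with steep warm/cold flanks and an intermediate plateau (class B
    scarce relative to A and C).  Illustrative, not fitted to any dataset.
    """
    return INPPopulation(
        (
            INPClassSpec(
                "A",
                5.0e5,
                ActivationDistribution("truncnorm", mean=-4.2, sd=0.3, lower=-4.5, upper=0.0),
            ),
            INPClassSpec(
                "B",
                2.0e6,
                ActivationDistribution("truncnorm", mean=-5.5, sd=0.5, lower=-6.5, upper=-4.5),
            ),
            INPClassSpec(
                "C",
                6.0e7,
                ActivationDistribution("truncnorm", mean=-8.5, sd=0.6, upper=-7.5),
            ),
        )
    )


def simulate_counts(
    pop: INPPopulation,
    t: float,
    n: int,
    v_ml: float,
    cm_mg_per_ml: float,
    rng: np.random.Generator | int,
) -> int:
    """Draw a frozen count Nf ~ Binomial(N, f_expected(T)) for the population."""
    if n <= 0:
        raise EmptySampleError("need N > 0 droplets")
    rng = np.random.default_rng(rng)
    p = expected_frozen_fraction(population_nm(pop, t), v_ml, cm_mg_per_ml)
    return int(rng.binomial(n, p))


def simulate_curve(
    pop: INPPopulation,
    temperatures: Sequence[float],
    n_per_point: int,
    v_ml: float,
    cm_mg_per_ml: float,
    rng: np.random.Generator | int,
) -> FreezingCurve:
    """Simulate binomial counts at each temperature and assemble a curve."""
    rng = np.random.default_rng(rng)
    temps = sorted(set(float(t) for t in temperatures), reverse=True)
    pts = tuple(
        TemperaturePoint(t, n_per_point, simulate_counts(pop, t, n_per_point, v_ml, cm_mg_per_ml, rng))
        for t in temps
    )
    return FreezingCurve(pts, v_ml, cm_mg_per_ml)
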