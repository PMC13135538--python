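"""Gestation-dependent maternal and fetal physiological reference data.

The model tracks a small set of physiological quantities — tissue masses,
blood flows and blood volumes — that change over the 280 days of gestation
(days counted since conception, term at day 280).  Reference values are known
only at a handful of anchor gestational days; between anchors every quantity
is linearly interpolated, and outside the anchored range the boundary value is
held constant (no extrapolation).  The single deliberate exception is the
umbilical-vein flow, which is extrapolated linearly backward from its first
anchor (and floored at zero) so that placental exchange exists from day 105,
when the placenta is fully developed.

All tissue masses are converted to volumes at unit density (1 g/ml).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "AnchorSeries",
    "PhysiologyLibrary",
    "default_library",
    "check_day",
    "anchor_interpolate",
    "fetal_blood_volume",
    "kidney_adjustment",
    "uteroplacental_flow",
    "umbilical_vein_flow",
    "fetal_other_mass",
]

#: first gestational day at which the fetal side of the model is defined
#: (placenta fully developed at week 15)
FETAL_MODEL_START = 105.0
#: gestational day at which the fetal thyroid / bone-marrow / "other"
#: compartments join the model (week 16)
FETAL_OTHER_START = 126.0
#: gestational day at which the fetal adipose compartment joins (week 23)
FETAL_ADIPOSE_START = 161.0
#: term
TERM = 280.0

ML_PER_MIN_TO_L_PER_DAY = 1.44  # 1 ml/min = 1.44 l/day


class ConfigurationError(ValueError):
    """A parameter table or series is malformed or insufficient."""


def check_day(day: float, low: float = 0.0, high: float = TERM) -> float:
    day = float(day)
    if not low <= day <= high:
        raise ValueError(f"gestational day {day} outside [{low}, {high}]")
    return day


@dataclass(frozen=True)
class AnchorSeries:
    """A quantity known at anchor gestational days, linear between anchors.

    Outside the anchored range the boundary value is held constant, which is
    also :func:`numpy.interp` semantics.
    """

    name: str
    unit: str
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "values", values)
        if days.size < 2:
            raise ConfigurationError(
                f"series {self.name!r} needs at least two anchors, got {days.size}"
            )
        if days.size != values.size:
            raise ConfigurationError(f"series {self.name!r}: day/value length mismatch")
        if not np.all(np.diff(days) > 0):
            raise ConfigurationError(f"series {self.name!r}: anchor days not strictly increasing")
        if np.any(values < 0):
            raise ConfigurationError(f"series {self.name!r}: negative anchor value")

    def __call__(self, day: float | np.ndarray):
        return np.interp(day, self.days, self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"day": self.days, "value": self.values})


def anchor_interpolate(series: AnchorSeries, day: float) -> float:
    """Evaluate *series* at *day*: exact on anchors, linear between, clamped outside."""
    return float(series(day))


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("radonpreg.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


@dataclass
class PhysiologyLibrary:
    """Packaged physiological reference tables, exposed as anchor series.

    The default instance (see :func:`default_library`) reads the CSV tables
    shipped with the package: maternal pregnancy mass increments, maternal
    blood-flow fractions, fetal organ masses and blood flows, radon
    tissue:blood partition coefficients, and scalar reference constants.
    """

    maternal_increments: dict[str, AnchorSeries] = field(default_factory=dict)
    maternal_flow_pct: pd.DataFrame | None = None
    fetal_masses: dict[str, AnchorSeries] = field(default_factory=dict)
    fetal_flows: dict[str, AnchorSeries] = field(default_factory=dict)
    partition_coefficients: dict[str, float] = field(default_factory=dict)
    constants: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_packaged_data(cls) -> "PhysiologyLibrary":
        lib = cls()
        inc = _read_packaged("maternal_mass_gain.csv")
        for tissue, grp in inc.groupby("tissue"):
            g = grp.sort_values("day")
            lib.maternal_increments[tissue] = AnchorSeries(
                f"maternal increment {tissue}", "g", g["day"].to_numpy(), g["increment_g"].to_numpy()
            )
        lib.maternal_flow_pct = _read_packaged("maternal_blood_flow.csv").set_index("quantity")
        fm = _read_packaged("fetal_masses.csv")
        for organ, grp in fm.groupby("organ"):
            g = grp.sort_values("day")
            lib.fetal_masses[organ] = AnchorSeries(
                f"fetal mass {organ}", "g", g["day"].to_numpy(), g["mass_g"].to_numpy()
            )
        ff = _read_packaged("fetal_flows.csv")
        for organ, grp in ff.groupby("organ"):
            g = grp.sort_values("day")
            lib.fetal_flows[organ] = AnchorSeries(
                f"fetal flow {organ}", "l/h", g["day"].to_numpy(), g["flow_l_per_h"].to_numpy()
            )
        pc = _read_packaged("partition_coefficients.csv")
        lib.partition_coefficients = dict(zip(pc["tissue"], pc["partition_coefficient"].astype(float)))
        if any(v <= 0 for v in lib.partition_coefficients.values()):
            raise ConfigurationError("partition coefficients must be positive")
        cons = _read_packaged("constants.csv")
        lib.constants = dict(zip(cons["name"], cons["value"].astype(float)))
        return lib

    # -- convenience accessors -------------------------------------------------

    def partition(self, tissue: str) -> float:
        try:
            return self.partition_coefficients[tissue]
        except KeyError:
            raise ConfigurationError(f"no partition coefficient for tissue {tissue!r}") from None

    def constant(self, name: str) -> float:
        try:
            return self.constants[name]
        except KeyError:
            raise ConfigurationError(f"no packaged constant {name!r}") from None

    def cardiac_output(self, day: float) -> float:
        """Maternal cardiac output in l/day, linear from conception to term."""
        day = check_day(day)
        co0 = self.constant("cardiac_output_nonpregnant")
        co1 = self.constant("cardiac_output_term")
        return co0 + (co1 - co0) * day / TERM

    def maternal_tissue_flow(self, tissue: str, day: float) -> float:
        """Blood flow (l/day) to a maternal tissue group, interpolating the
        percent-of-cardiac-output between the non-pregnant and term values."""
        day = check_day(day)
        row = self.maternal_flow_pct.loc[tissue]
        pct = row["nonpregnant"] + (row["pregnant_term"] - row["nonpregnant"]) * day / TERM
        return pct / 100.0 * self.cardiac_output(day)

    def uterus_mass(self, day: float) -> float:
        """Uterus mass (g): non-pregnant baseline plus the pregnancy increment."""
        base = self.constant("volume_uterus_baseline") * 1000.0
        return base + anchor_interpolate(self.maternal_increments["uterus"], day)

    def placenta_mass(self, day: float) -> float:
        return anchor_interpolate(self.maternal_increments["placenta"], day)

    def fetal_mass(self, organ: str, day: float) -> float:
        try:
            series = self.fetal_masses[organ]
        except KeyError:
            raise ConfigurationError(f"no fetal mass series for {organ!r}") from None
        return anchor_interpolate(series, day)

    def fetal_flow(self, organ: str, day: float) -> float:
        """Fetal organ blood flow in l/day."""
        try:
            series = self.fetal_flows[organ]
        except KeyError:
            raise ConfigurationError(f"no fetal flow series for {organ!r}") from None
        return anchor_interpolate(series, day) * 24.0


@lru_cache(maxsize=1)
def default_library() -> PhysiologyLibrary:
    return PhysiologyLibrary.from_packaged_data()


def fetal_blood_volume(fetal_mass_g: float, lib: PhysiologyLibrary | None = None) -> float:
    """Total fetal blood volume in litres: 16.2 ml per 100 g of fetal mass."""
    if fetal_mass_g < 0:
        raise ValueError(f"negative fetal mass: {fetal_mass_g}")
    lib = lib or default_library()
    return lib.constant("fetal_blood_ml_per_100g") / 100.0 * fetal_mass_g / 1000.0


def kidney_adjustment(day: float) -> tuple[float, float]:
    """Pregnancy adjustment factors (mass, flow) for the maternal kidneys.

    Mass rises linearly to +30 % at term.  Renal blood flow is unchanged
    through day 70, rises linearly to +80 % at day 105 (second trimester),
    then falls linearly to +50 % at term.
    """
    day = check_day(day)
    mass = 1.0 + 0.3 * day / TERM
    if day <= 70.0:
        flow = 1.0
    elif day <= FETAL_MODEL_START:
        flow = 1.0 + 0.8 * (day - 70.0) / (FETAL_MODEL_START - 70.0)
    else:
        flow = 1.8 - 0.3 * (day - FETAL_MODEL_START) / (TERM - FETAL_MODEL_START)
    return mass, flow


#: uteroplacental flow anchors (gestational day, ml/min); held constant after 266
_UTEROPLACENTAL_ANCHORS = AnchorSeries(
    "uteroplacental flow", "ml/min", np.array([105.0, 140.0, 266.0]), np.array([350.0, 513.0, 970.0])
)


def uteroplacental_flow(day: float) -> float:
    """Maternal blood flow uterus→placenta in ml/min (day ≥ 105).

    The same volumetric flow returns placenta→uterus (balanced uteroplacental
    circulation).
    """
    day = check_day(day, low=FETAL_MODEL_START)
    return anchor_interpolate(_UTEROPLACENTAL_ANCHORS, day)


def umbilical_vein_flow(day: float) -> float:
    """Umbilical-vein flow placenta→fetus in ml/min (day ≥ 105).

    Linear between (140, 50) and (280, 275); extrapolated linearly backward on
    [105, 140) and floored at zero.
    """
    day = check_day(day, low=FETAL_MODEL_START)
    flow = 50.0 + (275.0 - 50.0) * (day - 140.0) / (280.0 - 140.0)
    return max(flow, 0.0)


#: fetal organs subtracted from the total body mass to form the "other" pool
_EXPLICIT_FETAL_ORGANS = (
    "brain",
    "kidneys",
    "liver",
    "lungs",
    "red-marrow",
    "bone",
    "thyroid",
)


def fetal_other_mass(day: float, lib: PhysiologyLibrary | None = None) -> float:
    """Mass (g) of the aggregated fetal "other" compartment (day ≥ 126).

    Total fetal body mass minus the explicitly modelled organs; adipose is
    subtracted only from day 161, when the adipose compartment exists.
    """
    day = check_day(day, low=FETAL_OTHER_START)
    lib = lib or default_library()
    total = lib.fetal_mass("total-body", day)
    explicit = sum(lib.fetal_mass(o, day) for o in _EXPLICIT_FETAL_ORGANS)
    if day >= FETAL_ADIPOSE_START:
        explicit += lib.fetal_mass("adipose", day)
    other = total - explicit
    if other <= 0:
        raise ConfigurationError(
            f"fetal 'other' mass non-positive at day {day}: total {total} g vs "
            f"explicit organs {explicit} g"
        )
    return other
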