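"""Perfusion-limited transfer coefficients and their gestational-age parameterization.

Two routes produce a transfer coefficient ``k`` (per day):

* the *derivation* route applies perfusion-limited (Fick) kinetics to the
  physiology tables —

  - uptake from a blood pool:      ``k = F / V_blood``
  - washout from a tissue:         ``k = F / (V_tissue * P)``

  where ``F`` is the blood flow to the tissue (l/day), ``V`` a volume (l) and
  ``P`` the dimensionless tissue:blood partition coefficient;

* the *packaged* route evaluates the shipped piecewise-linear regressions
  ``k = a * t + b`` in gestational day ``t`` (one table for maternal tissues,
  one for the placenta / cord-blood / fetal tissues).

The packaged route is the primary parameterization used by the simulator; the
derivation route is retained as an independent, tolerance-tested cross-check
(several of its inputs, such as the cord-blood volume split, are calibration
parameters rather than tabulated reference values).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from . import physiology
from .physiology import (
    ConfigurationError,
    PhysiologyLibrary,
    default_library,
    ML_PER_MIN_TO_L_PER_DAY,
)

__all__ = [
    "rate_in",
    "rate_out",
    "RampRule",
    "apply_ramp",
    "mass_ratio_scale",
    "fit_linear_segments",
    "PiecewiseLinearRate",
    "RateTable",
    "packaged_rate_table",
    "evaluate_packaged",
    "derive_placenta_loop",
    "derive_uterus_uptake",
    "derive_fetal_organ_rates",
]


# ---------------------------------------------------------------------------
# elementary perfusion-limited rates

def rate_in(flow_l_per_day: float, blood_volume_l: float) -> float:
    """Uptake coefficient blood→tissue: flow divided by the blood-pool volume."""
    if blood_volume_l <= 0:
        raise ValueError(f"blood volume must be positive, got {blood_volume_l}")
    if flow_l_per_day < 0:
        raise ValueError(f"negative blood flow: {flow_l_per_day}")
    return flow_l_per_day / blood_volume_l

def rate_out(flow_l_per_day: float, tissue_volume_l: float, partition: float) -> float:
    """Washout coefficient tissue→blood: flow over (tissue volume × partition)."""
    if tissue_volume_l <= 0:
        raise ValueError(f"tissue volume must be positive, got {tissue_volume_l}")
    if partition <= 0:
        raise ValueError(f"partition coefficient must be positive, got {partition}")
    if flow_l_per_day < 0:
        raise ValueError(f"negative blood flow: {flow_l_per_day}")
    return flow_l_per_day / (tissue_volume_l * partition)


# ---------------------------------------------------------------------------
# ramp-in of late-appearing fetal compartments

@dataclass(frozen=True)
class RampRule:
    """Linear ramp of a coefficient from zero at ``zero_day`` to full value at
    ``full_day`` — gradual physiological growth instead of an abrupt appearance."""

    target: str
    zero_day: float
    full_day: float

    def __post_init__(self) -> None:
        if not self.zero_day < self.full_day:
            raise ConfigurationError(f"ramp for {self.target!r}: zero_day must precede full_day")

    def multiplier(self, day: float) -> float:
        if day <= self.zero_day:
            return 0.0
        if day >= self.full_day:
            return 1.0
        return (day - self.zero_day) / (self.full_day - self.zero_day)


THYROID_RAMP = RampRule("fetal-thyroid", 126.0, 140.0)
MARROW_RAMP = RampRule("fetal-bone-marrow", 126.0, 140.0)
OTHER_RAMP = RampRule("fetal-other", 126.0, 140.0)
ADIPOSE_RAMP = RampRule("fetal-adipose", 161.0, 175.0)


def apply_ramp(rate: float, rule: RampRule, day: float) -> float:
    return rate * rule.multiplier(day)


def mass_ratio_scale(reference_rate: float, organ_mass_g: float, other_mass_g: float) -> float:
    """Scale a reference coefficient by the organ : "other"-compartment mass ratio.

    Used for fetal tissues without specific flow data (thyroid, red bone
    marrow), whose coefficients are taken proportional to those of the
    aggregated "other" compartment.
    """
    if other_mass_g <= 0:
        raise ValueError(f"'other' mass must be positive, got {other_mass_g}")
    if organ_mass_g < 0:
        raise ValueError(f"negative organ mass: {organ_mass_g}")
    return reference_rate * organ_mass_g / other_mass_g


# ---------------------------------------------------------------------------
# piecewise-linear parameterization k = a*t + b

@dataclass(frozen=True)
class PiecewiseLinearRate:
    """A transfer coefficient as contiguous linear segments of gestational day.

    ``segments`` is an ordered array of rows ``(t_start, t_end, a, b)``;
    evaluation is ``a*t + b`` on the segment containing ``t`` (right-continuous
    at interior breakpoints), clipped at zero.  ``maternal`` rows clamp to the
    boundary segment value outside their day range; fetal rows evaluate to
    zero before their first segment (the compartment does not exist yet).
    """

    source: str
    target: str
    segments: np.ndarray  # shape (n, 4): t_start, t_end, a, b
    maternal: bool

    def __post_init__(self) -> None:
        seg = np.atleast_2d(np.asarray(self.segments, dtype=float))
        object.__setattr__(self, "segments", seg)
        if seg.shape[1] != 4:
            raise ConfigurationError(f"{self.source}->{self.target}: segments need 4 columns")
        if np.any(seg[:, 0] >= seg[:, 1]):
            raise ConfigurationError(f"{self.source}->{self.target}: empty or inverted segment")
        if not np.allclose(seg[:-1, 1], seg[1:, 0]):
            raise ConfigurationError(
                f"{self.source}->{self.target}: segments not contiguous "
                f"({seg[:-1, 1]} vs {seg[1:, 0]})"
            )

    @property
    def t_start(self) -> float:
        return float(self.segments[0, 0])

    @property
    def t_end(self) -> float:
        return float(self.segments[-1, 1])

    def _segment_index(self, day: float) -> int:
        # right-continuous: at a shared breakpoint use the later segment
        idx = int(np.searchsorted(self.segments[:, 0], day, side="right")) - 1
        return max(idx, 0)

    def __call__(self, day: float) -> float:
        day = float(day)
        if day < self.t_start:
            if not self.maternal:
                return 0.0
            day = self.t_start
        elif day > self.t_end:
            day = self.t_end
        _, _, a, b = self.segments[self._segment_index(day)]
        return max(a * day + b, 0.0)

    def linear_pieces(self) -> list[tuple[float, float, float, float]]:
        """Segments refined so that ``a*t + b`` does not change sign inside any
        piece: rows ``(t_start, t_end, a, b)`` with clipped pieces as (a=0, b=0).

        Used by the simulator to keep the rate matrix exactly linear in ``t``
        between breakpoints.
        """
        pieces: list[tuple[float, float, float, float]] = []
        for t0, t1, a, b in self.segments:
            crossings = []
            if a != 0.0:
                tc = -b / a
                if t0 < tc < t1:
                    crossings = [tc]
            bounds = [t0, *crossings, t1]
            for lo, hi in zip(bounds[:-1], bounds[1:]):
                mid = 0.5 * (lo + hi)
                if a * mid + b <= 0:
                    pieces.append((lo, hi, 0.0, 0.0))
                else:
                    pieces.append((lo, hi, a, b))
        return pieces


def fit_linear_segments(
    points: list[tuple[float, float]] | np.ndarray,
    breakpoints: list[float] | None = None,
) -> list[tuple[float, float]]:
    """Ordinary least-squares slope/intercept per segment of (day, k) points.

    ``breakpoints`` are interior segment boundaries; points on a boundary are
    assigned to both adjacent segments.  Each segment needs at least two
    points (exact line through two).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (day, k) pairs")
    days, ks = pts[:, 0], pts[:, 1]
    bounds = [-np.inf, *(breakpoints or []), np.inf]
    fits = []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        sel = (days >= lo) & (days <= hi)
        if sel.sum() < 2:
            raise ConfigurationError(f"segment ({lo}, {hi}) has fewer than two points")
        a, b = np.polyfit(days[sel], ks[sel], 1)
        fits.append((float(a), float(b)))
    return fits


# ---------------------------------------------------------------------------
# packaged rate table

class RateTable:
    """The packaged piecewise-linear transfer-coefficient parameterization."""

    def __init__(self, rates: dict[tuple[str, str], PiecewiseLinearRate]):
        self._rates = rates

    @classmethod
    def from_frames(cls, maternal: pd.DataFrame, fetal: pd.DataFrame) -> "RateTable":
        rates: dict[tuple[str, str], PiecewiseLinearRate] = {}
        for frame, is_maternal in ((maternal, True), (fetal, False)):
            for (src, dst), grp in frame.groupby(["from", "to"], sort=False):
                seg = grp.sort_values("t_start")[["t_start", "t_end", "a", "b"]].to_numpy(float)
                rates[(src, dst)] = PiecewiseLinearRate(src, dst, seg, maternal=is_maternal)
        return cls(rates)

    @classmethod
    def from_packaged_data(cls) -> "RateTable":
        def read(name: str) -> pd.DataFrame:
            with resources.files("radonpreg.data").joinpath(name).open() as fh:
                return pd.read_csv(fh)

        return cls.from_frames(read("regressions_maternal.csv"), read("regressions_fetal.csv"))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._rates

    def pairs(self) -> list[tuple[str, str]]:
        return list(self._rates)

    def rate(self, source: str, target: str) -> PiecewiseLinearRate:
        try:
            return self._rates[(source, target)]
        except KeyError:
            raise ConfigurationError(
                f"no packaged transfer coefficient for {source!r} -> {target!r}"
            ) from None

    def evaluate(self, source: str, target: str, day: float) -> float:
        return self.rate(source, target)(day)

    def slope(self, source: str, target: str, day: float) -> float:
        """The regression slope ``a`` of the segment containing *day*."""
        rate = self.rate(source, target)
        return float(rate.segments[rate._segment_index(day)][2])


@lru_cache(maxsize=1)
def packaged_rate_table() -> RateTable:
    return RateTable.from_packaged_data()


def evaluate_packaged(source: str, target: str, day: float) -> float:
    """Evaluate the packaged coefficient ``source -> target`` (per day) at *day*."""
    return packaged_rate_table().evaluate(source, target, day)


# ---------------------------------------------------------------------------
# derivation route: Fick kinetics on the physiology tables

def derive_uterus_uptake(day: float, lib: PhysiologyLibrary | None = None) -> float:
    """Arterial-blood→uterus coefficient from uterine flow and arterial volume."""
    lib = lib or default_library()
    flow = lib.maternal_tissue_flow("uterus", day)
    return rate_in(flow, lib.constant("volume_arterial_blood"))


def derive_placenta_loop(day: float, lib: PhysiologyLibrary | None = None) -> tuple[float, float]:
    """(uterus→placenta, placenta→uterus) coefficients from the uteroplacental flow.

    Both directions use the placental volume (the exchange compartment, with a
    blood-equivalent partition P = 1) and the balanced uteroplacental flow.
    """
    lib = lib or default_library()
    flow = physiology.uteroplacental_flow(day) * ML_PER_MIN_TO_L_PER_DAY
    volume = lib.placenta_mass(day) / 1000.0 / lib.constant("tissue_density")
    k_up = rate_in(flow, volume)
    k_pu = rate_out(flow, volume, lib.partition("placenta"))
    return k_up, k_pu


_ORGAN_TO_PARTITION = {
    "brain": "brain",
    "kidneys": "kidney",
    "liver": "liver",
    "lungs": "lung",
    "adipose": "fat",
    "bone": "bone",
}

_COMPARTMENT_TO_ORGAN = {
    "fetal-brain": "brain",
    "fetal-kidneys": "kidneys",
    "fetal-liver": "liver",
    "fetal-lungs": "lungs",
    "fetal-adipose": "adipose",
    "fetal-bone": "bone",
}


def derive_fetal_organ_rates(
    organ: str, day: float, lib: PhysiologyLibrary | None = None
) -> tuple[float, float]:
    """(venous-cord-blood→organ, organ→arterial-cord-blood) from fetal physiology.

    Uptake divides the organ flow by the venous cord-blood volume (a
    calibration fraction of the total fetal blood volume); washout divides it
    by organ volume × adult partition coefficient.  Applies the ramp-in rule
    for the adipose compartment.
    """
    lib = lib or default_library()
    organ = _COMPARTMENT_TO_ORGAN.get(organ, organ)
    if organ not in _ORGAN_TO_PARTITION:
        raise ConfigurationError(f"no derivation recipe for fetal organ {organ!r}")
    day = physiology.check_day(day, low=physiology.FETAL_MODEL_START)
    flow = lib.fetal_flow(organ, day)
    total_mass = lib.fetal_mass("total-body", day)
    v_blood = physiology.fetal_blood_volume(total_mass, lib)
    v_vcb = v_blood * lib.constant("vcb_volume_fraction")
    k_in = rate_in(flow, v_vcb)
    organ_volume = lib.fetal_mass(organ, day) / 1000.0 / lib.constant("tissue_density")
    k_out = rate_out(flow, organ_volume, lib.partition(_ORGAN_TO_PARTITION[organ]))
    if organ == "adipose":
        k_in = apply_ramp(k_in, ADIPOSE_RAMP, day)
        k_out = apply_ramp(k_out, ADIPOSE_RAMP, day)
    return k_in, k_out
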