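"""Recomputation of the model's headline reference numbers.

Everything here is computed from the packaged parameterization at call time:
nothing is looked up.  Used by the ``reproduce`` CLI command and by the
repository's acceptance script.
"""

from __future__ import annotations

import numpy as np

from .model import ModelParameters, default_parameters, load_baseline, subtract_uterus_from_other
from .simulate import acute_fetal_fraction

__all__ = [
    "ACUTE_SCAN_DAYS",
    "peak_acute_fetal_fraction_pct",
    "adjusted_other_coefficient",
    "cord_blood_adipose_coefficient",
    "reproduce_summary",
]

#: intake days scanned for the acute-exposure bound (every ~5 weeks from the
#: placental start of the fetal model to term)
ACUTE_SCAN_DAYS: tuple[float, ...] = (105.0, 140.0, 175.0, 210.0, 245.0, 280.0)


def peak_acute_fetal_fraction_pct(
    params: ModelParameters | None = None,
    scan_days: tuple[float, ...] = ACUTE_SCAN_DAYS,
    route: str = "inhalation",
) -> tuple[float, dict[float, float]]:
    """Maximum peak fetal-side fraction of a unit acute intake, in percent,
    over the scanned intake days (inclusive tally: fetal tissues + cord blood
    + placenta)."""
    params = params or default_parameters()
    per_day = {d: 100.0 * acute_fetal_fraction(d, route=route, params=params) for d in scan_days}
    return max(per_day.values()), per_day


def adjusted_other_coefficient(params: ModelParameters | None = None) -> float:
    """Arterial-blood→other coefficient (per day) after uterus extraction,
    recomputed from the pre-extraction baseline file."""
    params = params or default_parameters()
    lib = params.library
    adjusted = subtract_uterus_from_other(
        load_baseline(),
        lib.constant("uterine_flow_nonpregnant"),
        lib.constant("volume_arterial_blood"),
    )
    return adjusted.rate("arterial-blood", "other")


def cord_blood_adipose_coefficient(
    params: ModelParameters | None = None,
    days: tuple[float, ...] = (175.0, 200.0, 240.0, 280.0),
) -> float:
    """Venous-cord-blood→fetal-adipose coefficient after its ramp-in;
    verifies constancy across *days* and returns the common value (per day)."""
    params = params or default_parameters()
    values = [params.rate_table.evaluate("venous-cord-blood", "fetal-adipose", d) for d in days]
    if not np.allclose(values, values[0], rtol=1e-12, atol=0.0):
        raise AssertionError(f"cord-blood→adipose coefficient not constant over {days}: {values}")
    return float(values[0])


def reproduce_summary(params: ModelParameters | None = None) -> list[dict]:
    """Observed-vs-reference table for the model's headline numbers."""
    params = params or default_parameters()
    peak_pct, per_day = peak_acute_fetal_fraction_pct(params)
    rows = [
        {
            "quantity": "peak acute fetal fraction over intake days 105-280 (% of intake)",
            "observed": peak_pct,
            "reference": 1e-3,
            "comparison": "<=",
            "ok": peak_pct <= 1e-3,
            "detail": {f"day {d:g}": v for d, v in per_day.items()},
        },
        {
            "quantity": "arterial-blood→other after uterus extraction (1/day)",
            "observed": adjusted_other_coefficient(params),
            "reference": 5.02e3,
            "comparison": "==",
            "ok": abs(adjusted_other_coefficient(params) - 5.02e3) < 0.5,
        },
        {
            "quantity": "venous-cord-blood→fetal-adipose, constant on [175, 280] (1/day)",
            "observed": cord_blood_adipose_coefficient(params),
            "reference": 1.0e3,
            "comparison": "==",
            "ok": abs(cord_blood_adipose_coefficient(params) - 1.0e3) < 0.5,
        },
    ]
    return rows
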