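"""Compartment structure and assembly of the time-dependent rate matrix.

The model has 24 compartments: the maternal systemic model (lung air, arterial
and venous blood, two fat pools, glandular and adipose breast, kidneys, liver,
uterus and an aggregated "other"), an absorbing exhaled-air sink that makes
exhalation explicit and mass balance testable, and — from gestational day 105,
when the placenta is fully developed — the placenta, venous and arterial cord
blood, and nine fetal tissues.  Radon reaches the fetus only through
uterus → placenta → venous cord blood, and returns only through
arterial cord blood → placenta → uterus.

The state equation is ``dA/dt = K(t) A + s(t)`` with ``K`` assembled here:
off-diagonal entry ``(j, i)`` is the transfer coefficient i→j, and each
diagonal balances the outflows of its column plus the radioactive decay
constant (sink excepted: what has been exhaled stays counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources

import networkx as nx
import numpy as np
import yaml

from .physiology import ConfigurationError, PhysiologyLibrary, check_day, default_library
from .rates import RateTable, packaged_rate_table, rate_in

__all__ = [
    "COMPARTMENTS",
    "MATERNAL_COMPARTMENTS",
    "FETAL_COMPARTMENTS",
    "SINK",
    "MissingEdgeError",
    "BaselineParameters",
    "load_baseline",
    "subtract_uterus_from_other",
    "ModelParameters",
    "default_parameters",
    "build_graph",
    "RateMatrix",
    "assemble_rate_matrix",
    "rate_matrix_breakpoints",
    "rate_matrix_linear",
    "validate_parameterization",
]


class MissingEdgeError(ConfigurationError):
    """A structural edge has no parameter that covers it."""


@lru_cache(maxsize=1)
def _model_definition() -> dict:
    with resources.files("radonpreg.data").joinpath("model.yaml").open() as fh:
        return yaml.safe_load(fh)


def _compartment_table() -> dict[str, dict]:
    return {c["id"]: c for c in _model_definition()["compartments"]}


COMPARTMENTS: tuple[str, ...] = tuple(c["id"] for c in _model_definition()["compartments"])
SINK = "exhaled-air"
MATERNAL_COMPARTMENTS: tuple[str, ...] = tuple(
    c["id"] for c in _model_definition()["compartments"] if c["group"] == "maternal"
)
#: fetal-side compartments in the inclusive sense: fetal tissues plus the
#: cord blood and the placenta (the exchange interface)
FETAL_COMPARTMENTS: tuple[str, ...] = tuple(
    c["id"] for c in _model_definition()["compartments"] if c["group"] in ("fetal", "exchange")
)
FETAL_TISSUES: tuple[str, ...] = tuple(
    c["id"] for c in _model_definition()["compartments"] if c["group"] == "fetal"
)

ACTIVE_FROM: dict[str, float] = {c["id"]: float(c["active_from"]) for c in _model_definition()["compartments"]}


# ---------------------------------------------------------------------------
# baseline (non-pregnant adult female) constant coefficients

@dataclass(frozen=True)
class BaselineParameters:
    """Constant transfer coefficients of the adult-female baseline model.

    ``uterus_extracted`` records whether the uterine contribution has already
    been removed from the aggregated arterial-blood→other coefficient.
    """

    rates: dict[tuple[str, str], float]
    uterus_extracted: bool = False

    def rate(self, source: str, target: str) -> float:
        try:
            return self.rates[(source, target)]
        except KeyError:
            raise MissingEdgeError(f"baseline has no coefficient {source!r} -> {target!r}") from None


def load_baseline() -> BaselineParameters:
    """Load the packaged baseline file (arterial→other still pre-extraction)."""
    import pandas as pd

    with resources.files("radonpreg.data").joinpath("baseline_rates.csv").open() as fh:
        frame = pd.read_csv(fh)
    rates = {
        (row["from"], row["to"]): float(row["k_per_day"]) for _, row in frame.iterrows()
    }
    if any(v < 0 for v in rates.values()):
        raise ConfigurationError("baseline coefficients must be non-negative")
    return BaselineParameters(rates=rates, uterus_extracted=False)


def subtract_uterus_from_other(
    baseline: BaselineParameters,
    uterus_flow_l_per_day: float,
    arterial_volume_l: float | None = None,
) -> BaselineParameters:
    """Remove the uterine contribution from the aggregated "other" coefficient.

    With the uterus promoted to an explicit compartment, its blood flow must
    leave the "other" pool to avoid double counting: the arterial-blood→other
    coefficient drops by the uterine uptake ``F_uterus / V_arterial`` and stays
    constant thereafter.  The other→liver and other→venous-blood washout
    coefficients are unchanged.
    """
    if baseline.uterus_extracted:
        raise ValueError("uterus contribution already extracted from this baseline")
    if arterial_volume_l is None:
        arterial_volume_l = default_library().constant("volume_arterial_blood")
    contribution = rate_in(uterus_flow_l_per_day, arterial_volume_l)
    adjusted = baseline.rate("arterial-blood", "other") - contribution
    if adjusted < 0:
        raise ConfigurationError(
            f"uterus extraction drives arterial-blood->other negative ({adjusted:.3g})"
        )
    rates = dict(baseline.rates)
    rates[("arterial-blood", "other")] = adjusted
    return BaselineParameters(rates=rates, uterus_extracted=True)


# ---------------------------------------------------------------------------
# full parameter bundle

@dataclass(frozen=True)
class ModelParameters:
    """Everything needed to assemble K(t): tables, baseline, decay, toggles."""

    rate_table: RateTable
    baseline: BaselineParameters
    lambda_decay: float
    library: PhysiologyLibrary
    ventilation_enabled: bool = True
    inclusive_fetal_tally: bool = True

    def without_ventilation(self) -> "ModelParameters":
        """A sealed variant: the lung-air→sink vent is disabled."""
        return replace(self, ventilation_enabled=False)

    def with_decay(self, lambda_decay: float) -> "ModelParameters":
        return replace(self, lambda_decay=lambda_decay)


def default_parameters(
    lambda_decay: float | None = None,
    library: PhysiologyLibrary | None = None,
) -> ModelParameters:
    """Packaged tables, extracted baseline and the Rn-222 decay constant."""
    library = library or default_library()
    if lambda_decay is None:
        lambda_decay = np.log(2.0) / library.constant("rn222_half_life")
    baseline = subtract_uterus_from_other(
        load_baseline(),
        library.constant("uterine_flow_nonpregnant"),
        library.constant("volume_arterial_blood"),
    )
    return ModelParameters(
        rate_table=packaged_rate_table(),
        baseline=baseline,
        lambda_decay=float(lambda_decay),
        library=library,
    )


# ---------------------------------------------------------------------------
# graph construction

def _edges() -> list[dict]:
    return _model_definition()["edges"]


def build_graph(day: float) -> nx.DiGraph:
    """The directed transfer structure active at gestational *day*.

    Before day 105 only the maternal subgraph exists; fetal compartments join
    at their activation days (thyroid, marrow and "other" at 126, adipose at
    161), with edges present from the activation day even while the ramped
    coefficient is still zero.
    """
    day = check_day(day)
    g = nx.DiGraph(day=day)
    for comp, meta in _compartment_table().items():
        if day >= meta["active_from"]:
            g.add_node(comp, group=meta["group"])
    for edge in _edges():
        src, dst = edge["from"], edge["to"]
        if src in g and dst in g:
            g.add_edge(src, dst, source=edge["source"])
    return g


# ---------------------------------------------------------------------------
# rate-matrix assembly

@dataclass(frozen=True)
class RateMatrix:
    """Numeric rate matrix at a gestational day, column convention i→row j."""

    day: float
    compartments: tuple[str, ...]
    matrix: np.ndarray
    lambda_decay: float

    def index(self, compartment: str) -> int:
        return self.compartments.index(compartment)

    def entry(self, source: str, target: str) -> float:
        return float(self.matrix[self.index(target), self.index(source)])


def _edge_rate(params: ModelParameters, edge: dict, day: float) -> float:
    src, dst = edge["from"], edge["to"]
    source = edge["source"]
    if source == "baseline":
        if (src, dst) == ("lung-air", SINK) and not params.ventilation_enabled:
            return 0.0
        return params.baseline.rate(src, dst)
    if source in ("maternal-table", "fetal-table"):
        if (src, dst) not in params.rate_table:
            raise MissingEdgeError(f"rate table has no entry for edge {src!r} -> {dst!r}")
        return params.rate_table.evaluate(src, dst, day)
    raise ConfigurationError(f"unknown edge source {source!r} for {src}->{dst}")


def assemble_rate_matrix(
    day: float,
    params: ModelParameters | None = None,
    lambda_decay: float | None = None,
) -> RateMatrix:
    """Assemble K at *day*: off-diagonals from the parameterization, diagonals
    balancing outflows plus decay (no decay on the exhaled-air sink)."""
    params = params or default_parameters()
    lam = params.lambda_decay if lambda_decay is None else float(lambda_decay)
    day = check_day(day)
    n = len(COMPARTMENTS)
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    k = np.zeros((n, n))
    for edge in _edges():
        value = _edge_rate(params, edge, day)
        i, j = idx[edge["from"]], idx[edge["to"]]
        k[j, i] += value
        k[i, i] -= value
    # decay on active body compartments only: inactive fetal compartments keep
    # identically zero rows/columns (they hold no activity by construction)
    for comp, i in idx.items():
        if comp != SINK and ACTIVE_FROM[comp] <= day:
            k[i, i] -= lam
    return RateMatrix(day=day, compartments=COMPARTMENTS, matrix=k, lambda_decay=lam)


def rate_matrix_breakpoints(params: ModelParameters | None = None) -> np.ndarray:
    """Gestational days at which K(t) changes slope (segment bounds and
    zero-crossings of clipped regression lines)."""
    params = params or default_parameters()
    days: set[float] = {0.0, 280.0}
    for pair in params.rate_table.pairs():
        for t0, t1, _, _ in params.rate_table.rate(*pair).linear_pieces():
            days.update((float(t0), float(t1)))
    return np.array(sorted(d for d in days if 0.0 <= d <= 280.0))


def rate_matrix_linear(
    t0: float,
    t1: float,
    params: ModelParameters | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(K0, K1) with K(t) = K0 + t·K1 exactly on the breakpoint-free interval
    (t0, t1); raises if a rate changes slope inside the interval."""
    params = params or default_parameters()
    n = len(COMPARTMENTS)
    idx = {c: i for i, c in enumerate(COMPARTMENTS)}
    k0 = np.zeros((n, n))
    k1 = np.zeros((n, n))
    mid = 0.5 * (t0 + t1)

    def add(i: int, j: int, b: float, a: float) -> None:
        k0[j, i] += b
        k0[i, i] -= b
        k1[j, i] += a
        k1[i, i] -= a

    for edge in _edges():
        i, j = idx[edge["from"]], idx[edge["to"]]
        if edge["source"] == "baseline":
            add(i, j, _edge_rate(params, edge, mid), 0.0)
            continue
        rate = params.rate_table.rate(edge["from"], edge["to"])
        if mid <= rate.t_start:
            if rate.maternal:  # clamp to the boundary value, constant in t
                add(i, j, rate(rate.t_start), 0.0)
            continue  # fetal edge not yet active: zero
        if mid >= rate.t_end:
            add(i, j, rate(rate.t_end), 0.0)
            continue
        piece = next((p for p in rate.linear_pieces() if p[0] <= mid <= p[1]), None)
        if piece is None or t0 < piece[0] - 1e-9 or t1 > piece[1] + 1e-9:
            raise ValueError(
                f"interval ({t0}, {t1}) crosses a breakpoint of {edge['from']}->{edge['to']}"
            )
        _, _, a, b = piece
        add(i, j, b, a)
    lam = params.lambda_decay
    for comp, i in idx.items():
        if comp != SINK and ACTIVE_FROM[comp] <= mid:
            k0[i, i] -= lam
    return k0, k1


# ---------------------------------------------------------------------------
# validation

def validate_parameterization(params: ModelParameters | None = None) -> list[str]:
    """Structural checks: segment contiguity, non-negativity after clipping,
    and coverage of every graph edge at every activation epoch.  Returns a
    list of problem descriptions (empty = valid)."""
    params = params or default_parameters()
    problems: list[str] = []
    sample_days = np.linspace(0.0, 280.0, 281)
    for pair in params.rate_table.pairs():
        try:
            rate = params.rate_table.rate(*pair)  # construction re-validates segments
        except ConfigurationError as err:
            problems.append(str(err))
            continue
        values = np.array([rate(d) for d in sample_days])
        if np.any(values < 0):
            problems.append(f"{pair[0]}->{pair[1]}: negative value after clipping")
    for day in (50.0, 105.0, 126.0, 161.0, 200.0, 280.0):
        try:
            assemble_rate_matrix(day, params)
        except MissingEdgeError as err:
            problems.append(f"day {day}: {err}")
    for edge in _edges():
        src, dst = edge["from"], edge["to"]
        if edge["source"] == "baseline":
            if (src, dst) not in params.baseline.rates:
                problems.append(f"missing baseline coefficient for edge {src}->{dst}")
        elif (src, dst) not in params.rate_table:
            problems.append(f"missing packaged regression for edge {src}->{dst}")
    return problems
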