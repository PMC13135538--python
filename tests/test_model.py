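"""Compartment graph, baseline adjustment and rate-matrix assembly."""

import networkx as nx
import numpy as np
import pytest

from radonpreg import (
    COMPARTMENTS,
    assemble_rate_matrix,
    build_graph,
    default_parameters,
    evaluate_packaged,
    load_baseline,
    subtract_uterus_from_other,
)
from radonpreg.model import SINK, MissingEdgeError, validate_parameterization
from radonpreg.physiology import ConfigurationError


class TestGraph:
    def test_maternal_subgraph_before_placentation(self):
        g = build_graph(50.0)
        assert "uterus" in g
        assert "placenta" not in g
        assert not any("fetal" in c for c in g.nodes)

    def test_placental_transfer_from_day_105(self):
        assert not build_graph(104.9).has_node("placenta")
        g = build_graph(105.0)
        assert g.has_edge("uterus", "placenta")
        assert g.has_edge("placenta", "venous-cord-blood")

    def test_late_compartments_join_at_activation_days(self):
        assert "fetal-thyroid" not in build_graph(125.0)
        assert build_graph(126.0).has_edge("venous-cord-blood", "fetal-thyroid")
        assert "fetal-adipose" not in build_graph(160.0)
        g161 = build_graph(161.0)
        assert g161.has_edge("venous-cord-blood", "fetal-adipose")
        # present with a still-zero ramped coefficient
        assert evaluate_packaged("venous-cord-blood", "fetal-adipose", 161.0) == 0.0

    @pytest.mark.parametrize("day, reachable", [(50.0, False), (104.0, False), (105.0, True), (200.0, True)])
    def test_fetal_reachability_from_arterial_blood(self, day, reachable):
        g = build_graph(day)
        if "fetal-brain" not in g:
            assert not reachable
            return
        assert nx.has_path(g, "arterial-blood", "fetal-brain") == reachable

    def test_fetal_return_path_via_arterial_cord_blood(self):
        g = build_graph(200.0)
        path = nx.shortest_path(g, "fetal-brain", "venous-blood")
        assert path[:3] == ["fetal-brain", "arterial-cord-blood", "placenta"]

    def test_24_compartments_at_term(self):
        assert len(build_graph(280.0)) == len(COMPARTMENTS) == 24


class TestBaselineAdjustment:
    def test_zero_flow_leaves_baseline_unchanged(self):
        base = load_baseline()
        adj = subtract_uterus_from_other(base, 0.0, 1.1)
        assert adj.rate("arterial-blood", "other") == base.rate("arterial-blood", "other")

    def test_packaged_extraction_value(self, library):
        adj = subtract_uterus_from_other(
            load_baseline(),
            library.constant("uterine_flow_nonpregnant"),
            library.constant("volume_arterial_blood"),
        )
        assert adj.rate("arterial-blood", "other") == pytest.approx(5.02e3, abs=1e-6)

    def test_extraction_additivity(self, library):
        base = load_baseline()
        flow = library.constant("uterine_flow_nonpregnant")
        v = library.constant("volume_arterial_blood")
        adj = subtract_uterus_from_other(base, flow, v)
        assert adj.rate("arterial-blood", "other") + flow / v == pytest.approx(
            base.rate("arterial-blood", "other"), rel=1e-12
        )

    def test_double_extraction_rejected(self, library):
        adj = subtract_uterus_from_other(load_baseline(), 10.0, 1.1)
        with pytest.raises(ValueError):
            subtract_uterus_from_other(adj, 10.0, 1.1)

    def test_overdraw_rejected(self):
        with pytest.raises(ConfigurationError):
            subtract_uterus_from_other(load_baseline(), 1e9, 1.1)


class TestRateMatrix:
    def test_fetal_rows_zero_before_placentation(self, params):
        rm = assemble_rate_matrix(50.0, params)
        fetal_idx = [i for i, c in enumerate(COMPARTMENTS) if c not in
                     ("exhaled-air", "lung-air", "arterial-blood", "venous-blood", "fat1", "fat2",
                      "breast-g", "breast-a", "kidneys", "liver", "other", "uterus")]
        sub = rm.matrix[np.ix_(fetal_idx, range(len(COMPARTMENTS)))]
        assert np.all(sub == 0.0)
        assert np.all(rm.matrix[:, fetal_idx] == 0.0)

    @pytest.mark.parametrize("day", [50.0, 105.0, 200.0, 280.0])
    def test_mass_balance_columns_sum_to_zero_without_decay(self, params, day):
        rm = assemble_rate_matrix(day, params, lambda_decay=0.0)
        assert np.abs(rm.matrix.sum(axis=0)).max() < 1e-12 * np.abs(rm.matrix).max()

    def test_decay_appears_on_all_body_diagonals(self, params):
        lam = params.lambda_decay
        rm0 = assemble_rate_matrix(200.0, params, lambda_decay=0.0)
        rm1 = assemble_rate_matrix(200.0, params)
        diff = rm0.matrix - rm1.matrix
        for i, comp in enumerate(COMPARTMENTS):
            expected = 0.0 if comp == SINK else lam
            assert diff[i, i] == pytest.approx(expected)

    def test_off_diagonals_nonnegative(self, params):
        for day in (0.0, 130.0, 270.0):
            m = assemble_rate_matrix(day, params).matrix.copy()
            np.fill_diagonal(m, 0.0)
            assert m.min() >= 0.0

    def test_entries_match_packaged_table(self, params):
        rm = assemble_rate_matrix(200.0, params)
        assert rm.entry("uterus", "placenta") == evaluate_packaged("uterus", "placenta", 200.0)
        assert rm.entry("venous-cord-blood", "fetal-liver") == evaluate_packaged(
            "venous-cord-blood", "fetal-liver", 200.0
        )

    def test_assembly_deterministic(self, params):
        a = assemble_rate_matrix(173.25, params).matrix
        b = assemble_rate_matrix(173.25, params).matrix
        assert np.array_equal(a, b)

    def test_uteroplacental_loop_flow_symmetry(self, library):
        """The volumetric flow behind uterus→placenta equals the one behind
        placenta→uterus at every day (balanced circulation)."""
        from radonpreg import derive_placenta_loop

        for day in (105.0, 150.0, 220.0, 280.0):
            k_up, k_pu = derive_placenta_loop(day)
            v = library.placenta_mass(day) / 1000.0
            assert k_up * v == pytest.approx(k_pu * v * library.partition("placenta"), rel=1e-12)


class TestValidation:
    def test_packaged_parameterization_valid(self, params):
        assert validate_parameterization(params) == []

    def test_missing_edge_detected(self, params):
        from dataclasses import replace

        broken_rates = {k: v for k, v in params.rate_table._rates.items() if k != ("uterus", "placenta")}
        broken = replace(params, rate_table=type(params.rate_table)(broken_rates))
        problems = validate_parameterization(broken)
        assert any("uterus" in p and "placenta" in p for p in problems)
        with pytest.raises(MissingEdgeError):
            assemble_rate_matrix(200.0, broken)

    def test_overlapping_segments_detected(self):
        import pandas as pd

        from radonpreg.rates import RateTable

        maternal = pd.DataFrame(
            {
                "from": ["arterial-blood"] * 2,
                "to": ["uterus"] * 2,
                "t_start": [0.0, 100.0],
                "t_end": [150.0, 280.0],
                "a": [1.0, 1.0],
                "b": [0.0, 0.0],
            }
        )
        with pytest.raises(ConfigurationError):
            RateTable.from_frames(maternal, maternal.iloc[:0])
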