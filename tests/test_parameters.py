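"""Parameter loading, validation, and the hazard-based table builders."""

import logging
import math

import numpy as np
import pytest
import yaml
from hypothesis import given, settings
from hypothesis import strategies as st

from copdsim.parameters import (
    ParameterParseError,
    ParameterValidationError,
    SmokingStatus,
    Stage,
    build_mortality_table,
    build_progression_table,
    default_parameters,
    load_parameters,
    write_parameters,
)

MINIMAL_CONFIG = """
severity_distribution: {GOLD1: 0.3508, GOLD2: 0.4817, GOLD3: 0.1396, GOLD4: 0.0279}
quit_prob: 0.047
relapse_prob: 0.026
exacerbation_prob: {GOLD1: 0.25, GOLD2: 0.3945, GOLD3: 0.441, GOLD4: 0.657}
utility:
  stable: {GOLD1: 0.8971, GOLD2: 0.7511, GOLD3: 0.7481, GOLD4: 0.5493}
  exacerbated: {GOLD1: 0.8951, GOLD2: 0.7364, GOLD3: 0.7261, GOLD4: 0.5357}
annual_cost: {GOLD1: 220, GOLD2: 726, GOLD3: 3758, GOLD4: 9470}
"""


class TestDefaults:
    def test_reference_case_scalars(self, default_params):
        p = default_params
        assert p.severity_distribution == pytest.approx([0.3508, 0.4817, 0.1396, 0.0279])
        assert p.quit_prob == 0.047
        assert p.relapse_prob == 0.026
        assert p.exacerbation_prob[:, 0] == pytest.approx([0.25, 0.3945, 0.441, 0.657])
        # both smoking statuses share exacerbation risk in the reference case
        assert np.array_equal(p.exacerbation_prob[:, 0], p.exacerbation_prob[:, 1])
        assert p.utility[:, 0] == pytest.approx([0.8971, 0.7511, 0.7481, 0.5493])
        assert p.utility[:, 1] == pytest.approx([0.8951, 0.7364, 0.7261, 0.5357])
        assert p.annual_cost == pytest.approx([220, 726, 3758, 9470])
        assert p.annual_cost[Stage.GOLD4] == 9470
        assert p.discount_rate == 0.035
        assert p.max_age == 110

    def test_ex_smoker_dominance_cellwise(self, default_params):
        """Ex-smokers never progress or die more readily than smokers."""
        p = default_params
        sm, ex = SmokingStatus.SMOKER, SmokingStatus.EX_SMOKER
        assert np.all(p.progression_prob[:, :, ex] <= p.progression_prob[:, :, sm])
        assert np.all(p.death_prob[:, :, ex, :] <= p.death_prob[:, :, sm, :])

    def test_every_state_lookup_resolves(self, default_params):
        p = default_params
        ages = np.arange(40, p.max_age + 1)
        bands = p.band_index(ages)
        assert np.all((bands >= 0) & (bands < p.n_bands))
        vals = p.death_prob[:, bands, :, :]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_progression_death_fit_one_cycle(self, default_params):
        p = default_params
        total = p.progression_prob[:, :, :, None] + p.death_prob
        assert np.all(total <= 1)


class TestLoading:
    def test_minimal_config_fills_optionals_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="copdsim.parameters"):
            p = load_parameters(MINIMAL_CONFIG)
        assert p.discount_rate == 0.035
        assert p.max_age == 110
        assert any("discount_rate" in r.message for r in caplog.records)

    def test_probability_out_of_bounds_names_field(self):
        bad = MINIMAL_CONFIG.replace("quit_prob: 0.047", "quit_prob: 1.2")
        with pytest.raises(ParameterValidationError, match="quit_prob"):
            load_parameters(bad)

    def test_malformed_document_names_line(self):
        with pytest.raises(ParameterParseError, match="line"):
            load_parameters("quit_prob: [unclosed\n  - 1\n")

    def test_missing_required_key_rejected(self):
        bad = MINIMAL_CONFIG.replace("quit_prob: 0.047\n", "")
        with pytest.raises(ParameterParseError, match="quit_prob"):
            load_parameters(bad)

    def test_round_trip_reproduces_document(self, default_params):
        text = write_parameters(default_params)
        again = load_parameters(text)
        assert yaml.safe_load(write_parameters(again)) == yaml.safe_load(text)
        assert np.array_equal(again.death_prob, default_params.death_prob)
        assert np.array_equal(again.progression_prob, default_params.progression_prob)


class TestProgressionBuilder:
    @pytest.mark.parametrize(
        "baseline, modifier, expected",
        [
            (0.0, 2.0, 0.0),  # no progression is a fixed point
            (0.10, 1.0, 0.10),  # identity modifier
            (0.10, 0.5, 1 - math.exp(0.5 * math.log(0.9))),
        ],
    )
    def test_rate_transform(self, baseline, modifier, expected):
        table = build_progression_table(
            np.full((3, 1), baseline), [1.0, modifier] if modifier <= 1 else [modifier, 1.0]
        )
        col = SmokingStatus.EX_SMOKER if modifier <= 1 else SmokingStatus.SMOKER
        assert table[0, 0, col] == pytest.approx(expected, abs=1e-12)

    def test_certain_baseline_clamps_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            table = build_progression_table(np.full((3, 1), 1.0), [1.0, 0.5])
        assert np.all(table[:3] == 1.0)
        assert any("clamp" in r.message for r in caplog.records)

    def test_negative_modifier_rejected(self):
        with pytest.raises(ParameterValidationError):
            build_progression_table(np.full((3, 1), 0.1), [1.0, -0.5])

    def test_ex_smoker_modifier_must_not_exceed_smoker(self):
        with pytest.raises(ParameterValidationError):
            build_progression_table(np.full((3, 1), 0.1), [0.5, 1.0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        baseline=st.floats(0.0, 0.99),
        mod_ex=st.floats(0.01, 1.0),
        mod_extra=st.floats(0.0, 3.0),
    )
    def test_dominance_and_bounds_hold_for_any_inputs(self, baseline, mod_ex, mod_extra):
        table = build_progression_table(
            np.full((3, 2), baseline), [mod_ex + mod_extra, mod_ex]
        )
        assert np.all((table >= 0) & (table <= 1))
        assert np.all(
            table[:, :, SmokingStatus.EX_SMOKER] <= table[:, :, SmokingStatus.SMOKER] + 1e-15
        )


class TestMortalityBuilder:
    def test_identity_hazards_recover_all_cause(self):
        ac = np.array([0.01, 0.05, 0.2])
        t = build_mortality_table(ac, np.ones(4), np.ones(2), np.ones(2))
        assert t[2, :, 0, 0] == pytest.approx(ac, abs=1e-12)

    def test_rate_domain_doubling(self):
        t = build_mortality_table(np.array([0.02]), np.full(4, 2.0), np.ones(2), np.ones(2))
        assert t[0, 0, 0, 0] == pytest.approx(1 - 0.98**2, abs=1e-12)

    def test_smoker_cell_exceeds_ex_smoker(self):
        t = build_mortality_table(np.array([0.05]), np.ones(4), np.array([1.5, 1.0]), np.ones(2))
        assert np.all(t[:, :, SmokingStatus.SMOKER, :] > t[:, :, SmokingStatus.EX_SMOKER, :])

    def test_negative_hazard_rejected(self):
        with pytest.raises(ParameterValidationError):
            build_mortality_table(np.array([0.05]), np.full(4, -1.0), np.ones(2), np.ones(2))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(ac=st.floats(0.0, 0.95), h=st.floats(0.0, 10.0), extra=st.floats(0.0, 5.0))
    def test_monotone_in_each_hazard(self, ac, h, extra):
        lo = build_mortality_table(np.array([ac]), np.full(4, h), np.ones(2), np.ones(2))
        hi = build_mortality_table(np.array([ac]), np.full(4, h + extra), np.ones(2), np.ones(2))
        assert np.all(hi >= lo - 1e-15)


def test_default_parameters_are_independent_copies():
    a = default_parameters()
    b = default_parameters()
    a.annual_cost[0] = 999.0
    assert b.annual_cost[0] == 220.0
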