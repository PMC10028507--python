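"""Payoff matrix, expected payoffs, closed-form gains and the equation audit."""

import math

import pytest
from hypothesis import given

from ehrgame import (
    BASELINE,
    GovStrategy,
    HospitalStrategy,
    MixedState,
    ParameterSet,
    PatientStrategy,
    PureProfile,
    all_profiles,
    derivation_audit,
    expected_payoffs_enumerated,
    gain_closed_form,
    gain_parameter_support,
    gains_enumerated,
    payoff_triple,
)
from ehrgame.params import ConstraintError

from conftest import mixed_states, parameter_sets, random_parameter_set

PUSH, NEG = GovStrategy.PUSH, GovStrategy.NEGATIVE
ACT, PAS = HospitalStrategy.ACTIVE, HospitalStrategy.PASSIVE
SUP, WAI = PatientStrategy.SUPERVISE, PatientStrategy.WAIVE

ZEROS = ParameterSet.zeros()


class TestParameterSet:
    def test_strict_mode_enforces_orderings(self):
        with pytest.raises(ConstraintError, match="Cg > Kg"):
            ParameterSet(**{**BASELINE.as_dict(), "Cg": 2.0, "Kg": 5.0})
        with pytest.raises(ConstraintError, match="Ch > Kh"):
            ParameterSet(**{**BASELINE.as_dict(), "Ch": 1.0, "Kh": 5.0})

    def test_nonnegativity_always_enforced(self):
        with pytest.raises(ConstraintError, match="nonnegative"):
            ParameterSet(**{**BASELINE.as_dict(), "Rg": -1.0}, strict=False)

    def test_test_mode_admits_degenerate_sets(self):
        assert ZEROS.Cg == ZEROS.Kg == 0.0

    def test_twelve_parameters(self):
        assert len(BASELINE.as_dict()) == 12


class TestPayoffTriple:
    @pytest.mark.parametrize(
        "profile, params, expected",
        [
            # cooperative profile at baseline: (Rg-Cg-Fh-Fp, Rh-Ch+Fh, Fp-Cp)
            (PureProfile(PUSH, ACT, SUP), BASELINE, (14.0, 51.0, 1.0)),
            # universal defection at baseline: (-Kg-Fg, -Kh, -Rp)
            (PureProfile(NEG, PAS, WAI), BASELINE, (-7.0, -5.0, -6.0)),
            (PureProfile(PUSH, PAS, SUP), ZEROS, (0.0, 0.0, 0.0)),
            (PureProfile(PUSH, ACT, WAI), BASELINE, (16.0, 51.0, 0.0)),
            (PureProfile(PUSH, PAS, WAI), BASELINE, (34.0, -15.0, -6.0)),
            (PureProfile(NEG, ACT, SUP), BASELINE, (-3.0, 43.0, -1.0)),
            (PureProfile(NEG, ACT, WAI), BASELINE, (-3.0, 43.0, 0.0)),
            (PureProfile(NEG, PAS, SUP), BASELINE, (-7.0, -5.0, -1.0)),
            (PureProfile(PUSH, PAS, SUP), BASELINE, (34.0, -15.0, -5.0)),
        ],
    )
    def test_matrix_cells(self, profile, params, expected):
        assert payoff_triple(profile, params).as_tuple() == expected

    def test_invalid_profile_rejected(self):
        with pytest.raises(TypeError):
            PureProfile("push", ACT, SUP)
        with pytest.raises(TypeError):
            payoff_triple("not-a-profile", BASELINE)

    def test_eight_distinct_profiles(self):
        assert len(set(all_profiles())) == 8


class TestExpectedPayoffs:
    def test_degenerate_mixture_selects_pure_cell(self, baseline):
        e = expected_payoffs_enumerated(MixedState(1, 1, 1), baseline)
        assert (e.Eg1, e.Eh1, e.Ep1) == (14.0, 51.0, 1.0)

    def test_equal_weights_patient_gain(self, baseline):
        e = expected_payoffs_enumerated(MixedState(0.5, 0.5, 0.5), baseline)
        assert e.Ep1 - e.Ep2 == pytest.approx(1.5, abs=1e-12)

    def test_all_zero_parameters_give_zero_payoffs(self):
        e = expected_payoffs_enumerated(MixedState(0.3, 0.7, 0.2), ZEROS)
        assert all(v == 0.0 for v in vars(e).values())

    def test_state_outside_cube_rejected(self, baseline):
        with pytest.raises(ConstraintError):
            expected_payoffs_enumerated((1.2, 0.5, 0.5), baseline)

    @given(state=mixed_states(), params=parameter_sets())
    def test_mixture_identities(self, state, params):
        e = expected_payoffs_enumerated(state, params)
        scale = max(1.0, abs(e.Eg), abs(e.Eh), abs(e.Ep))
        assert abs(e.Eg - (state.x * e.Eg1 + (1 - state.x) * e.Eg2)) <= 1e-9 * scale
        assert abs(e.Eh - (state.y * e.Eh1 + (1 - state.y) * e.Eh2)) <= 1e-9 * scale
        assert abs(e.Ep - (state.z * e.Ep1 + (1 - state.z) * e.Ep2)) <= 1e-9 * scale

    @pytest.mark.parametrize("y", [0.0, 1.0])
    @pytest.mark.parametrize("z", [0.0, 1.0])
    def test_conditional_expectation_degeneracy(self, y, z, baseline):
        """At y, z in {0,1} the government conditionals are single cells."""
        e = expected_payoffs_enumerated(MixedState(0.3, y, z), baseline)
        hosp = ACT if y == 1.0 else PAS
        pat = SUP if z == 1.0 else WAI
        assert e.Eg1 == payoff_triple(PureProfile(PUSH, hosp, pat), baseline).u_g
        assert e.Eg2 == payoff_triple(PureProfile(NEG, hosp, pat), baseline).u_g


class TestGains:
    @pytest.mark.parametrize(
        "state, expected",
        [
            ((1, 1, 1), (17.0, 66.0, 1.0)),
            ((0, 0, 0), (41.0, 48.0, 5.0)),
        ],
    )
    def test_closed_form_baseline_values(self, state, expected, baseline):
        assert gain_closed_form(MixedState(*state), baseline).as_tuple() == expected

    def test_zero_parameters_zero_gains(self):
        g = gain_closed_form(MixedState(0.4, 0.6, 0.1), ZEROS)
        assert g.as_tuple() == (0.0, 0.0, 0.0)

    @given(state=mixed_states(), params=parameter_sets())
    def test_closed_form_equals_enumeration(self, state, params):
        """Oracle equivalence: closed forms vs payoff-matrix enumeration."""
        closed = gain_closed_form(state, params).as_tuple()
        enum = gains_enumerated(state, params).as_tuple()
        for c, e in zip(closed, enum):
            assert math.isclose(c, e, rel_tol=1e-9, abs_tol=1e-9)

    def test_closed_form_equals_enumeration_bulk(self, rng):
        """The same equivalence over 1000 seeded random (state, params) pairs."""
        for _ in range(1000):
            params = random_parameter_set(rng)
            state = MixedState(*rng.uniform(0, 1, 3))
            closed = gain_closed_form(state, params).as_tuple()
            enum = gains_enumerated(state, params).as_tuple()
            for c, e in zip(closed, enum):
                assert math.isclose(c, e, rel_tol=1e-9, abs_tol=1e-9)

    @pytest.mark.parametrize(
        "gain, param, sign",
        [
            ("g_x", "Rg", +1), ("g_x", "Fg", +1), ("g_x", "Kg", +1),
            ("g_x", "Mh", +1), ("g_x", "Cg", -1),
            ("g_y", "Rh", +1), ("g_y", "Kh", +1), ("g_y", "Fh", +1),
            ("g_y", "Mh", +1), ("g_y", "Ch", -1),
            ("g_z", "Fp", +1), ("g_z", "Cp", -1),
        ],
    )
    def test_gain_monotone_in_parameters(self, gain, param, sign, baseline):
        """Each gain is monotone in every parameter, with the derived sign."""
        state = MixedState(0.6, 0.4, 0.7)
        lo = getattr(gain_closed_form(state, baseline), gain)
        # bump in test mode: a raised Kg/Kh may overtake its strict bound
        bumped = baseline.replace(**{param: getattr(baseline, param) + 5.0},
                                  strict=False)
        hi = getattr(gain_closed_form(state, bumped), gain)
        assert sign * (hi - lo) >= 0


class TestSymbolicLayer:
    def test_gain_parameter_support_sizes(self):
        support = gain_parameter_support()
        assert len(support["x"]) == 7
        assert len(support["y"]) == 5
        assert len(support["z"]) == 3

    def test_gain_parameter_support_members(self):
        support = gain_parameter_support()
        assert support["x"] == ("Cg", "Fg", "Fh", "Fp", "Kg", "Mh", "Rg")
        assert support["y"] == ("Ch", "Fh", "Kh", "Mh", "Rh")
        assert support["z"] == ("Cp", "Fp", "Rp")


@pytest.fixture(scope="module")
def audit():
    return {a.equation: a for a in derivation_audit(BASELINE)}


class TestDerivationAudit:
    def test_reduced_government_gain_matches(self, audit):
        entry = audit["g_x (government gain, reduced)"]
        assert entry.matches and entry.residual == "0"

    def test_system_form_government_line_flagged(self, audit):
        """The system-form x line carries a +Cg where the derivation has -Cg."""
        entry = audit["g_x (system form)"]
        assert not entry.matches
        assert entry.residual == "-2*Cg"
        assert float(entry.residual_at_params) == -12.0

    def test_reduced_hospital_gain_flagged_on_x_coefficient(self, audit):
        entry = audit["g_y (hospital gain, reduced)"]
        assert not entry.matches
        assert entry.residual.replace(" ", "") == "2*Fh*x+2*Mh*x"

    def test_patient_gain_flagged_with_yrp_residual(self, audit):
        entry = audit["g_z (patient gain, reduced)"]
        assert not entry.matches
        assert entry.residual == "2*Rp*x*y"

    def test_duplicated_term_variant_flagged(self, audit):
        entry = audit["E_h2 (hospital, passive)"]
        assert not entry.matches
        assert "Kh" in entry.residual

    def test_at_least_four_discrepancies_reported(self, audit):
        assert sum(not a.matches for a in audit.values()) >= 4

    def test_system_form_hospital_and_patient_lines_match(self, audit):
        assert audit["g_y (system form)"].matches
        assert audit["g_z (system form)"].matches
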