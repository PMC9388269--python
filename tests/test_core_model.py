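"""Parameter validation, incidence terms, and the vector fields."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from coexdyn import (
    ModelId,
    ParameterError,
    Parameters,
    dump_parameters,
    forces_of_infection,
    load_parameters,
    rhs,
    reference_parameters,
    validate_parameters,
)
from coexdyn.core_model import PARAM_NAMES, as_state
from coexdyn._symbolic import _P, _STATE_SYMS, vector_field_exprs


class TestValidation:
    def test_reference_parameters_accepted(self, ref_params):
        assert validate_parameters(ref_params) == ref_params
        assert ref_params.Lambda == 50.0 and ref_params.gamma1 == 0.007

    @pytest.mark.parametrize(
        "changes, field",
        [
            ({"omega1": 0.5}, "omega1"),
            ({"omega2": 0.99}, "omega2"),
            ({"mu": 0.0}, "mu"),
            ({"mu": -0.1}, "mu"),
            ({"Lambda": 0.0}, "Lambda"),
            ({"gamma2": -1e-9}, "gamma2"),
            ({"theta3": -0.2}, "theta3"),
            ({"alpha": float("nan")}, "alpha"),
        ],
    )
    def test_invalid_field_named_in_error(self, ref_params, changes, field):
        raw = ref_params.as_dict() | changes
        with pytest.raises(ParameterError, match=field):
            validate_parameters(raw)

    def test_missing_and_unknown_keys_rejected(self, ref_params):
        raw = ref_params.as_dict()
        del raw["sigma1"]
        with pytest.raises(ParameterError, match="sigma1"):
            validate_parameters(raw)
        raw = ref_params.as_dict() | {"delta": 1.0}
        with pytest.raises(ParameterError, match="delta"):
            validate_parameters(raw)

    def test_config_roundtrip(self, ref_params, tmp_path):
        for name in ("p.yaml", "p.json"):
            path = tmp_path / name
            dump_parameters(ref_params, path)
            assert load_parameters(path) == ref_params


class TestForcesOfInfection:
    def test_hand_computed_example(self):
        p = reference_parameters(alpha=0.1, beta=0.5, omega1=2.0, omega2=3.0)
        state = [50, 10, 5, 5, 10, 10, 10]  # N = 100
        foi = forces_of_infection(state, p)
        assert foi.lambda_C == pytest.approx(0.5 * (10 + 2 * 5) / 100)  # 0.1
        assert foi.lambda_R == pytest.approx(0.1 * (5 + 3 * 5))         # 2.0

    def test_zero_without_infectives_and_at_empty_population(self, ref_params):
        foi = forces_of_infection([100, 0, 0, 0, 5, 5, 5], ref_params)
        assert foi.lambda_C == 0.0 and foi.lambda_R == 0.0
        foi = forces_of_infection(np.zeros(7), ref_params)  # N = 0: no division fault
        assert foi.lambda_C == 0.0 and foi.lambda_R == 0.0

    def test_matches_endemic_force_of_toy_fixture(self, toy_racism):
        foi = forces_of_infection([5.0, 0, 10.0 / 3, 0, 0, 5.0 / 3, 0], toy_racism)
        assert foi.lambda_R == pytest.approx(0.04 * 10.0 / 3, rel=1e-12)

    def test_standard_incidence_variant_divides_by_population(self):
        p = reference_parameters(alpha=0.1, beta=0.5)
        state = [50, 10, 5, 5, 10, 10, 10]
        ma = forces_of_infection(state, p).lambda_R
        std = forces_of_infection(state, p, racism_incidence="standard").lambda_R
        assert std == pytest.approx(ma / 100)


class TestVectorField:
    def test_contagion_free_point_is_equilibrium(self, ref_params):
        dfe = np.array([ref_params.Lambda / ref_params.mu, 0, 0, 0, 0, 0, 0])
        for model in ModelId:
            assert np.allclose(rhs(model, dfe, ref_params), 0.0, atol=1e-12)

    def test_toy_racism_endemic_point_annihilates_rhs(self, toy_racism):
        state = [5.0, 0, 3.3333, 0, 0, 1.6667, 0]
        assert np.max(np.abs(rhs(ModelId.RACISM, state, toy_racism))) <= 1e-4
        exact = [5.0, 0, 10.0 / 3, 0, 0, 5.0 / 3, 0]
        assert np.max(np.abs(rhs(ModelId.RACISM, exact, toy_racism))) <= 1e-9

    def test_nonfinite_state_rejected(self, ref_params):
        with pytest.raises(ValueError):
            rhs(ModelId.FULL, [np.inf, 0, 0, 0, 0, 0, 0], ref_params)

    @pytest.mark.parametrize("model", list(ModelId))
    def test_submodel_restriction_of_full_field(self, model, ref_params, rng):
        from coexdyn.core_model import active_indices, pin_absent

        state = rng.uniform(0, 500, size=7)
        pinned = pin_absent(model, state)
        d_model = rhs(model, state, ref_params)
        d_full = rhs(ModelId.FULL, pinned, ref_params)
        idx = list(active_indices(model))
        assert np.allclose(d_model[idx], d_full[idx], rtol=1e-12, atol=1e-12)

    def test_symbolic_transfer_terms_cancel_exactly(self):
        # the component sum telescopes to Lambda - mu*N with every transfer
        # term cancelling identically, not just numerically
        total = sp.simplify(
            sum(vector_field_exprs())
            - (_P["Lambda"] - _P["mu"] * sum(_STATE_SYMS))
        )
        assert total == 0


@st.composite
def states_and_params(draw):
    state = draw(
        st.lists(st.floats(0.0, 1e6, allow_nan=False), min_size=7, max_size=7)
    )
    scale = draw(st.floats(0.1, 10.0))
    base = reference_parameters(alpha=draw(st.floats(0, 1e-3)), beta=draw(st.floats(0, 3.0)))
    return np.array(state), base.replace(mu=base.mu * scale)


class TestInvariants:
    @given(sp_=states_and_params())
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_conservation_identity(self, sp_):
        state, params = sp_
        d = rhs(ModelId.FULL, state, params)
        N = state.sum()
        expected = params.Lambda - params.mu * N
        scale = max(1.0, abs(expected), params.mu * N)
        assert abs(d.sum() - expected) <= 1e-9 * scale

    @given(sp_=states_and_params(), zeroed=st.integers(0, 6))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_nonnegative_orthant_invariance(self, sp_, zeroed):
        # a compartment sitting at zero can only be pushed inward
        state, params = sp_
        state = state.copy()
        state[zeroed] = 0.0
        d = rhs(ModelId.FULL, state, params)
        assert d[zeroed] >= -1e-12


class TestStateCoercion:
    def test_mapping_and_shape_checks(self):
        y = as_state({"S": 1.0, "R": 2.0})
        assert y[0] == 1.0 and y[2] == 2.0 and y.sum() == 3.0
        with pytest.raises(ValueError):
            as_state([1.0, 2.0])
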