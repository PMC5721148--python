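"""Precision operators, safe logarithm, model validation and model-file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epiforage import (
    CategoricalTable,
    GenerativeModel,
    InitialBelief,
    PolicySpace,
    PrecisionSet,
    PreferenceVector,
    TransitionTable,
    apply_sensory_precision,
    apply_transition_precision,
    load_model,
    precision_softmax,
    safe_log,
    save_model,
    validate_model,
)
from epiforage.model import LOG_FLOOR
from epiforage.scene import SceneConfig, build_scene_model, diagonally_dominant


def positive_column(n):
    return st.lists(
        st.floats(min_value=1e-3, max_value=1.0), min_size=n, max_size=n
    ).map(lambda xs: np.array(xs) / np.sum(xs))


class TestPrecisionSoftmax:
    @pytest.mark.parametrize(
        "col,zeta,expected",
        [
            ([0.9, 0.1], 1.0, [0.9, 0.1]),  # precision 1 is the identity map
            ([0.9, 0.1], 0.0, [0.5, 0.5]),  # zero inverse temperature -> uniform
            ([0.9, 0.1], 2.0, [0.81 / 0.82, 0.01 / 0.82]),  # hand evaluation
        ],
    )
    def test_reference_columns(self, col, zeta, expected):
        np.testing.assert_allclose(
            precision_softmax(np.array(col), zeta), expected, atol=1e-10
        )

    def test_infinite_precision_is_argmax_onehot(self):
        np.testing.assert_allclose(
            precision_softmax(np.array([0.8, 0.1, 0.1]), np.inf), [1, 0, 0]
        )

    def test_infinite_precision_ties_are_uniform_over_argmax(self):
        np.testing.assert_allclose(
            precision_softmax(np.array([0.4, 0.4, 0.2]), np.inf), [0.5, 0.5, 0.0]
        )

    def test_negative_precision_rejected(self):
        with pytest.raises(ValueError):
            precision_softmax(np.array([0.5, 0.5]), -1.0)

    @settings(max_examples=200, deadline=None)
    @given(col=positive_column(4), prec=st.floats(min_value=0.01, max_value=50))
    def test_normalization_and_order_preserved(self, col, prec):
        out = precision_softmax(col, prec)
        assert abs(out.sum() - 1.0) < 1e-10
        assert np.all(out >= 0)
        # ranking within the column is preserved (weakly: extreme precisions
        # may underflow distinct small entries to tied zeros)
        for i in range(len(col)):
            for j in range(len(col)):
                if col[i] < col[j]:
                    assert out[i] <= out[j]

    @settings(max_examples=100, deadline=None)
    @given(
        col=st.lists(st.floats(min_value=0.05, max_value=1.0), min_size=3, max_size=3).map(
            lambda xs: np.array(xs) / np.sum(xs)
        ),
        z1=st.floats(0.25, 3),
        z2=st.floats(0.25, 3),
    )
    def test_composition_multiplies_precisions(self, col, z1, z2):
        # holds while intermediate entries stay above the log floor
        once = precision_softmax(precision_softmax(col, z1), z2)
        combined = precision_softmax(col, z1 * z2)
        np.testing.assert_allclose(once, combined, atol=1e-9)


class TestSafeLog:
    def test_reference_values(self):
        assert safe_log(1.0) == 0.0
        assert abs(safe_log(np.exp(-1.0)) + 1.0) < 1e-12
        assert abs(safe_log(0.0) + 16.0) < 1e-12  # ln of the default floor

    def test_exact_above_floor_and_monotone(self):
        xs = np.array([LOG_FLOOR, 1e-4, 0.3, 1.0])
        out = safe_log(xs)
        np.testing.assert_allclose(out[1:], np.log(xs[1:]))
        assert np.all(np.diff(out) >= 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            safe_log(np.array([-0.1, 0.5]))


class TestSensoryPrecisionOperator:
    def scene(self):
        return build_scene_model(SceneConfig())

    def test_identity_at_unit_precision(self):
        m = build_scene_model(SceneConfig(zeta_by_location=[1.0] * 5))
        out = apply_sensory_precision(m.A, m.precision)
        np.testing.assert_allclose(out.values[0], m.A.values[0], atol=1e-10)

    def test_input_table_unmodified(self):
        m = self.scene()
        before = m.A.values[0].copy()
        apply_sensory_precision(m.A, m.precision)
        np.testing.assert_array_equal(m.A.values[0], before)

    def test_columns_renormalized(self):
        m = self.scene()
        out = apply_sensory_precision(m.A, m.precision)
        np.testing.assert_allclose(out.values[0].sum(axis=0), 1.0, atol=1e-10)

    def test_nonpositive_zeta_rejected(self):
        m = self.scene()
        bad = PrecisionSet(zeta=np.array([1, -2, 1, 1, 1.0]), zeta_factor=4, zeta_modalities=(0,))
        with pytest.raises(ValueError):
            apply_sensory_precision(m.A, bad)


class TestTransitionPrecisionOperator:
    def test_unit_omega_returns_base_unchanged(self):
        B = TransitionTable([diagonally_dominant(3, 0.8)[:, :, None]])
        out = apply_transition_precision(B, PrecisionSet(omega=np.array([1.0])))
        np.testing.assert_array_equal(out.values[0], B.values[0])

    def test_zero_volatility_limit_is_identity_matrix(self):
        # infinite transition precision on a diagonally dominant base
        B = TransitionTable([diagonally_dominant(3, 0.8)[:, :, None]])
        out = apply_transition_precision(B, PrecisionSet(omega=np.array([np.inf])))
        np.testing.assert_allclose(out.values[0][:, :, 0], np.eye(3))

    def test_zero_precision_limit_is_uniform(self):
        B = TransitionTable([diagonally_dominant(3, 0.8)[:, :, None]])
        out = apply_transition_precision(B, PrecisionSet(omega=np.array([1e-12])))
        np.testing.assert_allclose(out.values[0][:, :, 0], np.full((3, 3), 1 / 3), atol=1e-9)

    def test_zero_entries_in_modulated_base_rejected(self):
        B = TransitionTable([np.eye(2)[:, :, None]])
        with pytest.raises(ValueError, match="degenerate"):
            apply_transition_precision(B, PrecisionSet(omega=np.array([2.0])))

    @settings(max_examples=100, deadline=None)
    @given(col=positive_column(3), w=st.floats(0.05, 20))
    def test_normalization_closure(self, col, w):
        B = TransitionTable([np.repeat(col[:, None], 3, axis=1)[:, :, None]])
        out = apply_transition_precision(B, PrecisionSet(omega=np.array([w])))
        np.testing.assert_allclose(out.values[0].sum(axis=0), 1.0, atol=1e-10)


class TestValidateModel:
    def test_wellformed_scene_passes(self):
        report = validate_model(build_scene_model(SceneConfig()))
        assert report.ok and report.violations == []

    def test_unnormalized_likelihood_column_named(self):
        m = build_scene_model(SceneConfig())
        m.A.values[0][(0,) + (0,) * 4 + (1,)] -= 0.1
        report = validate_model(m)
        assert not report.ok
        assert any("A[what]" in v for v in report.violations)

    def test_zero_entry_omega_factor_flagged(self):
        A = CategoricalTable([np.array([[0.9, 0.2], [0.1, 0.8]])])
        B = TransitionTable([np.eye(2)[:, :, None]])
        m = GenerativeModel(
            A=A, B=B, C=PreferenceVector.uniform([2]), D=InitialBelief([np.array([0.5, 0.5])]),
            precision=PrecisionSet(omega=np.array([2.0])),
            policies=PolicySpace.single_step(1),
        )
        report = validate_model(m)
        assert not report.ok
        assert any("omega" in v for v in report.violations)

    def test_dimension_mismatch_reported(self):
        A = CategoricalTable([np.array([[0.9, 0.2], [0.1, 0.8]])])
        B = TransitionTable([np.eye(3)[:, :, None]])
        m = GenerativeModel(
            A=A, B=B, C=PreferenceVector.uniform([2]), D=InitialBelief([np.array([0.5, 0.5])]),
        )
        assert not validate_model(m).ok


class TestModelFileRoundTrip:
    def test_scene_model_roundtrip_lossless(self, tmp_path):
        m = build_scene_model(SceneConfig(omega_by_stimulus=[0.5, 4.0, np.inf, 1.0]))
        path = tmp_path / "scene.yaml"
        save_model(m, path)
        m2 = load_model(path)
        for a, b in zip(m.A.values, m2.A.values):
            np.testing.assert_allclose(a, b, atol=1e-12)
        for a, b in zip(m.B.values, m2.B.values):
            np.testing.assert_allclose(a, b, atol=1e-12)
        np.testing.assert_array_equal(m.precision.omega, m2.precision.omega)
        np.testing.assert_allclose(m.precision.zeta, m2.precision.zeta, atol=1e-12)
        assert m2.gamma_prior == m.gamma_prior

    def test_named_transition_constructors(self, tmp_path):
        m = build_scene_model(SceneConfig())
        from epiforage import model_to_dict, model_from_dict

        d = model_to_dict(m)
        d["B"] = ["diagonally_dominant(0.6)"] * 4 + [d["B"][4]]
        m2 = model_from_dict(d)
        np.testing.assert_allclose(
            m2.B.values[0][:, :, 0], diagonally_dominant(3, 0.6), atol=1e-12
        )
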