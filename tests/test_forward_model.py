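"""Watson integrals, ODI mapping, and the three-compartment signal."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

from noddisim.forward_model import (
    SignalModel,
    TissueParams,
    kappa_from_odi,
    odi_from_kappa,
    synthesize_signal,
    watson_normalization,
    watson_tau1,
)
from noddisim.schemes import AcquisitionScheme, Measurement, build_protocol
from noddisim.validation import oracle_sweep, quadrature_signal_oracle

#: small three-shell scheme for the randomized property tests
_PROP_SCHEME = build_protocol("p123", seed=3)


class TestWatsonNormalization:
    def test_uniform_limit(self):
        assert watson_normalization(0.0) == 1.0

    @pytest.mark.parametrize("kappa", [0.25, 1.0, 4.0, 16.0, 64.0])
    def test_matches_adaptive_quadrature(self, kappa):
        # Z(kappa) = Int_0^1 exp(kappa t^2) dt
        expected, _ = quad(lambda t: np.exp(kappa * t * t), 0.0, 1.0)
        assert watson_normalization(kappa) == pytest.approx(expected, abs=1e-10 * expected)

    @pytest.mark.parametrize("kappa", [0.25, 1.0, 4.0, 16.0])
    def test_density_integrates_to_one(self, kappa):
        # spherical integral of exp(kappa t^2)/(4 pi Z) over S^2
        z = watson_normalization(kappa)
        val, _ = quad(lambda t: np.exp(kappa * t * t) / (2.0 * z), -1.0, 1.0)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_negative_kappa(self):
        with pytest.raises(ValueError):
            watson_normalization(-0.1)


class TestWatsonTau1:
    def test_uniform_second_moment(self):
        assert watson_tau1(0.0) == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_delta_limit(self):
        assert watson_tau1(1e6) >= 0.999

    @pytest.mark.parametrize("kappa", [0.25, 1.0, 4.0, 16.0])
    def test_matches_1d_quadrature(self, kappa):
        num, _ = quad(lambda t: t * t * np.exp(kappa * t * t), 0, 1)
        den, _ = quad(lambda t: np.exp(kappa * t * t), 0, 1)
        assert watson_tau1(kappa) == pytest.approx(num / den, abs=1e-8)

    def test_strictly_increasing(self):
        ks = [0.0, 0.1, 0.5, 1.0, 4.0, 16.0, 64.0, 256.0]
        vals = [watson_tau1(k) for k in ks]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_negative_kappa(self):
        with pytest.raises(ValueError):
            watson_tau1(-1.0)


class TestOdiMapping:
    def test_reference_points(self):
        assert odi_from_kappa(1.0) == pytest.approx(0.5, abs=1e-14)
        assert odi_from_kappa(0.0) == 1.0

    def test_kappa_16(self):
        import sympy

        expected = float(2 / sympy.pi * sympy.atan(sympy.Rational(1, 16)))
        assert odi_from_kappa(16.0) == pytest.approx(expected, abs=1e-14)

    def test_strictly_decreasing_and_invertible(self):
        ks = [0.0, 0.25, 1.0, 4.0, 16.0, 64.0]
        vals = [odi_from_kappa(k) for k in ks]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        for k in ks[1:]:
            assert kappa_from_odi(odi_from_kappa(k)) == pytest.approx(k, rel=1e-10)

    def test_negative_kappa(self):
        with pytest.raises(ValueError):
            odi_from_kappa(-0.5)


def _single(b, g):
    return AcquisitionScheme("one", (Measurement(b, tuple(g), 0),))


class TestSynthesizeSignal:
    def test_b0_is_one(self, p12345, fiber):
        tissue = TissueParams(0.5, 4.0, 0.2, tuple(fiber))
        sig = synthesize_signal(tissue, p12345)
        np.testing.assert_array_equal(sig.values[p12345.bvals == 0], 1.0)

    def test_pure_free_water_closed_form(self):
        tissue = TissueParams(0.5, 4.0, 1.0)
        sig = synthesize_signal(tissue, _single(3375.0, (1.0, 0, 0)))
        assert sig.values[0] == pytest.approx(np.exp(-10.125), rel=1e-12)

    def test_perpendicular_stick_limit(self):
        # delta dispersion, g perpendicular to mu: no attenuation
        tissue = TissueParams(1.0, 1e8, 0.0, (0, 0, 1.0))
        sig = synthesize_signal(tissue, _single(6000.0, (1.0, 0, 0)))
        assert sig.values[0] == pytest.approx(1.0, abs=1e-4)

    def test_parallel_stick_limit(self):
        tissue = TissueParams(1.0, 1e8, 0.0, (0, 0, 1.0))
        sig = synthesize_signal(tissue, _single(1500.0, (0, 0, 1.0)))
        assert sig.values[0] == pytest.approx(np.exp(-1500 * 1.7e-3), abs=1e-4)

    def test_matches_quadrature_oracle(self, rng):
        g = rng.standard_normal(3)
        g /= np.linalg.norm(g)
        mu = rng.standard_normal(3)
        mu /= np.linalg.norm(mu)
        tissue = TissueParams(0.5, 4.0, 0.0, tuple(mu))
        m = Measurement(1500.0, tuple(g), 0)
        fast = synthesize_signal(tissue, AcquisitionScheme("one", (m,))).values[0]
        assert fast == pytest.approx(quadrature_signal_oracle(tissue, m), abs=1e-6)

    def test_oracle_equivalence_sweep(self):
        # random tissue/measurement cases vs dense spherical quadrature
        reports = oracle_sweep(n_cases=25, seed=7, tolerance=1e-6)
        assert all(r.passed for r in reports), [
            (r.case_id, r.abs_error) for r in reports if not r.passed
        ]


class TestModelProperties:
    def test_rotation_invariance(self, p12345, rng):
        tissue = TissueParams(0.6, 2.0, 0.1, (0, 0, 1.0))
        base = synthesize_signal(tissue, p12345).values
        rot = Rotation.random(random_state=3).as_matrix()
        rotated_scheme = AcquisitionScheme(
            "rot",
            tuple(
                Measurement(m.b, tuple(rot @ np.asarray(m.g)) if m.b > 0 else m.g, m.shell_id)
                for m in p12345.measurements
            ),
        )
        rotated_tissue = TissueParams(0.6, 2.0, 0.1, tuple(rot @ np.array([0, 0, 1.0])))
        np.testing.assert_allclose(
            synthesize_signal(rotated_tissue, rotated_scheme).values, base, atol=1e-10
        )

    def test_monotone_in_b(self, fiber):
        g = np.array([0.6, 0.64, 0.48])
        g /= np.linalg.norm(g)
        tissue = TissueParams(0.7, 4.0, 0.1, tuple(fiber))
        bs = [0.0, 375.0, 1500.0, 3375.0, 6000.0, 9375.0]
        vals = [
            synthesize_signal(tissue, _single(b, g) if b > 0 else
                              AcquisitionScheme("b0", (Measurement(0.0, (0, 0, 0), 0),))).values[0]
            for b in bs
        ]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_convex_combination_bounds(self, fiber, rng):
        g = rng.standard_normal(3)
        g /= np.linalg.norm(g)
        b = 3375.0
        f_ic, kappa, f_iso = 0.55, 2.5, 0.2
        full = synthesize_signal(
            TissueParams(f_ic, kappa, f_iso, tuple(fiber)), _single(b, g)
        ).values[0]
        e_ic = synthesize_signal(
            TissueParams(1.0, kappa, 0.0, tuple(fiber)), _single(b, g)
        ).values[0]
        e_ec = synthesize_signal(
            TissueParams(f_ic, kappa, 0.0, tuple(fiber)), _single(b, g)
        ).values[0]
        e_ec = (e_ec - f_ic * e_ic) / (1 - f_ic)  # isolate hindered part
        e_iso = np.exp(-b * 3.0e-3)
        comps = [e_ic, e_ec, e_iso]
        assert min(comps) - 1e-12 <= full <= max(comps) + 1e-12

    def test_kappa_zero_direction_free(self, p12345):
        a = synthesize_signal(TissueParams(0.5, 0.0, 0.0, (0, 0, 1.0)), p12345).values
        mu2 = np.array([1.0, 1.0, 1.0]) / np.sqrt(3)
        b = synthesize_signal(TissueParams(0.5, 0.0, 0.0, tuple(mu2)), p12345).values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_signal_in_unit_interval(self, p12345, rng):
        for _ in range(5):
            mu = rng.standard_normal(3)
            mu /= np.linalg.norm(mu)
            t = TissueParams(
                float(rng.uniform(0, 1)),
                float(rng.uniform(0, 64)),
                float(rng.uniform(0, 1)),
                tuple(mu),
            )
            v = synthesize_signal(t, p12345).values
            assert np.all(v > 0) and np.all(v <= 1.0 + 1e-12)


class TestSignalModel:
    def test_identical_to_reference_path(self, p12345, rng):
        model = SignalModel(p12345)
        for _ in range(10):
            mu = rng.standard_normal(3)
            mu /= np.linalg.norm(mu)
            f_ic = float(rng.uniform(0, 1))
            kappa = float(rng.uniform(0, 64))
            f_iso = float(rng.uniform(0, 1))
            t = TissueParams(f_ic, kappa, f_iso, tuple(mu))
            np.testing.assert_allclose(
                model.evaluate(f_ic, kappa, f_iso, mu),
                synthesize_signal(t, p12345).values,
                rtol=0, atol=1e-13,  # same expansion, different op order
            )

    def test_grid_batch_matches_single(self, p14, rng):
        model = SignalModel(p14)
        mu = rng.standard_normal(3)
        mu /= np.linalg.norm(mu)
        f_ics = np.array([0.2, 0.8])
        f_isos = np.array([0.0, 0.4])
        grid = model.evaluate_grid(f_ics, 4.0, f_isos, mu)
        for i, fic in enumerate(f_ics):
            for j, fiso in enumerate(f_isos):
                np.testing.assert_allclose(
                    grid[i, j], model.evaluate(float(fic), 4.0, float(fiso), mu),
                    atol=1e-14,
                )


class TestPropertyInvariants:
    """Randomized invariants of the Watson maps and the signal."""

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(kappa=st.floats(min_value=1e-6, max_value=64.0))
    def test_watson_maps_consistent(self, kappa):
        tau = watson_tau1(kappa)
        assert 1.0 / 3.0 - 1e-12 <= tau < 1.0
        assert kappa_from_odi(odi_from_kappa(kappa)) == pytest.approx(
            kappa, rel=1e-9
        )
        assert watson_normalization(kappa) >= 1.0  # e^{kappa t^2} >= 1

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        f_ic=st.floats(0.0, 1.0),
        kappa=st.floats(0.0, 64.0),
        f_iso=st.floats(0.0, 1.0),
        seed=st.integers(0, 2**16),
    )
    def test_signal_bounded_and_unity_at_b0(self, f_ic, kappa, f_iso, seed):
        scheme = _PROP_SCHEME
        rng = np.random.default_rng(seed)
        mu = rng.standard_normal(3)
        mu /= np.linalg.norm(mu)
        sig = synthesize_signal(
            TissueParams(f_ic, kappa, f_iso, tuple(mu)), scheme
        )
        assert np.all(sig.values > 0.0)
        assert np.all(sig.values <= 1.0 + 1e-12)
        assert sig.values[scheme.bvals == 0][0] == 1.0


class TestTissueParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(f_ic=-0.1, kappa=1.0, f_iso=0.0),
            dict(f_ic=0.5, kappa=-1.0, f_iso=0.0),
            dict(f_ic=0.5, kappa=1.0, f_iso=1.2),
            dict(f_ic=0.5, kappa=1.0, f_iso=0.0, mu=(0, 0, 2.0)),
        ],
    )
    def test_invalid_params(self, kwargs):
        with pytest.raises(ValueError):
            TissueParams(**kwargs)

    def test_defaults(self):
        t = TissueParams(0.5, 1.0, 0.0)
        assert t.d_par == 1.7e-3 and t.d_iso == 3.0e-3
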