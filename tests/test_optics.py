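"""Keratometry -> power vector -> power matrix -> thick-lens power."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from keravec import (
    Keratometry,
    PowerMatrix,
    PowerVector,
    RefractiveIndices,
    equivalent_radius,
    gullstrand_total_power,
    keratometric_power,
    matrix_to_power_vector,
    mean_radius,
    power_vector_to_matrix,
    surface_power_vector,
    total_power_vector,
)

IDX = RefractiveIndices()

finite = st.floats(-80.0, 80.0, allow_nan=False, allow_infinity=False)
pv_strategy = st.builds(PowerVector, veq=finite, v0=finite, v45=finite)


def scalar_gullstrand(pa, pp, cct_mm, nc=1.376):
    """Independent scalar thick-lens oracle."""
    return pa + pp - pp * pa * cct_mm * 1e-3 / nc


class TestKeratometry:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [(7.81, 7.65, 7.73), (8.0, 8.0, 8.0), (7.8186, 7.6784, 7.7485)],
    )
    def test_mean_radius(self, r1, r2, expected):
        assert mean_radius(Keratometry(r1, r2)) == pytest.approx(expected, abs=1e-4)

    @pytest.mark.parametrize(
        "r1, r2, expected",
        [(7.5, 7.5, 45.0), (6.75, 6.75, 50.0), (7.8186, 7.6784, 43.561)],
    )
    def test_keratometric_power(self, r1, r2, expected):
        assert keratometric_power(Keratometry(r1, r2), IDX) == pytest.approx(
            expected, abs=1e-3
        )

    def test_axis_normalised_modulo_180(self):
        assert Keratometry(7.8, 7.6, 271.0).axis == pytest.approx(91.0)

    @pytest.mark.parametrize("r1, r2", [(0.0, 7.5), (7.5, -1.0)])
    def test_non_positive_radius_rejected(self, r1, r2):
        with pytest.raises(ValueError):
            Keratometry(r1, r2)


class TestSurfacePowerVector:
    def test_spherical_front_surface(self):
        pv = surface_power_vector(Keratometry(7.52, 7.52, 0.0), 1.0, 1.376)
        assert pv.veq == pytest.approx(50.0, abs=1e-10)
        assert pv.v0 == 0.0 and pv.v45 == 0.0

    def test_spherical_back_surface(self):
        pv = surface_power_vector(Keratometry(6.9085, 6.9085), 1.376, 1.336)
        assert pv.veq == pytest.approx(-5.790, abs=1e-3)

    def test_toric_front_surface_at_axis_90(self):
        pv = surface_power_vector(Keratometry(7.9, 7.7, 90.0), 1.0, 1.376)
        assert pv.v0 == pytest.approx(-1.236, abs=1e-3)
        assert pv.v45 == pytest.approx(0.0, abs=1e-9)

    @given(
        r1=st.floats(6.5, 9.5),
        dr=st.floats(0.0, 0.6),
        axis=st.floats(0.0, 179.99),
    )
    @settings(max_examples=60, derandomize=True)
    def test_axis_plus_180_invariance(self, r1, dr, axis):
        a = surface_power_vector(Keratometry(r1 + dr, r1, axis), 1.0, 1.376)
        b = surface_power_vector(Keratometry(r1 + dr, r1, axis + 180.0), 1.0, 1.376)
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-9)

    @given(
        r1=st.floats(6.5, 9.5),
        dr=st.floats(0.0, 0.6),
        axis=st.floats(0.0, 179.99),
    )
    @settings(max_examples=60, derandomize=True)
    def test_meridian_swap_equals_axis_rotation_by_90(self, r1, dr, axis):
        """Rotating the flat axis by 90 deg negates (v0, v45), keeps veq."""
        a = surface_power_vector(Keratometry(r1 + dr, r1, axis), 1.0, 1.376)
        b = surface_power_vector(Keratometry(r1 + dr, r1, axis + 90.0), 1.0, 1.376)
        assert b.veq == pytest.approx(a.veq, abs=1e-9)
        assert b.v0 == pytest.approx(-a.v0, abs=1e-9)
        assert b.v45 == pytest.approx(-a.v45, abs=1e-9)


class TestPowerMatrix:
    @pytest.mark.parametrize(
        "pv, matrix",
        [
            ((44, 1, 0), [[45, 0], [0, 43]]),
            ((10, 0, 2), [[10, 2], [2, 10]]),
            ((0, 0, 0), [[0, 0], [0, 0]]),
        ],
    )
    def test_construction(self, pv, matrix):
        m = power_vector_to_matrix(PowerVector(*pv))
        np.testing.assert_allclose(m.as_array(), matrix)

    def test_asymmetric_extraction_averages_off_diagonal(self):
        pv = matrix_to_power_vector(PowerMatrix(10, 3, 1, 10))
        assert (pv.veq, pv.v0, pv.v45) == (10, 0, 2)

    @given(pv=pv_strategy)
    @settings(max_examples=80, derandomize=True)
    def test_round_trip_identity(self, pv):
        back = matrix_to_power_vector(power_vector_to_matrix(pv))
        np.testing.assert_allclose(back.as_array(), pv.as_array(), atol=1e-12)

    @given(pv=pv_strategy)
    @settings(max_examples=80, derandomize=True)
    def test_eigenvalues_are_principal_powers(self, pv):
        evals = np.linalg.eigvalsh(power_vector_to_matrix(pv).as_array())
        cyl = np.hypot(pv.v0, pv.v45)
        np.testing.assert_allclose(
            np.sort(evals), [pv.veq - cyl, pv.veq + cyl], atol=1e-9
        )


class TestGullstrand:
    def test_zero_thickness_is_thin_lens_sum(self):
        pa = power_vector_to_matrix(PowerVector(48.0, 1.5, -0.3))
        pp = power_vector_to_matrix(PowerVector(-5.9, -0.2, 0.1))
        total = gullstrand_total_power(pa, pp, 0.0, IDX)
        np.testing.assert_array_equal(total.as_array(), pa.as_array() + pp.as_array())

    def test_spherical_case_matches_scalar_oracle(self):
        pa = power_vector_to_matrix(PowerVector(48.69, 0.0, 0.0))
        pp = power_vector_to_matrix(PowerVector(-5.80, 0.0, 0.0))
        total = gullstrand_total_power(pa, pp, 0.5544, IDX)
        expected = scalar_gullstrand(48.69, -5.80, 0.5544)
        assert expected == pytest.approx(43.0038, abs=1e-4)
        np.testing.assert_allclose(total.as_array(), expected * np.eye(2), atol=1e-9)

    def test_aligned_toric_surfaces_match_per_meridian_oracle(self):
        front = Keratometry(7.9, 7.6, 30.0)
        back = Keratometry(6.9, 6.6, 30.0)
        cct = 0.55
        pv = total_power_vector(front, back, cct, IDX)
        total_evals = np.sort(
            np.linalg.eigvalsh(power_vector_to_matrix(pv).as_array())
        )
        pa = surface_power_vector(front, 1.0, IDX.n_cornea)
        pp = surface_power_vector(back, IDX.n_cornea, IDX.n_aqueous)
        # principal powers of each surface along the shared axes
        ca, cp = np.hypot(pa.v0, pa.v45), -np.hypot(pp.v0, pp.v45)
        merid = sorted(
            scalar_gullstrand(pa.veq + sa * ca, pp.veq + sa * cp, cct)
            for sa in (-1.0, 1.0)
        )
        np.testing.assert_allclose(total_evals, merid, atol=1e-9)

    def test_crossed_axes_match_longhand_rotation_oracle(self):
        """Brute-force each surface matrix via rotation conjugation and
        multiply 2x2 matrices explicitly."""
        front = Keratometry(7.9, 7.6, 20.0)
        back = Keratometry(6.9, 6.6, 110.0 + 37.0)  # deliberately crossed
        cct = 0.6

        def surface_matrix(k, n_before, n_after):
            dn = n_after - n_before
            p1, p2 = dn * 1e3 / k.r1, dn * 1e3 / k.r2
            veq, cyl = 0.5 * (p1 + p2), p2 - p1
            th = np.deg2rad(float(k.axis))
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            return rot @ np.diag([veq + cyl, veq - cyl]) @ rot.T

        pa = surface_matrix(front, 1.0, IDX.n_cornea)
        pp = surface_matrix(back, IDX.n_cornea, IDX.n_aqueous)
        oracle = pa + pp - pp @ pa * (cct * 1e-3 / IDX.n_cornea)
        expected = np.array(
            [
                0.5 * (oracle[0, 0] + oracle[1, 1]),
                0.5 * (oracle[0, 0] - oracle[1, 1]),
                0.5 * (oracle[0, 1] + oracle[1, 0]),
            ]
        )
        pv = total_power_vector(front, back, cct, IDX)
        np.testing.assert_allclose(pv.as_array(), expected, atol=1e-9)

    def test_negative_thickness_rejected(self):
        pa = power_vector_to_matrix(PowerVector(48.0, 0, 0))
        with pytest.raises(ValueError):
            gullstrand_total_power(pa, pa, -0.1, IDX)


class TestTotalPowerVector:
    def test_spherical_thin_cornea_sums_surface_powers(self):
        pv = total_power_vector(
            Keratometry(7.52, 7.52), Keratometry(6.9085, 6.9085), 0.0, IDX
        )
        assert pv.veq == pytest.approx(50.0 - 5.790, abs=1e-3)
        assert pv.v0 == 0.0 and pv.v45 == 0.0

    def test_spherical_surfaces_have_no_astigmatism(self):
        pv = total_power_vector(
            Keratometry(7.8, 7.8, 40.0), Keratometry(6.5, 6.5, 120.0), 0.55, IDX
        )
        assert pv.v0 == pytest.approx(0.0, abs=1e-12)
        assert pv.v45 == pytest.approx(0.0, abs=1e-12)


class TestEquivalentRadius:
    @pytest.mark.parametrize(
        "veq, dn, expected", [(50.0, 0.376, 7.52), (45.0, 0.3375, 7.5)]
    )
    def test_known_values(self, veq, dn, expected):
        r = equivalent_radius(PowerVector(veq, 0, 0), dn)
        assert r == pytest.approx(expected, abs=1e-6)

    @given(r=st.floats(6.0, 10.0))
    @settings(max_examples=40, derandomize=True)
    def test_round_trip_with_surface_power(self, r):
        pv = surface_power_vector(Keratometry(r, r), 1.0, 1.376)
        assert equivalent_radius(pv, 0.376) == pytest.approx(r, rel=1e-12)

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            equivalent_radius(PowerVector(0.0, 1.0, 0.0), 0.376)
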