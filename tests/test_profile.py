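"""Scattering math: P(r), Debye intensity, Rg, resampling, differentiability."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from saxsfold import (
    AtomicStructure,
    FixtureSpec,
    ScatteringGeometry,
    compute_pr,
    compute_pr_soft,
    debye_intensity,
    make_chain,
    pr_to_intensity,
    q_from_angle,
    resample_pr,
    rg_from_coords,
    rg_from_pr,
    soft_pr_vjp,
)
from saxsfold.errors import (
    DegenerateInputError,
    InvalidGeometryError,
    InvalidParameterError,
    MissingScaleError,
)
from oracles import brute_force_debye, brute_force_pr, brute_force_rg, reference_interp


class TestQFromAngle:
    @pytest.mark.parametrize("lam,theta_deg,expected", [
        (1.0, 0.0, 0.0),
        (1.0, 30.0, 2 * math.pi),
        (1.54, 5.0, 4 * math.pi / 1.54 * math.sin(math.radians(5.0))),
    ])
    def test_formula(self, lam, theta_deg, expected):
        q = q_from_angle(ScatteringGeometry(lam, math.radians(theta_deg)))
        assert q == pytest.approx(expected, rel=1e-12)

    def test_invalid_wavelength(self):
        with pytest.raises(InvalidGeometryError):
            ScatteringGeometry(0.0, 0.1)

    def test_invalid_angle(self):
        with pytest.raises(InvalidGeometryError):
            ScatteringGeometry(1.0, math.pi)


class TestComputePr:
    def test_single_pair(self, two_atom):
        pr = compute_pr(two_atom, dr=0.5, normalize=True)
        assert pr.area == pytest.approx(1.0, abs=1e-12)
        assert abs(pr.dmax - 10.0) <= 1e-12
        k = int(np.argmax(pr.p))
        assert abs(pr.r[k] - 10.0) <= 0.5  # mass sits in the bin holding r=10
        assert pr.p[pr.p > 0].size == 1

    def test_equilateral_triangle(self):
        side = 8.0
        coords = side * np.array([
            [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.5, math.sqrt(3) / 2, 0.0],
        ])
        st_ = AtomicStructure.from_ca(coords, z=1)
        # dr chosen so the side length is interior to a bin, not on a boundary
        pr = compute_pr(st_, dr=0.6)
        assert (pr.p > 0).sum() == 1
        assert pr.dmax == pytest.approx(8.0)

    def test_matches_brute_force(self, globule30):
        pr = compute_pr(globule30, dr=0.5)
        centers, hist = brute_force_pr(globule30.coords, globule30.z, 0.5)
        assert len(pr.p) == len(hist)
        np.testing.assert_allclose(pr.p, hist, rtol=1e-9)
        np.testing.assert_allclose(pr.r, centers)
        assert pr.self_term == pytest.approx(float((globule30.z ** 2).sum()))

    def test_rigid_invariance_and_reorder(self, globule30):
        pr = compute_pr(globule30, dr=0.5)
        rot = Rotation.random(random_state=7).as_matrix()
        moved = globule30.transformed(rot, np.array([5.0, -3.0, 1.0]))
        pr2 = compute_pr(moved, dr=0.5)
        np.testing.assert_allclose(pr2.p, pr.p, atol=1e-9)
        # atom reordering: bit-identical histogram
        perm = np.random.default_rng(0).permutation(globule30.n_atoms)
        reordered = AtomicStructure.from_ca(globule30.coords[perm])
        pr3 = compute_pr(reordered, dr=0.5)
        assert (pr3.p == compute_pr(
            AtomicStructure.from_ca(globule30.coords), dr=0.5).p).all()

    def test_single_atom_rejected(self):
        lone = AtomicStructure.from_ca(np.zeros((1, 3)))
        with pytest.raises(DegenerateInputError):
            compute_pr(lone)

    def test_bad_dr(self, two_atom):
        with pytest.raises(InvalidParameterError):
            compute_pr(two_atom, dr=0.0)


class TestSoftPr:
    def test_limit_matches_hard(self, globule30):
        hard = compute_pr(globule30, dr=0.5, normalize=True)
        soft = compute_pr_soft(globule30, dr=0.5, bandwidth=5e-4,
                               normalize=True, n_bins=len(hard.r))
        np.testing.assert_allclose(soft.p, hard.p, atol=1e-6)

    def test_rigid_invariance(self, globule30):
        a = compute_pr_soft(globule30, dr=0.5, bandwidth=0.5)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = globule30.transformed(rot, np.array([-2.0, 8.0, 0.5]))
        b = compute_pr_soft(moved, dr=0.5, bandwidth=0.5, n_bins=len(a.r))
        np.testing.assert_allclose(b.p, a.p, atol=1e-9)

    @pytest.mark.parametrize("atom,axis", [(0, 0), (4, 1), (11, 2)])
    def test_gradient_matches_central_difference(self, atom, axis):
        st_ = make_chain(FixtureSpec(kind="globule", n_residues=12, seed=3))
        curve, cache = compute_pr_soft(st_, dr=0.5, bandwidth=0.5, return_cache=True)
        weights = curve.r.copy()  # scalar = sum_k p_k r_k
        analytic = soft_pr_vjp(cache, weights)[atom, axis]
        eps = 1e-5

        def value(delta):
            coords = st_.coords.copy()
            coords[atom, axis] += delta
            c = compute_pr_soft(AtomicStructure.from_ca(coords), dr=0.5,
                                bandwidth=0.5, n_bins=len(curve.r))
            return float((c.p * c.r).sum())

        numeric = (value(eps) - value(-eps)) / (2 * eps)
        assert analytic == pytest.approx(numeric, rel=1e-4)

    def test_bad_bandwidth(self, globule30):
        with pytest.raises(InvalidParameterError):
            compute_pr_soft(globule30, bandwidth=0.0)


class TestDebye:
    def test_two_atom_values(self, two_atom):
        prof = debye_intensity(two_atom, np.array([0.0, 0.1]))
        assert prof.i[0] == pytest.approx(4.0)
        assert prof.i[1] == pytest.approx(2.0 * (1.0 + math.sin(1.0) / 1.0))

    def test_i0_is_total_z_squared(self, globule30, q_grid):
        prof = debye_intensity(globule30, q_grid)
        assert prof.i[0] == pytest.approx(float(globule30.z.sum()) ** 2, rel=1e-12)

    def test_matches_brute_force(self, globule30):
        q = np.linspace(0.0, 0.5, 50)
        prof = debye_intensity(globule30, q)
        oracle = brute_force_debye(globule30.coords, globule30.z, q)
        np.testing.assert_allclose(prof.i, oracle, rtol=1e-9)

    def test_empty_grid(self, globule30):
        with pytest.raises(InvalidParameterError):
            debye_intensity(globule30, np.array([]))


class TestPrToIntensity:
    def test_exact_when_distance_on_bin_center(self):
        # distance 10.25 sits exactly on a bin center for dr=0.5
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 10.25]])
        st_ = AtomicStructure.from_ca(coords, z=1)
        q = np.linspace(0.0, 0.5, 26)
        via_pr = pr_to_intensity(compute_pr(st_, dr=0.5), q)
        direct = debye_intensity(st_, q)
        np.testing.assert_allclose(via_pr.i, direct.i, rtol=1e-9)

    def test_binning_error_small_and_monotone(self, globule30, q_grid):
        direct = debye_intensity(globule30, q_grid)
        errs = []
        for dr in (1.0, 0.5, 0.1):
            via = pr_to_intensity(compute_pr(globule30, dr=dr), q_grid)
            errs.append(float(np.max(np.abs(via.i - direct.i) / direct.i)))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.01

    def test_zero_curve_gives_constant_self_term(self):
        from saxsfold import PrCurve
        pr = PrCurve(r=(np.arange(5) + 0.5) * 0.5, p=np.zeros(5), dr=0.5,
                     dmax=0.0, normalized=False, self_term=42.0)
        prof = pr_to_intensity(pr, np.linspace(0, 0.3, 4))
        np.testing.assert_allclose(prof.i, 42.0)

    def test_normalized_without_scale_refused(self):
        from saxsfold import PrCurve
        pr = PrCurve(r=(np.arange(5) + 0.5) * 0.5, p=np.full(5, 0.4), dr=0.5,
                     dmax=2.25, normalized=True, self_term=1.0, total_weight=None)
        with pytest.raises(MissingScaleError):
            pr_to_intensity(pr, np.array([0.0, 0.1]))


class TestRg:
    def test_two_atoms_give_half_distance(self, two_atom):
        assert rg_from_coords(two_atom) == pytest.approx(5.0)
        pr = compute_pr(two_atom, dr=0.001)
        assert rg_from_pr(pr) == pytest.approx(5.0, abs=2e-3)

    def test_scale_invariance_of_pr_route(self, globule30):
        from dataclasses import replace
        pr = compute_pr(globule30, dr=0.5)
        scaled = replace(pr, p=pr.p * 7.5)
        assert rg_from_pr(scaled) == pytest.approx(rg_from_pr(pr), rel=1e-12)

    def test_rigid_invariance(self, globule30):
        rot = Rotation.random(random_state=11).as_matrix()
        moved = globule30.transformed(rot, np.array([1.0, 2.0, 3.0]))
        assert rg_from_coords(moved) == pytest.approx(rg_from_coords(globule30))

    def test_matches_brute_force(self):
        st_ = make_chain(FixtureSpec(kind="globule", n_residues=10, seed=5))
        assert rg_from_coords(st_, "electron") == pytest.approx(
            brute_force_rg(st_.coords, st_.z), rel=1e-12)
        assert rg_from_coords(st_, "uniform") == pytest.approx(
            brute_force_rg(st_.coords, np.ones(10)), rel=1e-12)

    @pytest.mark.parametrize("dr", [1.0, 0.25, 0.05])
    def test_pr_route_converges_to_coordinate_route(self, globule30, dr):
        rg_ref = rg_from_coords(globule30, "electron")
        assert rg_from_pr(compute_pr(globule30, dr=dr)) == pytest.approx(
            rg_ref, abs=2 * dr)


class TestResample:
    def test_identity_on_same_grid(self, globule30):
        pr = compute_pr(globule30, dr=0.5, normalize=True)
        out = resample_pr(pr, pr.r)
        np.testing.assert_allclose(out.p, pr.p, atol=1e-12)

    def test_unit_area_preserved(self, globule30):
        pr = compute_pr(globule30, dr=0.5, normalize=True)
        fine = (np.arange(200) + 0.5) * 0.25
        out = resample_pr(pr, fine)
        assert out.area == pytest.approx(1.0, abs=1e-6)

    def test_downsample_matches_reference_interpolation(self, globule30):
        pr = compute_pr(globule30, dr=0.5)  # raw curve: no renormalization step
        coarse = (np.arange(len(pr.r) // 2) + 0.5) * 1.0
        out = resample_pr(pr, coarse)
        expected = reference_interp(coarse, pr.r, pr.p)
        np.testing.assert_allclose(out.p, expected, atol=1e-12)

    def test_nonuniform_grid_rejected(self, globule30):
        pr = compute_pr(globule30, dr=0.5)
        with pytest.raises(InvalidParameterError):
            resample_pr(pr, np.array([0.25, 0.75, 2.0]))


@settings(deadline=None, max_examples=25)
@given(seed=st.integers(0, 10_000), n=st.integers(3, 20))
def test_property_pr_nonnegative_unit_area_bounded_support(seed, n):
    """Normalized P(r) of any random chain: unit area, non-negative, support
    bounded by the true maximum distance."""
    chain = make_chain(FixtureSpec(kind="globule", n_residues=n, seed=seed))
    pr = compute_pr(chain, dr=0.5, normalize=True)
    assert (pr.p >= 0).all()
    assert pr.area == pytest.approx(1.0, abs=1e-9)
    top = pr.r[np.max(np.nonzero(pr.p))]
    assert abs(top - pr.dmax) <= 0.5
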