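"""Cost functional: component formulas, contracts, gradient, symmetries."""

import numpy as np
import pytest
from scipy.special import ndtr

from boseg.bo_core import random_init, smooth_bo
from boseg.cost import (CostEngine, ModelParams, ScaleMultipliers, bending_cost,
                        continuity_cost, edge_alignment_cost, edge_responses,
                        multiscale, opposition_cost, saturation_cost, smoothed_ramp,
                        total_cost, total_gradient, vacancy_cost)
from oracles import (naive_edge_response_at, naive_opposition, naive_smoothed_ramp)

P = ModelParams()


def rot90_map(b, k=1):
    """Rotate a BO map by k*90 deg counter-clockwise (display coords):
    spatial rotation plus direction-index shift of k*L/4."""
    L = b.shape[2]
    out = np.rot90(b, k=k, axes=(0, 1))
    return out[..., (np.arange(L) - k * (L // 4)) % L]


class TestEdgeResponses:
    def test_constant_image_gives_zero(self):
        A = edge_responses(np.full((8, 8), 0.4), 1.0, 12)
        assert np.allclose(A, 0.0, atol=1e-14)

    def test_dead_zone_sign_function(self):
        # the filter's sign factor is zero within |x| <= 0.001 of the axis;
        # probe it through a filter whose along-axis coordinate hits zero
        from boseg.cost import _edge_filter
        k = _edge_filter(0, 12, 1.0)
        r = k.shape[0] // 2
        assert np.all(k[:, r] == 0.0)          # on-axis column zeroed
        assert k[r, r + 1] > 0 and k[r, r - 1] < 0

    def test_vertical_step_matches_direct_sum(self):
        img = np.zeros((9, 9))
        img[:, :4] = 1.0
        A = edge_responses(img, 1.0, 12)
        # perpendicular direction is maximal at the edge
        y, x = 4, 4
        assert abs(A[y, x, 0]) == pytest.approx(np.abs(A[y, x]).max())
        for l in (0, 3, 6, 7):
            want = naive_edge_response_at(img, x, y, l, 12, 1.0)
            assert A[y, x, l] == pytest.approx(want, abs=1e-12)

    def test_odd_symmetry_between_opposite_directions(self):
        rng = np.random.default_rng(0)
        A = edge_responses(rng.random((7, 7)), 1.0, 12)
        assert np.allclose(A[..., 0], -A[..., 6], atol=1e-12)


class TestPointwiseComponents:
    def test_zero_maps_cost_nothing(self):
        c = np.zeros((4, 4, 8))
        A = np.ones_like(c)
        assert edge_alignment_cost(c, A) == 0
        assert saturation_cost(c) == 0
        assert vacancy_cost(c, A, 0.01) == 0
        assert opposition_cost(c, 1.0) == 0

    def test_alignment_single_site(self):
        c = np.zeros((2, 2, 4))
        A = np.zeros_like(c)
        c[0, 0, 0], A[0, 0, 0] = 1.0, 2.0
        assert edge_alignment_cost(c, A) == pytest.approx(-4 / 16)

    def test_saturation_single_site_and_homogeneity(self):
        c = np.zeros((2, 2, 4))
        c[1, 1, 2] = 2.0
        assert saturation_cost(c) == pytest.approx(1.0)
        rng = np.random.default_rng(2)
        c = rng.normal(size=(3, 3, 4))
        assert saturation_cost(3.0 * c) == pytest.approx(81.0 * saturation_cost(c))

    def test_vacancy_weights(self):
        c = np.zeros((2, 2, 4))
        c[0, 0, 0] = 1.0
        A = np.zeros_like(c)
        assert vacancy_cost(c, A, 0.01) == pytest.approx(1 / 16)    # no edge: weight 1
        A[0, 0, 0] = np.sqrt(99 * 0.01)                             # A^2 = 99 eps
        assert vacancy_cost(c, A, 0.01) == pytest.approx(0.01 / 16)

    def test_opposition_single_direction_is_free(self):
        c = np.zeros((5, 5, 12))
        c[2, 2, 4] = 1.3
        assert opposition_cost(c, 1.0) == pytest.approx(0.0, abs=1e-15)

    def test_opposition_matches_direct_sum(self):
        c = np.zeros((9, 9, 12))
        c[4, 4, 0] = 1.0
        c[4, 4, 6] = 1.0
        got = opposition_cost(c, 1.0)
        assert got == pytest.approx(naive_opposition(c, 1.0), abs=1e-12)
        rng = np.random.default_rng(3)
        c = rng.random((5, 4, 12))
        assert opposition_cost(c, 0.8) == pytest.approx(naive_opposition(c, 0.8),
                                                        abs=1e-12)


class TestSmoothedRamp:
    def test_far_field_limits(self):
        s = 0.1
        assert smoothed_ramp(10 * s, s) == pytest.approx(10 * s, rel=1e-12)
        assert smoothed_ramp(-10 * s, s) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_zero(self):
        s = 0.37
        assert smoothed_ramp(0.0, s) == pytest.approx(s / np.sqrt(2 * np.pi))

    @pytest.mark.parametrize("x", [-0.5, -0.05, 0.0, 0.02, 0.3])
    def test_matches_convolution_integral(self, x):
        assert smoothed_ramp(x, 0.1) == pytest.approx(
            naive_smoothed_ramp(x, 0.1), abs=1e-10)

    def test_derivative_is_normal_cdf(self):
        s, x, h = 0.2, 0.07, 1e-6
        num = (smoothed_ramp(x + h, s) - smoothed_ramp(x - h, s)) / (2 * h)
        assert num == pytest.approx(ndtr(x / s), rel=1e-6)


def _straight_edge_map(H=15, W=15, L=12, l=0, x=None, y0=0, y1=None, value=1.0):
    """BO along a vertical boundary at column x, ownership direction l."""
    b = np.zeros((H, W, L))
    x = W // 2 if x is None else x
    y1 = H if y1 is None else y1
    b[y0:y1, x, l] = value
    return b


class TestContinuityContracts:
    def test_zero_map_costs_nothing(self):
        assert continuity_cost(np.zeros((8, 8, 12)), P) == pytest.approx(0.0, abs=1e-15)

    def test_dangling_end_costs_more_than_full_edge(self):
        full = smooth_bo(_straight_edge_map(), P.sigma_sa, P.sigma_sx)
        dangling = smooth_bo(_straight_edge_map(y1=8), P.sigma_sa, P.sigma_sx)
        assert continuity_cost(dangling, P) > continuity_cost(full, P)

    def test_occluder_restores_continuity(self):
        # Adding a perpendicular edge through the ending point supplies an
        # origin for the ending edge.  The occluder carries its own cost, so
        # the claim is about the interaction: the combined map costs less
        # than the sum of its parts.
        dangle = _straight_edge_map(y1=8)
        occluder = np.zeros_like(dangle)
        occluder[8, :, 3] = 1.0
        sm = lambda m: smooth_bo(m, P.sigma_sa, P.sigma_sx)
        c_d = continuity_cost(sm(dangle), P)
        c_occ = continuity_cost(sm(occluder), P)
        c_both = continuity_cost(sm(dangle + occluder), P)
        assert c_both < c_d + c_occ
        # and the relief is substantial: most of the dangling excess is gone
        assert (c_d + c_occ) - c_both > 0.4 * c_d

    def test_head_on_junction_of_opposite_ownership_is_discontinuous(self):
        # two collinear edges whose owned sides differ meet head-on: neither
        # is a valid continuation of the other (the owned region would have
        # to jump sides), so both ends count as dangling — the patchwork
        # states this rules out would otherwise beat coherent object rings
        sm = lambda m: smooth_bo(m, P.sigma_sa, P.sigma_sx)
        consistent = _straight_edge_map()                      # one edge through
        mixed = np.zeros((15, 15, 12))
        mixed[0:8, 7, 0] = 1.0    # upper half owned to the right
        mixed[8:15, 7, 6] = 1.0   # lower half owned to the left
        c_mixed = continuity_cost(sm(mixed), P)
        c_cons = continuity_cost(sm(consistent), P)
        dangling = continuity_cost(sm(_straight_edge_map(y1=8)), P)
        assert c_mixed > 2.5 * c_cons
        assert c_mixed > 1.5 * dangling

    def test_unbroken_edge_stays_near_baseline(self):
        # mid-edge sites have origins matching their endings, so an unbroken
        # edge moves the cost off the equality baseline far less than a
        # dangling end does
        full = continuity_cost(smooth_bo(_straight_edge_map(), P.sigma_sa, P.sigma_sx), P)
        dangling = continuity_cost(
            smooth_bo(_straight_edge_map(y1=8), P.sigma_sa, P.sigma_sx), P)
        assert dangling > 1.5 * abs(full)


def _square_ring_map(side=8, H=16, W=16, L=12, inward=True):
    """Closed square boundary with ownership pointing in or out."""
    b = np.zeros((H, W, L))
    o = (H - side) // 2
    hi = o + side - 1
    # direction indices: 0 = +x, 3 = +y (display, y up => row decreasing)
    left, right, up, down = 0, 6, 3, 9
    b[o : hi + 1, o, left if inward else right] = 1.0     # left wall owns rightward
    b[o : hi + 1, hi, right if inward else left] = 1.0
    b[o, o : hi + 1, 9 if inward else 3] = 1.0            # top row: object below
    b[hi, o : hi + 1, 3 if inward else 9] = 1.0
    return b


class TestBendingContracts:
    def test_straight_continuation_is_free(self):
        c = smooth_bo(_straight_edge_map(), P.sigma_sa, P.sigma_sx)
        base = bending_cost(c, P)
        assert base < 0.05 * bending_cost(
            smooth_bo(_square_ring_map(), P.sigma_sa, P.sigma_sx), P)

    def test_convex_bend_cheaper_than_concave(self):
        inward = smooth_bo(_square_ring_map(inward=True), P.sigma_sa, P.sigma_sx)
        outward = smooth_bo(_square_ring_map(inward=False), P.sigma_sa, P.sigma_sx)
        assert bending_cost(inward, P) < bending_cost(outward, P)

    def test_concavity_ratio_tracks_kappa(self):
        inward = smooth_bo(_square_ring_map(inward=True), P.sigma_sa, P.sigma_sx)
        outward = smooth_bo(_square_ring_map(inward=False), P.sigma_sa, P.sigma_sx)
        ratio = bending_cost(outward, P) / bending_cost(inward, P)
        assert 1.2 < ratio  # strictly penalized; exact ratio depends on lobes


class TestMultiscale:
    def test_single_scale_identity(self):
        fn = lambda fac: 3.5 * fac
        assert multiscale(fn, 1, 2.0) == pytest.approx(3.5)

    def test_two_scales_average(self):
        fn = lambda fac: fac**2
        assert multiscale(fn, 2, 2.0) == pytest.approx((1 + 4) / 2)

    def test_engine_matches_manual_scale_average(self):
        rng = np.random.default_rng(8)
        img = rng.random((8, 8))
        b = rng.normal(size=(8, 8, 12)) * 0.3
        p2 = ModelParams(n_scales=2)
        eng = CostEngine(img, p2, s=0.0)
        c = eng.smooth(b)
        comps = eng.components(b)
        for n_fn, key in [(opposition_cost, "opposition")]:
            f0 = n_fn(c, p2.sigma_n, 1.0)
            f1 = n_fn(c, p2.sigma_n, p2.mu)
            assert comps[key] == pytest.approx((f0 + f1) / 2, rel=1e-10)


class TestTotalCost:
    def test_zero_map_has_only_ramp_floor(self):
        img = np.zeros((6, 6))
        p = ModelParams(alpha_c=0.0)
        assert total_cost(np.zeros((6, 6, 12)), img, p, s=0.1) == pytest.approx(0.0)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(9)
        img = rng.random((7, 7))
        b = rng.normal(size=(7, 7, 12)) * 0.5
        base = ModelParams()
        eng = CostEngine(img, base, s=0.2)
        comps = eng.components(b)
        only_a = ModelParams(alpha_a=2.0, alpha_r=0.0, alpha_v=0.0, alpha_n=0.0,
                             alpha_c=0.0, alpha_e=0.0)
        got = total_cost(b, img, only_a, s=0.2)
        assert got == pytest.approx(2.0 * comps["align"], rel=1e-10)

    def test_matches_independent_reimplementation(self):
        """Total cost vs a from-scratch recomposition out of the public
        component functions (smoothing, responses and components evaluated
        independently of the engine's fused path)."""
        rng = np.random.default_rng(10)
        img = rng.random((8, 8))
        b = rng.normal(size=(8, 8, 12)) * 0.4
        p = ModelParams()
        mult = ScaleMultipliers()
        s = 0.15
        c = smooth_bo(b, p.sigma_sa, p.sigma_sx * mult.bo(s))
        m_x = mult.spatial(s)
        sr = p.sigma_rp * mult.ramp(s)
        total = p.alpha_r * saturation_cost(c)
        for n in range(p.n_scales):
            fac = p.mu**n * m_x
            A = edge_responses(img, p.sigma_a * fac, p.L)
            total += (p.alpha_a * edge_alignment_cost(c, A)
                      + p.alpha_v * vacancy_cost(c, A, p.eps_v)
                      + p.alpha_n * opposition_cost(c, p.sigma_n, fac)
                      + p.alpha_c * continuity_cost(c, p, fac, sigma_rp=sr)
                      + p.alpha_e * bending_cost(c, p, fac)) / p.n_scales
        assert total_cost(b, img, p, s, mult) == pytest.approx(total, rel=1e-10)


class TestGradient:
    def test_zero_map_is_stationary(self):
        img = np.random.default_rng(0).random((6, 6))
        g = total_gradient(np.zeros((6, 6, 12)), img, ModelParams(), s=0.1)
        assert np.allclose(g, 0.0, atol=1e-12)

    def test_saturation_gradient_hand_value(self):
        p = ModelParams(alpha_a=0.0, alpha_r=1.0, alpha_v=0.0, alpha_n=0.0,
                        alpha_c=0.0, alpha_e=0.0, sigma_sa=1e-6, sigma_sx=1e-6)
        b = np.zeros((4, 4, 12))
        b[1, 1, 0] = 2.0
        g = total_gradient(b, np.zeros((4, 4)), p, s=0.0)
        assert g[1, 1, 0] == pytest.approx(4 * 2.0**3 / b.size, rel=1e-6)

    @pytest.mark.parametrize("s", [1.0, 0.3, 0.07])
    def test_finite_difference_agreement(self, s):
        """Analytic gradient vs central differences at every relaxation scale."""
        rng = np.random.default_rng(11)
        img = rng.random((6, 6))
        p = ModelParams()
        eng = CostEngine(img, p, s=s)
        h = 1e-5
        for trial in range(10):
            b = rng.uniform(-1, 1, (6, 6, 12))
            _, g = eng.cost_and_grad(b)
            for _ in range(6):
                i = tuple(rng.integers(0, d) for d in b.shape)
                bp, bm = b.copy(), b.copy()
                bp[i] += h
                bm[i] -= h
                fd = (eng.cost(bp) - eng.cost(bm)) / (2 * h)
                denom = max(abs(fd), abs(g[i]), 1e-8)
                assert abs(fd - g[i]) / denom < 1e-4


class TestSymmetries:
    def test_global_sign_flip_invariance(self):
        # the functional consumes the smoothed map only through its square,
        # so negating the whole map leaves every component unchanged (a
        # single-entry flip is NOT an invariance: smoothing mixes signs
        # before the squaring)
        rng = np.random.default_rng(12)
        img = rng.random((7, 7))
        b = rng.normal(size=(7, 7, 12)) * 0.5
        eng = CostEngine(img, ModelParams(), s=0.1)
        assert eng.cost(b) == pytest.approx(eng.cost(-b), rel=1e-12)

    def test_quarter_rotation_equivariance(self):
        rng = np.random.default_rng(13)
        img = rng.random((8, 8))
        b = rng.normal(size=(8, 8, 12)) * 0.5
        p = ModelParams()
        f = CostEngine(img, p, s=0.1).cost(b)
        f_rot = CostEngine(np.rot90(img), p, s=0.1).cost(rot90_map(b))
        assert f_rot == pytest.approx(f, rel=1e-10)
        comps = CostEngine(img, p, s=0.1).components(b)
        comps_rot = CostEngine(np.rot90(img), p, s=0.1).components(rot90_map(b))
        for k in comps:
            assert comps_rot[k] == pytest.approx(comps[k], rel=1e-9), k

    def test_mirror_equivariance(self):
        rng = np.random.default_rng(14)
        img = rng.random((8, 8))
        b = rng.normal(size=(8, 8, 12)) * 0.5
        p = ModelParams()
        L = 12
        # mirror through the vertical axis: x -> -x, angle -> pi - angle
        b_m = b[:, ::-1, :][..., [(6 - l) % L for l in range(L)]]
        f = CostEngine(img, p, s=0.1).cost(b)
        f_m = CostEngine(img[:, ::-1], p, s=0.1).cost(b_m)
        assert f_m == pytest.approx(f, rel=1e-10)
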