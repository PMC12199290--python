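"""Crooks/Bennett and Jarzynski estimators, work segmentation, the synthetic
Crooks-consistent generator and bootstrap errors."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from pathwork.neq_estimators import (
    FESProfile,
    SegmentWorkSet,
    bennett_solve,
    bootstrap_error,
    build_segment_work_set,
    cft_profile,
    generate_crooks_works,
    jarzynski_estimate,
    segment_works,
)
from pathwork.thermo import ThermoContext
from pathwork.toy_dynamics import WorkTrace

T300 = ThermoContext(300.0)
RT = T300.RT


def make_trace(s0, s1, w_fn, n=101, duration=1.0):
    """WorkTrace with a linear schedule and w_accum = w_fn(s_hat)."""
    t = np.linspace(0.0, duration, n)
    s_hat = s0 + (s1 - s0) * t / duration
    w = w_fn(s_hat) - w_fn(np.array([s0]))[0]
    return WorkTrace(times=t, s_hat=s_hat, s_inst=s_hat.copy(), w_accum=w)


class TestSegmentWorks:
    nodes = np.linspace(0.0, 1.0, 6)

    def test_linear_work_gives_equal_increments(self):
        tr = make_trace(0.0, 1.0, lambda s: 3.0 * s)
        _, inc = segment_works([tr], self.nodes, "forward")
        np.testing.assert_allclose(inc[:, 0], 3.0 / 5.0, atol=1e-12)

    def test_telescoping_sum_is_total_work(self):
        tr = make_trace(0.0, 1.0, lambda s: np.sin(3.0 * s) + 0.8 * s**2)
        _, inc = segment_works([tr], self.nodes, "forward")
        assert inc[:, 0].sum() == pytest.approx(tr.total_work, abs=1e-12)

    def test_crossing_interpolation_matches_hand_computation(self):
        # piecewise-linear w over 3 points; nodes fall between samples
        tr = WorkTrace(
            times=np.array([0.0, 1.0, 2.0]),
            s_hat=np.array([0.0, 0.5, 1.0]),
            s_inst=np.array([0.0, 0.5, 1.0]),
            w_accum=np.array([0.0, 2.0, 3.0]),
        )
        nodes = np.array([0.0, 0.25, 0.75, 1.0])
        _, inc = segment_works([tr], nodes, "forward")
        # w at s=0.25 → 1.0; at s=0.75 → 2.5
        np.testing.assert_allclose(inc[:, 0], [1.0, 1.5, 0.5], atol=1e-12)

    def test_backward_traces_flip_into_forward_convention(self):
        tr_b = make_trace(1.0, 0.0, lambda s: 2.0 * (1.0 - s))
        _, inc = segment_works([tr_b], self.nodes, "backward")
        # reverse process gains +2 total; forward convention → −2
        assert inc[:, 0].sum() == pytest.approx(-2.0, abs=1e-12)

    def test_non_spanning_trace_reports_replica(self):
        tr = make_trace(0.2, 1.0, lambda s: s)
        with pytest.raises(ValueError, match="replica 0"):
            segment_works([tr], self.nodes, "forward")


class TestBennett:
    def test_degenerate_fixed_point(self):
        w = np.full(7, 2.34)
        assert bennett_solve(w, w, T300) == pytest.approx(2.34, abs=1e-9)

    def test_single_sample_midpoint(self):
        assert bennett_solve([3.0], [1.0], T300) == pytest.approx(2.0, abs=1e-6)
        a, b = 5.7, -1.2
        assert bennett_solve([a], [b], T300) == pytest.approx((a + b) / 2, abs=1e-6)

    def test_matches_dense_scan_oracle_small_n(self):
        rng = np.random.default_rng(42)
        beta = T300.beta
        for n in (1, 2, 3):
            w_f = rng.normal(3.0, 1.0, n)
            w_b = rng.normal(2.0, 1.0, n)
            got = bennett_solve(w_f, w_b, T300)
            grid = np.arange(-10.0 * RT + min(w_b.min(), w_f.min()),
                             10.0 * RT + max(w_b.max(), w_f.max()), 1e-5 * RT)
            lhs = np.mean(1.0 / (1.0 + np.exp(beta * (w_f[:, None] - grid))), axis=0)
            rhs = np.mean(1.0 / (1.0 + np.exp(-beta * (w_b[:, None] - grid))), axis=0)
            k = int(np.argmin(np.abs(lhs - rhs)))
            assert got == pytest.approx(grid[k], abs=1e-4 * RT)

    def test_gaussian_crooks_recovery(self):
        dF = 5.0 * RT
        w_f, w_b = generate_crooks_works(dF, 2.0 * RT, 1000, T300, seed=1)
        est = bennett_solve(w_f, w_b, T300)
        boot = bootstrap_error(
            SegmentWorkSet(np.array([0.0, 1.0]), w_f[None, :], w_b[None, :]),
            lambda s: bennett_solve(s.w_forward[0], s.w_backward[0], T300),
            n_boot=200, seed=2,
        )
        assert est == pytest.approx(dF, abs=3 * boot.stderr)

    def test_direction_antisymmetry(self):
        rng = np.random.default_rng(3)
        w_f = rng.normal(2.0, 1.0, 20)
        w_b = rng.normal(1.0, 1.0, 20)
        assert bennett_solve(w_f, w_b, T300) == pytest.approx(
            -bennett_solve(-w_b, -w_f, T300), abs=1e-9
        )

    @given(st.floats(-5.0, 5.0))
    def test_constant_shift_moves_estimate_exactly(self, c):
        rng = np.random.default_rng(9)
        w_f = rng.normal(1.0, 0.5, 10)
        w_b = rng.normal(0.5, 0.5, 10)
        base = bennett_solve(w_f, w_b, T300)
        assert bennett_solve(w_f + c, w_b + c, T300) == pytest.approx(
            base + c, abs=1e-8
        )

    def test_unequal_counts_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            bennett_solve([1.0, 2.0], [1.0], T300)


class TestCFTProfile:
    def test_constant_increments_linear_profile(self):
        nodes = np.linspace(0.0, 1.0, 5)
        w = np.full((4, 6), 0.7)
        seg = SegmentWorkSet(nodes, w, w)
        fes = cft_profile(seg, T300)
        np.testing.assert_allclose(fes.F, 0.7 * np.arange(5), atol=1e-9)
        assert fes.F[0] == 0.0

    def test_direction_exchange_antisymmetry(self):
        rng = np.random.default_rng(5)
        nodes = np.linspace(0.0, 1.0, 4)
        wf = rng.normal(0.5, 0.3, (3, 8))
        wb = rng.normal(0.3, 0.3, (3, 8))
        fwd = cft_profile(SegmentWorkSet(nodes, wf, wb), T300)
        # swapping directions and negating works reverses the profile
        swapped = cft_profile(SegmentWorkSet(nodes, -wb, -wf), T300)
        np.testing.assert_allclose(swapped.F, -fwd.F, atol=1e-8)

    def test_bootstrap_errors_grow_along_profile(self):
        rng = np.random.default_rng(6)
        nodes = np.linspace(0.0, 1.0, 6)
        wf = rng.normal(0.5, 0.4, (5, 20))
        wb = rng.normal(0.4, 0.4, (5, 20))
        fes = cft_profile(SegmentWorkSet(nodes, wf, wb), T300, n_boot=150, seed=7)
        assert fes.stderr[0] == 0.0
        assert fes.stderr[-1] > fes.stderr[1] * 0.5  # cumulative, roughly growing
        assert np.all(fes.stderr[1:] > 0)


class TestJarzynski:
    def test_constant_works(self):
        dF, diag = jarzynski_estimate(np.full(10, 3.0), T300)
        assert dF == pytest.approx(3.0, abs=1e-12)
        assert diag.dissipated == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_closed_form(self):
        """⟨e^{−βW}⟩ for W ~ N(μ, σ²) gives ΔF = μ − βσ²/2."""
        mu, var = 7.0 * RT, 4.0 * RT * RT
        rng = np.random.default_rng(12)
        w = rng.normal(mu, np.sqrt(var), 100_000)
        batches = np.array([
            jarzynski_estimate(chunk, T300)[0] for chunk in np.split(w, 10)
        ])
        se = batches.std(ddof=1) / np.sqrt(10)
        dF, _ = jarzynski_estimate(w, T300)
        assert dF == pytest.approx(5.0 * RT, abs=3 * se)

    @given(st.lists(st.floats(-10.0, 10.0), min_size=1, max_size=30))
    def test_jensen_inequality(self, works):
        w = np.array(works)
        dF, diag = jarzynski_estimate(w, T300)
        assert dF <= w.mean() + 1e-9
        assert diag.dissipated >= -1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            jarzynski_estimate([], T300)


class TestCrooksGenerator:
    def test_zero_dissipation_limit(self):
        w_f, w_b = generate_crooks_works(2.0, 1e-9, 50, T300, seed=3)
        np.testing.assert_allclose(w_f, 2.0, atol=1e-7)
        np.testing.assert_allclose(w_b, 2.0, atol=1e-7)
        assert bennett_solve(w_f, w_b, T300) == pytest.approx(2.0, abs=1e-6)

    def test_log_density_ratio_is_crooks(self):
        """ln[P_f(W)/P_b(W)] = β(W − ΔF) for the generated Gaussian pair."""
        dF, sigma = 3.0, 1.5
        diss = T300.beta * sigma**2 / 2
        W = np.linspace(-2.0, 8.0, 31)
        log_ratio = (
            norm.logpdf(W, loc=dF + diss, scale=sigma)
            - norm.logpdf(W, loc=dF - diss, scale=sigma)
        )
        np.testing.assert_allclose(log_ratio, T300.beta * (W - dF), atol=1e-10)

    def test_symmetric_dissipation(self):
        dF, sigma, n = 5.0 * RT, 2.0 * RT, 4000
        w_f, w_b = generate_crooks_works(dF, sigma, n, T300, seed=8)
        se = sigma / np.sqrt(n)
        assert w_f.mean() - dF == pytest.approx(dF - w_b.mean(), abs=3 * np.sqrt(2) * se)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            generate_crooks_works(1.0, 0.0, 10, T300)
        with pytest.raises(ValueError):
            generate_crooks_works(1.0, 1.0, 0, T300)


class TestBootstrap:
    def test_zero_variance_zero_stderr(self):
        w = np.full(20, 1.5)
        res = bootstrap_error(w, lambda x: float(np.mean(x)), n_boot=100, seed=1)
        assert res.stderr == 0.0
        assert res.ci_low == res.ci_high == 1.5

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        w = rng.normal(size=30)
        r1 = bootstrap_error(w, lambda x: float(np.mean(x)), n_boot=150, seed=5)
        r2 = bootstrap_error(w, lambda x: float(np.mean(x)), n_boot=150, seed=5)
        assert (r1.stderr, r1.ci_low, r1.ci_high) == (r2.stderr, r2.ci_low, r2.ci_high)

    def test_ci_coverage_on_crooks_works(self):
        """95% bootstrap CI covers the true ΔF in ≥ 90/100 experiments."""
        dF = 5.0 * RT
        covered = 0
        for rep in range(100):
            w_f, w_b = generate_crooks_works(dF, 2.0 * RT, 30, T300, seed=1000 + rep)
            seg = SegmentWorkSet(np.array([0.0, 1.0]), w_f[None, :], w_b[None, :])
            res = bootstrap_error(
                seg,
                lambda s: bennett_solve(s.w_forward[0], s.w_backward[0], T300),
                n_boot=200, seed=rep,
            )
            covered += res.ci_low <= dF <= res.ci_high
        assert covered >= 90

    def test_block_bootstrap_shape_and_determinism(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        r1 = bootstrap_error(x, lambda v: float(np.mean(v)), n_boot=400, seed=9,
                             blocks=10)
        r2 = bootstrap_error(x, lambda v: float(np.mean(v)), n_boot=400, seed=9,
                             blocks=10)
        assert r1.stderr == r2.stderr > 0

    def test_too_few_replicas(self):
        seg = SegmentWorkSet(np.array([0.0, 1.0]),
                             np.array([[1.0]]), np.array([[1.0]]))
        with pytest.raises(ValueError, match="2 replicas"):
            bootstrap_error(seg, lambda s: 0.0, n_boot=100, seed=0)


def test_estimator_hierarchy_under_dissipation():
    """Bidirectional Bennett mitigates dissipation better than Jarzynski.

    At σ = 3 RT the Jarzynski exponential average is dominated by rare low
    tails and retains a positive bias that the paired estimator does not.
    """
    dF, sigma, n = 0.0, 3.0 * RT, 30
    bennett_err, jarz_err = [], []
    for rep in range(100):
        w_f, w_b = generate_crooks_works(dF, sigma, n, T300, seed=5000 + rep)
        bennett_err.append(bennett_solve(w_f, w_b, T300) - dF)
        jarz_err.append(jarzynski_estimate(w_f, T300)[0] - dF)
    assert abs(np.mean(bennett_err)) <= abs(np.mean(jarz_err))


def test_segment_work_set_validation():
    nodes = np.array([0.0, 0.5, 1.0])
    with pytest.raises(ValueError, match="equal numbers"):
        SegmentWorkSet(nodes, np.ones((2, 3)), np.ones((2, 4)))
    with pytest.raises(ValueError, match="finite"):
        SegmentWorkSet(nodes, np.full((2, 2), np.nan), np.ones((2, 2)))


def test_fes_profile_anchoring():
    with pytest.raises(ValueError, match="anchored"):
        FESProfile(np.array([0.0, 1.0]), np.array([1.0, 2.0]), np.zeros(2))


def test_build_segment_work_set_pairs_directions():
    tr_f = make_trace(0.0, 1.0, lambda s: 2.0 * s)
    tr_b = make_trace(1.0, 0.0, lambda s: 2.0 * (1.0 - s))
    seg = build_segment_work_set([tr_f], [tr_b], np.linspace(0.0, 1.0, 5))
    assert seg.n_replicas == 1
    # forward increments +0.5 each; backward in forward convention −0.5 each
    np.testing.assert_allclose(seg.w_forward[:, 0], 0.5)
    np.testing.assert_allclose(seg.w_backward[:, 0], -0.5)
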