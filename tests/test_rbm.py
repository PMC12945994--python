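"""Core model oracles: energy, free energy, conditionals, Gibbs sampling,
score function, and the exact small-model partition function."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crossrbm.exceptions import CapabilityError, DimensionError, ValidationError
from crossrbm.rbm import (
    GibbsChain,
    RBMParams,
    cond_hidden,
    cond_visible,
    energy,
    exact_log_partition,
    exact_visible_mixture,
    free_energy,
    gibbs_run,
    gibbs_sweep,
    sample_hidden,
    sample_visible,
    score_x,
)
from conftest import random_params


def energy_reference(x, h, p):
    """Independent term-by-term transcription of the energy function."""
    D, H = p.n_visible, p.n_hidden
    total = 0.0
    for d in range(D):
        total += 0.5 * p.lam[d] * (x[d] - p.c[d]) ** 2
    for j in range(H):
        for d in range(D):
            total -= h[j] * p.W[j, d] * p.lam[d] * x[d]
        total -= p.b[j] * h[j]
    return total


class TestEnergy:
    def test_zero_at_reference_state(self, small_params):
        p = small_params
        assert energy(p.c, np.zeros(p.n_hidden), p) == pytest.approx(0.0)

    def test_pure_quadratic_when_decoupled(self):
        p = RBMParams(W=np.zeros((2, 2)), b=np.zeros(2), c=np.zeros(2), lam=np.ones(2))
        for h in itertools.product([0.0, 1.0], repeat=2):
            assert energy(np.ones(2), np.array(h), p) == pytest.approx(1.0)

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(10):
            p = random_params(rng, D=3, H=2)
            x = rng.standard_normal(3)
            h = (rng.random(2) < 0.5).astype(float)
            assert energy(x, h, p) == pytest.approx(energy_reference(x, h, p), abs=1e-12)

    def test_shape_and_binary_validation(self, small_params):
        p = small_params
        with pytest.raises(DimensionError):
            energy(np.zeros(p.n_visible + 1), np.zeros(p.n_hidden), p)
        with pytest.raises(ValidationError):
            energy(np.zeros(p.n_visible), np.full(p.n_hidden, 0.5), p)


class TestFreeEnergy:
    def test_decoupled_closed_form(self):
        H = 4
        p = RBMParams(W=np.zeros((H, 2)), b=np.zeros(H), c=np.array([1.0, -2.0]),
                      lam=np.ones(2))
        assert free_energy(p.c, p) == pytest.approx(-H * np.log(2.0))

    def test_one_dim_closed_form(self):
        p = RBMParams(W=np.zeros((1, 1)), b=np.zeros(1), c=np.zeros(1), lam=np.array([2.0]))
        assert free_energy(np.array([1.0]), p) == pytest.approx(1.0 - np.log(2.0))

    @pytest.mark.parametrize("seed", range(5))
    def test_marginalization_identity(self, seed):
        """exp(-F(x)) equals the brute-force sum of exp(-E(x,h)) over all h."""
        rng = np.random.default_rng(seed)
        H = int(rng.integers(1, 11))
        p = random_params(rng, D=3, H=H)
        x = rng.standard_normal(3)
        hs = np.array(list(itertools.product([0.0, 1.0], repeat=H)))
        brute = sum(np.exp(-energy(x, h, p)) for h in hs)
        assert np.exp(-free_energy(x, p)) == pytest.approx(brute, rel=1e-10)

    def test_stable_at_extreme_field(self):
        """Noise-initialized states can drive WLx+b far positive; no overflow."""
        p = RBMParams(W=np.full((2, 2), 50.0), b=np.full(2, 100.0),
                      c=np.zeros(2), lam=np.ones(2))
        val = free_energy(np.full(2, 10.0), p)
        assert np.isfinite(val)


class TestConditionals:
    def test_hidden_decoupled_is_half(self):
        p = RBMParams(W=np.zeros((3, 2)), b=np.zeros(3), c=np.zeros(2), lam=np.ones(2))
        assert cond_hidden(np.array([0.3, -0.7]), p) == pytest.approx(0.5)

    def test_hidden_saturation(self):
        p = RBMParams(W=np.zeros((2, 2)), b=np.array([20.0, 0.0]),
                      c=np.zeros(2), lam=np.ones(2))
        probs = cond_hidden(np.zeros(2), p)
        assert probs[0] >= 1 - 3e-9

    def test_hidden_matches_joint_enumeration(self, rng):
        """p(h_j=1|x) from the sigmoid equals the ratio of enumerated joints."""
        p = random_params(rng, D=2, H=2)
        x = rng.standard_normal(2)
        hs = np.array(list(itertools.product([0.0, 1.0], repeat=2)))
        w = np.array([np.exp(-energy(x, h, p)) for h in hs])
        for j in range(2):
            marginal = w[hs[:, j] == 1].sum() / w.sum()
            assert cond_hidden(x, p)[j] == pytest.approx(marginal, rel=1e-10)

    def test_visible_mean_and_precision(self, small_params):
        p = small_params
        mean, prec = cond_visible(np.zeros(p.n_hidden), p)
        assert mean == pytest.approx(p.c)
        assert prec == pytest.approx(p.lam)
        mean1, _ = cond_visible(np.array([1.0, 0.0]), p)
        assert mean1 == pytest.approx(p.W[0] + p.c)


class TestSampling:
    def test_bit_reproducible(self, small_params):
        p = small_params
        x = np.ones(p.n_visible)
        h1 = sample_hidden(x, p, np.random.default_rng(5))
        h2 = sample_hidden(x, p, np.random.default_rng(5))
        assert np.array_equal(h1, h2)
        v1 = sample_visible(h1, p, np.random.default_rng(6))
        v2 = sample_visible(h1, p, np.random.default_rng(6))
        assert np.array_equal(v1, v2)

    def test_hidden_marginal_rate_decoupled(self):
        p = RBMParams(W=np.zeros((3, 2)), b=np.zeros(3), c=np.zeros(2), lam=np.ones(2))
        rng = np.random.default_rng(0)
        draws = sample_hidden(np.tile(np.ones(2), (10_000, 1)), p, rng)
        sd = 0.5 / np.sqrt(10_000)
        assert np.all(np.abs(draws.mean(axis=0) - 0.5) < 3 * sd + 1e-9)

    def test_visible_moments(self, rng, small_params):
        p = small_params
        h = np.array([1.0, 0.0])
        draws = sample_visible(np.tile(h, (100_000, 1)), p, rng)
        mean, prec = cond_visible(h, p)
        se = 1.0 / np.sqrt(prec * 100_000)
        assert np.all(np.abs(draws.mean(axis=0) - mean) < 4 * se)
        assert np.allclose(draws.var(axis=0), 1.0 / prec, rtol=0.05)


class TestGibbs:
    def test_k_validation(self, small_params):
        with pytest.raises(ValidationError):
            gibbs_run(np.zeros(3), 0, small_params, np.random.default_rng(0))

    def test_run_composes_sweeps(self, small_params):
        p = small_params
        x0 = np.ones(p.n_visible)
        out = gibbs_run(x0, 3, p, np.random.default_rng(9))
        chain = GibbsChain(x=x0.copy(), rng=np.random.default_rng(9))
        for _ in range(3):
            gibbs_sweep(chain, p)
        assert chain.step_count == 3
        assert np.array_equal(out, chain.x)

    def test_decoupled_forgets_start(self):
        """With W=0 one sweep already samples N(c, 1/lam) regardless of x0."""
        p = RBMParams(W=np.zeros((2, 2)), b=np.zeros(2),
                      c=np.array([2.0, -1.0]), lam=np.array([4.0, 1.0]))
        rng = np.random.default_rng(3)
        n = 20_000
        out = gibbs_run(np.tile([100.0, -100.0], (n, 1)), 1, p, rng)
        se = 1.0 / np.sqrt(p.lam * n)
        assert np.all(np.abs(out.mean(axis=0) - p.c) < 4 * se)
        assert np.allclose(out.var(axis=0), 1.0 / p.lam, rtol=0.05)

    def test_long_chain_matches_exact_mixture_moments(self, rng):
        """Stationary visible moments agree with the enumerated Gaussian
        mixture that is the exact marginal of a D=2, H=2 model."""
        p = random_params(rng, D=2, H=2, scale=0.6)
        logw, means, lam = exact_visible_mixture(p)
        w = np.exp(logw)
        exact_mean = w @ means
        exact_second = w @ (means**2 + 1.0 / lam)
        n_chains, k = 400, 60
        x = rng.standard_normal((n_chains, 2))
        samples = []
        chain = GibbsChain(x=x, rng=rng)
        for sweep in range(k):
            gibbs_sweep(chain, p)
            if sweep >= 10:
                samples.append(chain.x.copy())
        S = np.concatenate(samples)
        assert np.all(np.abs(S.mean(axis=0) - exact_mean) < 0.08)
        assert np.all(np.abs((S**2).mean(axis=0) - exact_second) < 0.15)


class TestScore:
    def test_gaussian_case(self):
        p = RBMParams(W=np.zeros((2, 3)), b=np.zeros(2),
                      c=np.array([1.0, 0.0, -1.0]), lam=np.array([1.0, 2.0, 3.0]))
        x = np.array([2.0, 1.0, 0.0])
        assert score_x(x, p) == pytest.approx(p.lam * (p.c - x))
        assert score_x(p.c, p) == pytest.approx(np.zeros(3), abs=1e-14)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_negative_free_energy_gradient(self, seed):
        rng = np.random.default_rng(seed)
        p = random_params(rng, D=4, H=3)
        x = rng.standard_normal(4)
        eps = 1e-5
        for d in range(4):
            e = np.zeros(4)
            e[d] = eps
            fd = -(free_energy(x + e, p) - free_energy(x - e, p)) / (2 * eps)
            assert score_x(x, p)[d] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_line_integral_recovers_free_energy_difference(self, rng):
        """The score is a gradient field: its line integral between two
        points equals -(F(x1) - F(x0))."""
        p = random_params(rng, D=3, H=2)
        x0, x1 = rng.standard_normal(3), rng.standard_normal(3)
        ts = np.linspace(0, 1, 2001)
        pts = x0 + ts[:, None] * (x1 - x0)
        integrand = score_x(pts, p) @ (x1 - x0)
        integral = np.trapezoid(integrand, ts)
        assert integral == pytest.approx(-(free_energy(x1, p) - free_energy(x0, p)),
                                         rel=1e-3, abs=1e-3)


class TestExactPartition:
    def test_decoupled_closed_form(self):
        H, D = 3, 2
        lam = np.array([2.0, 0.5])
        p = RBMParams(W=np.zeros((H, D)), b=np.zeros(H), c=np.ones(D), lam=lam)
        expect = H * np.log(2.0) + 0.5 * np.sum(np.log(2 * np.pi / lam))
        assert exact_log_partition(p) == pytest.approx(expect, rel=1e-12)

    def test_matches_quadrature(self, rng):
        """1-D model: grid quadrature of exp(-F) reproduces log Z."""
        p = random_params(rng, D=1, H=1)
        lo = p.c[0] - 30.0
        hi = p.c[0] + 30.0 + abs(p.W).max() * 30
        grid = np.linspace(lo, hi, 400_001)
        vals = np.exp(-free_energy(grid[:, None], p))
        logz = np.log(np.trapezoid(vals, grid))
        assert exact_log_partition(p) == pytest.approx(logz, abs=1e-6)

    def test_bias_shift_consistent_with_enumeration(self, rng):
        p = random_params(rng, D=2, H=3)
        shifted = RBMParams(p.W, p.b + 0.7, p.c, p.lam)
        # recompute both by enumeration; the implementation must track the shift
        assert exact_log_partition(shifted) > exact_log_partition(p)
        hs = np.array(list(itertools.product([0.0, 1.0], repeat=3)))
        x = rng.standard_normal(2)
        lhs = np.exp(-free_energy(x, shifted))
        rhs = sum(np.exp(-energy(x, h, shifted)) for h in hs)
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_enumeration_bound(self):
        p = RBMParams(W=np.zeros((13, 2)), b=np.zeros(13), c=np.zeros(2), lam=np.ones(2))
        with pytest.raises(CapabilityError):
            exact_log_partition(p)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    seed=st.integers(0, 2**20),
    D=st.integers(1, 4),
    H=st.integers(1, 6),
)
def test_property_marginalization_identity(seed, D, H):
    """For any small model, summing the hidden layer out of the joint
    Boltzmann weight reproduces exp(-F)."""
    rng = np.random.default_rng(seed)
    p = random_params(rng, D=D, H=H)
    x = rng.standard_normal(D)
    hs = np.array(list(itertools.product([0.0, 1.0], repeat=H)))
    brute = sum(np.exp(-energy(x, h, p)) for h in hs)
    assert np.exp(-free_energy(x, p)) == pytest.approx(brute, rel=1e-10)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 2**20))
def test_property_score_is_negative_free_energy_gradient(seed):
    rng = np.random.default_rng(seed)
    p = random_params(rng, D=3, H=3)
    x = rng.standard_normal(3)
    eps = 1e-5
    g = score_x(x, p)
    for d in range(3):
        e = np.zeros(3)
        e[d] = eps
        fd = -(free_energy(x + e, p) - free_energy(x - e, p)) / (2 * eps)
        assert g[d] == pytest.approx(fd, rel=2e-5, abs=1e-6)
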