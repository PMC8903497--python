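"""Unit tests of the measure battery against independent oracles and
known analytic limits."""

import numpy as np
import pytest

from nldeeg import measures as M
from nldeeg.decomposition import coarse_grain

import oracles


CFG = M.MeasureConfig()


def logistic_map(n: int, x0: float = 0.4) -> np.ndarray:
    x = np.empty(n)
    x[0] = x0
    for i in range(1, n):
        x[i] = 4.0 * x[i - 1] * (1.0 - x[i - 1])
    return x


@pytest.fixture(scope="module")
def random_series():
    rng = np.random.default_rng(12345)
    return [rng.standard_normal(n) for n in [200] * 10 + [1000] * 10]


# --------------------------------------------------------------------------
# brute-force oracle equivalence


@pytest.mark.parametrize("fast, naive", [
    (M.sample_entropy, oracles.sampen_naive),
    (M.approximate_entropy, oracles.apen_naive),
    (M.permutation_entropy, oracles.permen_naive),
    (M.lempel_ziv, oracles.lzc_naive),
    (M.higuchi_fd, oracles.higuchi_naive),
    (M.katz_fd, oracles.katz_naive),
], ids=["SampE", "AppE", "PermE", "LZC", "HFD", "KFD"])
def test_oracle_equivalence(fast, naive, random_series):
    """Accelerated implementations agree with naive template/loop versions
    to within numerical round-off on random series."""
    for x in random_series:
        assert fast(x, CFG) == pytest.approx(naive(x), abs=1e-9)


def test_sample_entropy_periodic_near_zero():
    x = np.tile([1.0, 2.0], 100)
    assert M.sample_entropy(x) == pytest.approx(0.0, abs=1e-9)


def test_permutation_entropy_hand_counted():
    # patterns of [4,7,9,10,6,11,3]: 012, 012, 201, 102, 201
    # -> probabilities 2/5, 2/5, 1/5
    x = np.array([4.0, 7.0, 9.0, 10.0, 6.0, 11.0, 3.0])
    expected = (-2 * (2 / 5) * np.log2(2 / 5)
                - (1 / 5) * np.log2(1 / 5))
    assert M.permutation_entropy(x) == pytest.approx(expected, abs=1e-12)


def test_permutation_entropy_monotone_is_zero():
    assert M.permutation_entropy(np.arange(50.0)) == 0.0


def test_permutation_entropy_uniform_limit():
    rng = np.random.default_rng(3)
    h = M.permutation_entropy(rng.uniform(size=100_000))
    assert h == pytest.approx(np.log2(6), abs=0.02)


# --------------------------------------------------------------------------
# affine invariance (where guaranteed)


@pytest.mark.parametrize("measure", [
    M.sample_entropy, M.approximate_entropy, M.permutation_entropy,
    M.katz_fd, M.higuchi_fd, M.lempel_ziv,
], ids=["SampE", "AppE", "PermE", "KFD", "HFD", "LZC"])
def test_affine_invariance(measure):
    rng = np.random.default_rng(7)
    x = rng.standard_normal(500)
    assert measure(5.0 * x + 3.0, CFG) == pytest.approx(measure(x, CFG),
                                                        rel=1e-9, abs=1e-9)


def test_power_rel_scaling_invariance_and_degenerate_cases():
    rng = np.random.default_rng(0)
    parent = rng.standard_normal(1000)
    band = parent * 0.3 + rng.standard_normal(1000) * 0.1
    v = M.power_rel(band, parent)
    assert M.power_rel(2.0 * band, 2.0 * parent) == pytest.approx(v, rel=1e-12)
    assert M.power_rel(np.zeros(100), parent) == 0.0
    assert M.power_rel(parent, parent) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# degenerate inputs


@pytest.mark.parametrize("measure", [
    M.sample_entropy, M.approximate_entropy, M.svd_entropy,
], ids=["SampE", "AppE", "SVDE"])
def test_constant_series_returns_zero(measure):
    assert measure(np.full(200, 3.14), CFG) == pytest.approx(0.0, abs=1e-9)


@pytest.mark.parametrize("measure", list(M.MEASURES.values()),
                         ids=list(M.MEASURES))
def test_errors_on_short_or_nonfinite(measure):
    with pytest.raises(ValueError):
        measure(np.array([1.0, 2.0]), CFG)
    bad = np.ones(300)
    bad[5] = np.nan
    with pytest.raises(ValueError):
        measure(bad, CFG)


def test_all_measures_finite_on_random_input():
    rng = np.random.default_rng(9)
    for n in (200, 1000):
        x = rng.standard_normal(n)
        for name, fn in M.MEASURES.items():
            assert np.isfinite(fn(x, CFG)), name


# --------------------------------------------------------------------------
# spectral and SVD entropy


def test_spectral_entropy_concentration():
    t = np.arange(5000) / 250.0
    sine = np.sin(2 * np.pi * 10 * t)
    rng = np.random.default_rng(2)
    assert M.spectral_entropy(sine) <= 0.2
    assert M.spectral_entropy(rng.standard_normal(5000)) >= 0.9
    assert M.spectral_entropy(3.0 * sine) == pytest.approx(
        M.spectral_entropy(sine), rel=1e-12)


def test_svd_entropy_rank_structure():
    t = np.arange(2000) / 250.0
    sine = np.sin(2 * np.pi * 10 * t)
    rng = np.random.default_rng(4)
    noise = rng.standard_normal(2000)
    h_sine = M.svd_entropy(sine)
    # two dominant singular values -> about one bit
    assert h_sine == pytest.approx(1.0, abs=0.15)
    assert M.svd_entropy(noise) > h_sine


# --------------------------------------------------------------------------
# fractal dimensions


def test_higuchi_limits():
    rng = np.random.default_rng(5)
    assert M.higuchi_fd(np.linspace(0, 1, 2000)) == pytest.approx(1.0, abs=0.05)
    noise_fd = np.mean([M.higuchi_fd(rng.standard_normal(2000))
                        for _ in range(5)])
    assert noise_fd == pytest.approx(2.0, abs=0.1)
    t = np.arange(5000) / 250.0
    assert M.higuchi_fd(np.sin(2 * np.pi * 10 * t)) < 1.3


def test_katz_straight_line_exact():
    assert M.katz_fd(np.linspace(0, 5, 100)) == 1.0


def test_katz_zigzag_hand_computed():
    x = np.array([0.0, 2.0, 1.0, 3.0, 0.5])
    # L = 2+1+2+2.5 = 7.5, d = 3, n = 4 steps
    expected = np.log10(4) / (np.log10(4) + np.log10(3.0 / 7.5))
    assert M.katz_fd(x) == pytest.approx(expected, abs=1e-12)


# --------------------------------------------------------------------------
# Lempel-Ziv


def test_lzc_known_sequences():
    rng = np.random.default_rng(6)
    n = 1000
    alternating = np.tile([0.0, 1.0], n // 2)
    assert M.lempel_ziv(alternating) <= 0.1
    assert M.lempel_ziv(rng.standard_normal(5000)) == pytest.approx(1.0,
                                                                    abs=0.1)
    # constant series: minimal phrase count
    assert M.lempel_ziv(np.zeros(1000)) <= 2 * np.log2(1000) / 1000


# --------------------------------------------------------------------------
# scaling exponents


def test_dfa_known_processes():
    rng = np.random.default_rng(8)
    white = np.mean([M.dfa_alpha(rng.standard_normal(10_000))
                     for _ in range(5)])
    assert white == pytest.approx(0.5, abs=0.05)
    walk = np.mean([M.dfa_alpha(np.cumsum(rng.standard_normal(10_000)))
                    for _ in range(5)])
    assert walk == pytest.approx(1.5, abs=0.1)
    pink = np.mean([M.dfa_alpha(oracles.fgn(10_000, 0.999, rng))
                    for _ in range(5)])
    assert pink == pytest.approx(1.0, abs=0.1)


def test_hurst_known_processes():
    rng = np.random.default_rng(10)
    white = np.mean([M.hurst_exponent(rng.standard_normal(10_000))
                     for _ in range(5)])
    assert white == pytest.approx(0.5, abs=0.07)
    persistent = np.mean([M.hurst_exponent(oracles.fgn(10_000, 0.8, rng))
                          for _ in range(5)])
    assert persistent == pytest.approx(0.8, abs=0.1)
    x = rng.standard_normal(5000)
    assert M.hurst_exponent(4.0 * x + 1.0) == pytest.approx(
        M.hurst_exponent(x), rel=1e-9)


# --------------------------------------------------------------------------
# Lyapunov


def test_lyapunov_logistic_map():
    lam = M.lyapunov_exponent(logistic_map(5000))
    assert lam == pytest.approx(np.log(2), abs=0.05)


def test_lyapunov_sinusoid_near_zero():
    t = np.arange(5000) / 250.0
    assert M.lyapunov_exponent(np.sin(2 * np.pi * 10 * t)) <= 0.01


def test_lyapunov_deterministic():
    x = logistic_map(3000, x0=0.31)
    assert M.lyapunov_exponent(x) == M.lyapunov_exponent(x)


# --------------------------------------------------------------------------
# multiscale entropy


def test_mse_scale_one_is_sample_entropy():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(1000)
    assert M.multiscale_entropy(x, 1) == M.sample_entropy(x)


def test_mse_matches_explicit_composition():
    rng = np.random.default_rng(12)
    x = rng.standard_normal(2000)
    for scale in (2, 3, 4):
        direct = M.sample_entropy(coarse_grain(x, 2 ** (scale - 1)))
        assert M.multiscale_entropy(x, scale) == direct


def test_mse_decreases_with_scale_for_white_noise():
    rng = np.random.default_rng(13)
    vals = [np.mean([M.multiscale_entropy(rng.standard_normal(4000), s)
                     for _ in range(3)]) for s in (1, 3, 5)]
    assert vals[0] > vals[1] > vals[2]
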