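"""Independent brute-force reference implementations used as test oracles.

Deliberately naive (explicit loops, O(n^2) template matching) and written
against the textbook definitions, not against the package's code paths.
"""

from __future__ import annotations

import math

import numpy as np


def chebyshev(a, b) -> float:
    return max(abs(x - y) for x, y in zip(a, b))


def sampen_naive(x, m=2, r_coeff=0.2) -> float:
    """Richman-Moorman sample entropy by explicit template counting,
    base-2 logs, matches at distance <= r, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = x.size
    r = r_coeff * x.std()
    n_t = n - m  # same template count at both lengths

    def count(mm, n_templates):
        tpl = np.array([x[i:i + mm] for i in range(n_templates)])
        c = 0
        for i in range(n_templates):
            d = np.max(np.abs(tpl - tpl[i]), axis=1)
            c += int(np.sum(d <= r)) - 1  # drop the self-match
        return c

    b = count(m, n_t)
    a = count(m + 1, n - m)
    if b == 0:
        return 0.0
    if a == 0:
        return math.log2(b)
    return -math.log2(a / b)


def apen_naive(x, m=2, r_coeff=0.2) -> float:
    """Pincus approximate entropy, self-matches included, base-2 logs."""
    x = np.asarray(x, dtype=float)
    n = x.size
    r = r_coeff * x.std()

    def phi(mm):
        n_t = n - mm + 1
        tpl = np.array([x[i:i + mm] for i in range(n_t)])
        total = 0.0
        for i in range(n_t):
            d = np.max(np.abs(tpl - tpl[i]), axis=1)
            c = int(np.sum(d <= r))
            total += math.log2(c / n_t)
        return total / n_t

    return phi(m) - phi(m + 1)


def permen_naive(x, order=3, delay=1) -> float:
    """Shannon entropy (bits) of ordinal patterns via stable argsort."""
    x = np.asarray(x, dtype=float)
    counts: dict[tuple, int] = {}
    n_win = x.size - (order - 1) * delay
    for i in range(n_win):
        w = x[i:i + (order - 1) * delay + 1:delay]
        pat = tuple(np.argsort(w, kind="stable"))
        counts[pat] = counts.get(pat, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_win
        h -= p * math.log2(p)
    return h


def lz76_naive(symbols) -> int:
    """Kaspar-Schuster LZ76 phrase-count algorithm (index-walking form)."""
    s = list(symbols)
    n = len(s)
    i, k, l = 0, 1, 1
    k_max, c = 1, 1
    while l + k <= n:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    if k > 1 or l < n:
        c += 1
    return c


def lzc_naive(x) -> float:
    x = np.asarray(x, dtype=float)
    bits = [1 if v > np.median(x) else 0 for v in x]
    n = len(bits)
    return lz76_naive(bits) * math.log2(n) / n


def higuchi_naive(x, kmax=8) -> float:
    x = np.asarray(x, dtype=float)
    n = x.size
    lk = []
    for k in range(1, kmax + 1):
        lengths = []
        for m in range(k):
            idx = list(range(m, n, k))
            if len(idx) < 2:
                continue
            path = sum(abs(x[idx[t + 1]] - x[idx[t]])
                       for t in range(len(idx) - 1))
            lengths.append(path * (n - 1) / ((len(idx) - 1) * k) / k)
        lk.append(sum(lengths) / len(lengths))
    xs = [math.log(1.0 / k) for k in range(1, kmax + 1)]
    ys = [math.log(v) for v in lk]
    return float(np.polyfit(xs, ys, 1)[0])


def katz_naive(x) -> float:
    x = np.asarray(x, dtype=float)
    L = sum(abs(x[i + 1] - x[i]) for i in range(x.size - 1))
    d = max(abs(v - x[0]) for v in x)
    if L == 0 or d == 0:
        return 1.0
    n = x.size - 1
    return math.log10(n) / (math.log10(n) + math.log10(d / L))


def coarse_naive(x, factor):
    x = np.asarray(x, dtype=float)
    out = []
    for j in range(x.size // factor):
        out.append(float(np.mean(x[j * factor:(j + 1) * factor])))
    return np.array(out)


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (Davies-Harte)."""
    k = np.arange(n + 1)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    eig = np.fft.fft(row).real
    eig[eig < 0] = 0.0  # numerical guard
    m = row.size
    noise = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    series = np.fft.fft(np.sqrt(eig / m) * noise)
    return series[:n].real
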