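"""Independent brute-force oracles used by the test suite.

Each function is a deliberately naive re-derivation (double loops,
exhaustive enumeration, direct formula evaluation) kept free of any code
path in the package under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sampen_brute(x, m: int, r: float) -> float:
    """Naive O(N^2) sample entropy, self-matches excluded."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


def apen_brute(x, m: int, r: float) -> float:
    """Naive O(N^2) approximate entropy, self-matches included."""
    x = np.asarray(x, dtype=float)

    def phi(mm: int) -> float:
        n_t = len(x) - mm + 1
        total = 0.0
        for i in range(n_t):
            c = 0
            for j in range(n_t):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
            total += math.log(c / n_t)
        return total / n_t

    return phi(m) - phi(m + 1)


def pren_brute(x, order: int = 3, delay: int = 1) -> float:
    """Permutation entropy by exhaustive enumeration of ordinal patterns."""
    x = np.asarray(x, dtype=float)
    counts: dict[tuple, int] = {}
    n = len(x) - (order - 1) * delay
    for i in range(n):
        window = [(x[i + k * delay], k) for k in range(order)]
        pattern = tuple(k for _, k in sorted(window))  # index breaks ties
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum(c / total * math.log(c / total) for c in counts.values())
    return h / math.log(math.factorial(order))


def svden_brute(x, order: int = 3, delay: int = 1) -> float:
    """SVD entropy from an explicitly built trajectory matrix."""
    x = np.asarray(x, dtype=float)
    n = len(x) - (order - 1) * delay
    mat = np.array([[x[i + k * delay] for k in range(order)] for i in range(n)])
    s = np.linalg.svd(mat, compute_uv=False)
    p = s / s.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)) / np.log(order))


def lz76_brute(bits: str) -> int:
    """LZ76 exhaustive parsing phrase count on a 0/1 string."""
    n = len(bits)
    i = phrases = 0
    while i < n:
        j = i + 1
        while j < n and bits[i:j] in bits[: j - 1]:
            j += 1
        phrases += 1
        i = j
    return phrases


def auc_pairs_brute(y_true, y_score) -> float:
    """AUC by counting concordant pairs (half credit for ties)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    pos = y_score[y_true == 1]
    neg = y_score[y_true == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def ks_sup_brute(a, b) -> float:
    """Two-sample KS statistic as the exhaustive ECDF sup-distance."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        best = max(best, abs(fa - fb))
    return best


def band_power_fft(x, fs, lo, hi) -> float:
    """FFT band power of a real signal, the filter-test oracle."""
    x = np.asarray(x, dtype=float)
    spec = np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(len(x), 1.0 / fs)
    return float(spec[(f >= lo) & (f <= hi)].sum())


def spearman_rank_pearson(x) -> np.ndarray:
    """Spearman matrix as Pearson correlation of ranks."""
    from scipy.stats import rankdata

    ranks = np.column_stack([rankdata(col) for col in np.asarray(x, float).T])
    return np.corrcoef(ranks, rowvar=False)
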