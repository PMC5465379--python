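"""Independent brute-force reference implementations used to check features.

These deliberately avoid the vectorized code paths in the package: explicit
loops, scipy.stats estimators, and a direct DFT sum.
"""

import numpy as np
from scipy import stats


def sampen_bruteforce(x, m, r):
    """Sample entropy by exhaustive template-pair enumeration.

    Both template lengths are counted over the same n - m starting
    positions (standard convention).
    """
    x = np.asarray(x, float)
    n = len(x)

    def count(mm):
        c = 0
        for i in range(n - m):
            for j in range(i + 1, n - m):
                if max(abs(x[i + k] - x[j + k]) for k in range(mm)) <= r:
                    c += 1
        return c

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return float("inf")
    return -np.log(a / b)


def periodogram_bruteforce(x, fs):
    """One-sided periodogram of the mean-removed series via an explicit DFT sum."""
    x = np.asarray(x, float)
    n = len(x)
    d = x - x.mean()
    freqs = np.arange(n // 2 + 1) * fs / n
    p = np.empty(len(freqs))
    t = np.arange(n)
    for k in range(len(freqs)):
        c = np.sum(d * np.cos(-2 * np.pi * k * t / n))
        s = np.sum(d * np.sin(-2 * np.pi * k * t / n))
        p[k] = (c * c + s * s) / (fs * n)
        if 0 < k < n / 2:
            p[k] *= 2.0
    return freqs, p


def band_power_bruteforce(x, fs, lo, hi):
    """Mean periodogram ordinate with frequency in [lo, hi)."""
    freqs, p = periodogram_bruteforce(x, fs)
    sel = (freqs >= lo - 1e-12) & (freqs < hi - 1e-12)
    return float(p[sel].mean())


def moments_bruteforce(x):
    """Population mean/SD/skew/non-excess-kurtosis via scipy estimators."""
    x = np.asarray(x, float)
    sd = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if sd == 0:
        return float(x.mean()), 0.0, 0.0, 0.0
    skew = float(stats.skew(x, bias=True))
    kurt = float(stats.kurtosis(x, fisher=False, bias=True))
    return float(x.mean()), sd, skew, kurt


def zhist_bruteforce(x):
    """Fractions of z-scores in [-2,-1), [-1,0), [0,1), [1,2] (last closed)."""
    x = np.asarray(x, float)
    sd = x.std()
    if sd == 0:
        return [0.0, 0.0, 0.0, 0.0]
    z = (x - x.mean()) / sd
    n = len(x)
    return [
        float(np.sum((z >= -2) & (z < -1)) / n),
        float(np.sum((z >= -1) & (z < 0)) / n),
        float(np.sum((z >= 0) & (z < 1)) / n),
        float(np.sum((z >= 1) & (z <= 2)) / n),
    ]


def interp_bruteforce(grid, t, v):
    """Pointwise linear interpolation by segment search."""
    out = np.empty(len(grid))
    for gi, g in enumerate(grid):
        if g <= t[0]:
            out[gi] = v[0]
            continue
        if g >= t[-1]:
            out[gi] = v[-1]
            continue
        j = np.searchsorted(t, g, side="right") - 1
        w = (g - t[j]) / (t[j + 1] - t[j])
        out[gi] = v[j] * (1 - w) + v[j + 1] * w
    return out
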