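"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by brute force, exact arithmetic or an
independent numerical route, never by calling the implementation under
test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np


def fisher_exact_bruteforce(table) -> float:
    """Two-sided Fisher p by exact-fraction enumeration of all tables with
    the observed margins."""
    t = np.asarray(table, dtype=int)
    a = int(t[0, 0])
    r1, r2 = int(t[0].sum()), int(t[1].sum())
    c1 = int(t[:, 0].sum())
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(c1, r1)
    denom = comb(n, c1)
    probs = {
        k: Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def moments_threshold_bruteforce(image) -> float:
    """Moment-preserving threshold with independent numerics: the moment
    system is solved with ``linalg.solve`` + ``np.roots`` and all 256 cut
    points are searched for the closest cumulative fraction."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    hist, _ = np.histogram(img, bins=256, range=(lo, hi))
    p = hist / hist.sum()
    lev = np.arange(256.0)
    m = [1.0, (p * lev).sum(), (p * lev**2).sum(), (p * lev**3).sum()]
    A = np.array([[m[0], m[1]], [m[1], m[2]]])
    b = np.array([-m[2], -m[3]])
    c0, c1 = np.linalg.solve(A, b)
    z0, z1 = np.sort(np.roots([1.0, c1, c0]).real)
    p0 = (z1 - m[1]) / (z1 - z0) if z1 != z0 else 0.5
    csum = np.cumsum(p)[:-1]
    k = int(np.argmin(np.abs(csum - p0)))
    return lo + (hi - lo) * (k + 1) / 256.0


def isodata_fixed_points(image) -> list[float]:
    """All intermeans fixed points of the 256-bin histogram, as intensity
    values (bin centres): cuts k where the class-mean midpoint falls in
    bin k."""
    img = np.asarray(image, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    hist, _ = np.histogram(img, bins=256, range=(lo, hi))
    lev = np.arange(256.0)
    out = []
    for k in range(255):
        below, above = hist[: k + 1], hist[k + 1 :]
        if below.sum() == 0 or above.sum() == 0:
            continue
        mb = (below * lev[: k + 1]).sum() / below.sum()
        ma = (above * lev[k + 1 :]).sum() / above.sum()
        mid = 0.5 * (mb + ma)
        if k <= mid < k + 1:
            out.append(lo + (hi - lo) * (k + 0.5) / 256.0)
    return out


def random_histogram_image(rng, mode: int) -> np.ndarray:
    """Random 1-D intensity sample with a variety of histogram shapes."""
    n = int(rng.integers(800, 5000))
    if mode % 4 == 0:
        w = rng.uniform(0.2, 0.8)
        mu1 = rng.uniform(20, 90)
        mu2 = mu1 + rng.uniform(60, 150)
        img = np.concatenate(
            [
                rng.normal(mu1, rng.uniform(5, 15), int(n * w)),
                rng.normal(mu2, rng.uniform(5, 15), n - int(n * w)),
            ]
        )
    elif mode % 4 == 1:
        img = rng.gamma(2.0, 30.0, n)
    elif mode % 4 == 2:
        img = np.concatenate(
            [rng.uniform(0, 80, n), rng.normal(200, 10, n // 3)]
        )
    else:
        img = rng.normal(100, 30, n)
    return np.clip(img, 0, 255)
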