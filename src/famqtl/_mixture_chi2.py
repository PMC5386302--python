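"""Tail probabilities of positive mixtures of 1-df chi-square variables.

Score statistics of the kernel set tests are distributed as
Q ~ sum_k lambda_k chi2_1 under the null. The survival function is
approximated by Liu-Tang-Zhang moment matching in the Lee modification
(skewness matched when possible, else kurtosis), refined by the Kuonen
saddlepoint approximation in the far right tail where moment matching is
least accurate. A single-component mixture is evaluated exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = ["mixture_sf", "mixture_isf"]

def _liu_params(lam: np.ndarray):
    c1 = lam.sum()
    c2 = (lam**2).sum()
    c3 = (lam**3).sum()
    c4 = (lam**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1**2 - s2))
        d = s1 * a**3 - a**2
        l = a**2 - 2.0 * d
    else:
        l = 1.0 / s2
        d = 0.0
    mu_q, sigma_q = c1, np.sqrt(2.0 * c2)
    mu_x = l + d
    sigma_x = np.sqrt(2.0) * np.sqrt(l + 2.0 * d)
    return l, d, mu_q, sigma_q, mu_x, sigma_x


def _liu_sf(q: float, lam: np.ndarray) -> float:
    l, d, mu_q, sigma_q, mu_x, sigma_x = _liu_params(lam)
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    if d > 0:
        return float(stats.ncx2.sf(x, l, d))
    return float(stats.chi2.sf(x, l))


def _kuonen_sf(q: float, lam: np.ndarray) -> float | None:
    """Saddlepoint (Lugannani-Rice) survival probability; None on failure."""
    lmax = lam.max()

    def kprime(z):
        return np.sum(lam / (1.0 - 2.0 * z * lam))

    ub = 1.0 / (2.0 * lmax) * (1.0 - 1e-10)
    if q <= lam.sum():  # saddlepoint unreliable left of the mean
        return None
    try:
        zhat = brentq(lambda z: kprime(z) - q, 0.0, ub, xtol=1e-14)
    except ValueError:
        return None
    kz = -0.5 * np.sum(np.log1p(-2.0 * zhat * lam))
    kpp = np.sum(2.0 * lam**2 / (1.0 - 2.0 * zhat * lam) ** 2)
    w = np.sign(zhat) * np.sqrt(max(2.0 * (zhat * q - kz), 0.0))
    v = zhat * np.sqrt(kpp)
    if w == 0 or v <= 0:
        return None
    return float(stats.norm.sf(w + np.log(v / w) / w))


def mixture_sf(q: float, lam) -> float:
    """P(sum_k lam_k chi2_1 > q)."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    p = _liu_sf(q, lam)
    # the saddlepoint is uniformly more accurate right of the mean; Liu
    # moment matching covers the left half where Lugannani-Rice degenerates
    if q > lam.sum():
        ps = _kuonen_sf(q, lam)
        if ps is not None and 0.0 < ps < 1.0:
            p = ps
    return float(min(max(p, 1e-300), 1.0))


def mixture_isf(p: float, lam) -> float:
    """Quantile q with P(mixture > q) = p (Liu moment-matched inverse)."""
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 1:
        return float(lam[0] * stats.chi2.isf(p, 1))
    l, d, mu_q, sigma_q, mu_x, sigma_x = _liu_params(lam)
    x = stats.ncx2.isf(p, l, d) if d > 0 else stats.chi2.isf(p, l)
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)
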