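"""Vectorised standard bivariate-normal CDF (Genz's algorithm).

``bvn_cdf(h, k, rho)`` returns P(X <= h, Y <= k) for a standard bivariate
normal with correlation ``rho``, vectorised over ``h``/``k`` (scalar ``rho``).
Used by the generator calibration, which averages rectangle probabilities
over many maternal-shift atoms and needs thousands of CDF evaluations per
solver iteration; accuracy is ~1e-14 (Gauss-Legendre panels, with Genz's
tail transformation for |rho| > 0.925).
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = ["bvn_cdf"]

# Gauss-Legendre nodes/weights on (0, 1), 20 points
_GX, _GW = np.polynomial.legendre.leggauss(20)
_GX = (_GX + 1.0) / 2.0
_GW = _GW / 2.0


def _bvnu(h, k, r):
    """P(X > h, Y > k), vectorised over h, k; scalar r."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    if r == 0.0:
        return norm.sf(h) * norm.sf(k)
    if abs(r) < 0.925:
        hk = h * k
        hs = (h * h + k * k) / 2.0
        asr = np.arcsin(r)
        sn = np.sin(asr * _GX)                     # (q,)
        num = sn[:, None] * hk.ravel()[None, :] - hs.ravel()[None, :]
        den = 1.0 - sn[:, None] ** 2
        bvn = (_GW[:, None] * np.exp(num / den)).sum(axis=0)
        bvn = bvn.reshape(h.shape) * asr / (2.0 * np.pi)
        return bvn + norm.sf(h) * norm.sf(k)
    # |r| >= 0.925: Genz's tail branch
    sgn = 1.0 if r > 0 else -1.0
    k2 = sgn * k
    hk = h * k2
    bvn = np.zeros_like(h, dtype=float)
    if abs(r) < 1.0:
        ass = (1.0 - r) * (1.0 + r)
        a = np.sqrt(ass)
        bs = (h - k2) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr0 = -(bs / ass + hk) / 2.0
        mask = asr0 > -100.0
        bvn = np.where(
            mask,
            a * np.exp(asr0) * (1.0 - c * (bs - ass) * (1.0 - d * bs / 5.0) / 3.0
                                + c * d * ass * ass / 5.0),
            0.0)
        mask2 = -hk < 100.0
        b = np.sqrt(bs)
        with np.errstate(over="ignore", invalid="ignore"):
            sp = np.sqrt(2.0 * np.pi) * norm.sf(b / a)
            term = -np.exp(-hk / 2.0) * sp * b * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0)
        bvn = bvn + np.where(mask2 & np.isfinite(term), term, 0.0)
        xs = (a * _GX[:, None]) ** 2
        asr1 = -(bs.ravel()[None, :] / xs + hk.ravel()[None, :]) / 2.0
        rs = np.sqrt(1.0 - xs)
        sp2 = 1.0 + c.ravel()[None, :] * xs * (1.0 + d.ravel()[None, :] * xs)
        ep = np.exp(-hk.ravel()[None, :] * xs / (2.0 * (1.0 + rs) ** 2)) / rs
        inner = np.where(asr1 > -100.0, np.exp(asr1) * (ep - sp2), 0.0)
        bvn = bvn + (a * (_GW[:, None] * inner).sum(axis=0)).reshape(h.shape)
        bvn = -bvn / (2.0 * np.pi)
    if r > 0:
        return bvn + norm.sf(np.maximum(h, k2))
    return -bvn + np.where(h < k2, norm.cdf(k2) - norm.cdf(h), 0.0)


def bvn_cdf(h, k, rho):
    """P(X <= h, Y <= k) for standard bivariate normal, vectorised over h, k."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    out = _bvnu(-h, -k, float(rho))
    return np.clip(out, 0.0, 1.0)
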