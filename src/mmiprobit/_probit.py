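"""Per-observation quantities for the cumulative probit likelihood.

Each ordinal observation contributes u = log(Phi(za) - Phi(zb)) where
za = alpha_upper - eta and zb = alpha_lower - eta are the standardised
distances from the latent mean eta to the bracketing thresholds
(za = +inf at the top category, zb = -inf at the bottom).

Derivatives are expressed through the Mills-type ratios
ra = phi(za)/p and rb = phi(zb)/p, using the convention
d/d eta = -(d/d za + d/d zb):

    g   = du/d eta           = rb - ra
    w   = -d2u/d eta2        = za*ra - zb*rb + (ra - rb)^2   (> 0)
    t   = dw/d eta
    g_a = dg/d za,  g_b = dg/d zb,  w_a = dw/d za,  w_b = dw/d zb

These identities are exercised against finite differences in the tests.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

_SQRT_2PI = np.sqrt(2.0 * np.pi)
_P_FLOOR = 1e-300
#: Lower clip for the per-observation curvature w; the exact value is
#: positive for all finite inputs, the clip only guards far-tail underflow.
W_FLOOR = 1e-12


def _phi(z: np.ndarray) -> np.ndarray:
    out = np.zeros_like(z)
    finite = np.isfinite(z)
    out[finite] = np.exp(-0.5 * z[finite] ** 2) / _SQRT_2PI
    return out


def interval_prob(za: np.ndarray, zb: np.ndarray) -> np.ndarray:
    """P(zb < Z <= za) for standard normal Z, stable in both tails.

    When both bounds sit in the upper tail the difference is computed on
    the mirrored scale Phi(-zb) - Phi(-za) to avoid cancellation at 1.
    """
    za = np.asarray(za, dtype=float)
    zb = np.asarray(zb, dtype=float)
    with np.errstate(invalid="ignore"):
        flip = (za + zb) > 0
    flip = np.where(np.isnan(za + zb), False, flip)
    p = np.where(flip, ndtr(-zb) - ndtr(-za), ndtr(za) - ndtr(zb))
    return np.maximum(p, _P_FLOOR)


def interval_stats(za: np.ndarray, zb: np.ndarray, order: int = 2) -> dict[str, np.ndarray]:
    """Log-probability and eta-derivatives for threshold intervals.

    Parameters
    ----------
    za, zb
        Upper/lower standardised threshold distances (+/- inf allowed).
    order
        1 -> u, g;  2 -> + w;  3 -> + g_a, g_b, w_a, w_b, t.
    """
    p = interval_prob(za, zb)
    out: dict[str, np.ndarray] = {"p": p, "u": np.log(p)}
    ra = _phi(za) / p
    rb = _phi(zb) / p
    # finite-masked copies: every occurrence of za/zb below multiplies the
    # corresponding ratio, which is exactly 0 at an infinite bound.
    za_f = np.where(np.isfinite(za), za, 0.0)
    zb_f = np.where(np.isfinite(zb), zb, 0.0)
    out["ra"], out["rb"] = ra, rb
    out["g"] = rb - ra
    if order >= 2:
        s = ra - rb
        out["w"] = np.maximum(za_f * ra - zb_f * rb + s * s, W_FLOOR)
    if order >= 3:
        s = ra - rb
        out["g_a"] = ra * (za_f + s)
        out["g_b"] = -rb * (zb_f + s)
        out["w_a"] = ra * (1.0 - za_f**2 - za_f * ra + zb_f * rb - 2.0 * s * (za_f + s))
        out["w_b"] = rb * (-1.0 + zb_f**2 + za_f * ra - zb_f * rb + 2.0 * s * (zb_f + s))
        out["t"] = -(out["w_a"] + out["w_b"])
    return out
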