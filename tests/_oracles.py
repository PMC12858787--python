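"""Independent oracles for validating the model machinery.

Everything here is deliberately naive and separate from the package
internals: tensor-grid Gauss-Hermite quadrature for the marginal
likelihood, a loop-based joint density for posterior-mode cross-checks,
and a hand-rolled percentile rule.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, ndtr

from mmiprobit import CategoryRange, MMIDataset, Thresholds


def quad_marginal_loglik(
    dataset: MMIDataset,
    thresholds: Thresholds,
    sigma2_by_factor: dict[str, float],
    n_nodes: int = 40,
) -> float:
    """Marginal log-likelihood by dense tensor-grid Gauss-Hermite quadrature.

    Integrates the likelihood against the Gaussian prior of every
    random-effect coordinate jointly; only feasible for a handful of
    coordinates, which is exactly the regime where it serves as an oracle.
    """
    dims: list[tuple[str, int, float]] = []
    for f, s2 in sigma2_by_factor.items():
        for lvl in range(dataset.n_levels(f)):
            dims.append((f, lvl, float(np.sqrt(s2))))
    x, w = np.polynomial.hermite_e.hermegauss(n_nodes)  # weight exp(-x^2/2)
    logw = np.log(w) - 0.5 * np.log(2.0 * np.pi)
    grids = np.meshgrid(*[x] * len(dims), indexing="ij")
    logwt = sum(np.meshgrid(*[logw] * len(dims), indexing="ij"))
    ext = thresholds.extended
    cat = dataset.scores - dataset.range.lo
    eta = np.zeros(grids[0].shape + (dataset.n_records,))
    for d, (f, lvl, sd) in enumerate(dims):
        mask = dataset.codes[f] == lvl
        eta[..., mask] += (sd * grids[d])[..., None]
    p = np.maximum(ndtr(ext[cat + 1] - eta) - ndtr(ext[cat] - eta), 1e-300)
    logp = np.log(p).sum(axis=-1)
    return float(logsumexp(logp + logwt))


def naive_joint_log_density(
    dataset: MMIDataset,
    thresholds: Thresholds,
    sigma2_by_factor: dict[str, float],
    b: np.ndarray,
) -> float:
    """Loop-based joint log-density (data term + Gaussian priors)."""
    ext = thresholds.extended
    off = 0
    eta = np.zeros(dataset.n_records)
    prior = 0.0
    for f, s2 in sigma2_by_factor.items():
        nf = dataset.n_levels(f)
        bf = b[off : off + nf]
        off += nf
        for i in range(dataset.n_records):
            eta[i] += bf[dataset.codes[f][i]]
        for v in bf:
            prior += -0.5 * v * v / s2 - 0.5 * np.log(2.0 * np.pi * s2)
    total = prior
    for i, score in enumerate(dataset.scores):
        cat = score - dataset.range.lo
        p = ndtr(ext[cat + 1] - eta[i]) - ndtr(ext[cat] - eta[i])
        total += np.log(max(p, 1e-300))
    return float(total)


def quad_posterior_mode(
    dataset: MMIDataset,
    thresholds: Thresholds,
    sigma2_by_factor: dict[str, float],
) -> np.ndarray:
    """Posterior mode by an independent quasi-Newton optimisation."""
    d = sum(dataset.n_levels(f) for f in sigma2_by_factor)
    res = minimize(
        lambda b: -naive_joint_log_density(dataset, thresholds, sigma2_by_factor, b),
        np.zeros(d),
        method="BFGS",
        options={"gtol": 1e-10, "maxiter": 500},
    )
    return res.x


def random_tiny_instance(rng: np.random.Generator):
    """A random tiny crossed instance (<= 4 random-effect levels, <= 12 obs).

    Replication comes from factors outside the model (each record gets its
    own station label when station is not modelled), so levels carry
    several observations each; variance magnitudes span the range typical
    of interview-score components.
    """
    kind = rng.integers(0, 3)
    if kind == 0:
        struct = {"candidate": 2, "interviewer": 2}
    elif kind == 1:
        struct = {"candidate": int(rng.integers(2, 5))}
    else:
        struct = {"candidate": 2, "day": 2}
    K = int(rng.integers(2, 5))
    cr = CategoryRange(3, 3 + K - 1)
    alpha = np.sort(rng.uniform(-1.5, 1.5, K - 1)) + np.arange(K - 1) * 0.15
    thresholds = Thresholds(alpha)
    sigma2 = {f: float(rng.uniform(0.05, 0.6)) for f in struct}
    n_obs = int(rng.integers(6, 13))
    rows = []
    for i in range(n_obs):
        rec = {"candidate": "c0", "interviewer": "i0", "station": f"s{i}", "day": "d0"}
        for f, n_lvl in struct.items():
            rec[f] = f"{f}{rng.integers(0, n_lvl)}"
        rec["score"] = int(rng.integers(cr.lo, cr.hi + 1))
        rows.append(rec)
    df = pd.DataFrame(rows)[["candidate", "interviewer", "station", "day", "score"]]
    dataset = MMIDataset(df, cr)
    sigma2 = {f: v for f, v in sigma2.items() if dataset.n_levels(f) >= 2}
    return dataset, thresholds, sigma2


def percentile_by_hand(values: np.ndarray, q: float) -> float:
    """Linear interpolation of order statistics (classic 'linear' rule)."""
    v = np.sort(np.asarray(values, dtype=float))
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return float(v[lo] + (h - lo) * (v[hi] - v[lo]))
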