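"""Cumulative probit mixed model (CPMM) with crossed random effects.

The observed ordinal score Y of candidate i, interviewer j, station k, day t
is the discretisation of a latent Gaussian variable

    Y* = S_i + T_j + U_k + V_t + eps,     eps ~ N(0, 1),

with independent zero-mean Gaussian random effects per factor (variances
sigma2_S, sigma2_T, sigma2_U, sigma2_V) and strictly increasing thresholds
alpha such that Y = h iff alpha_{h-1} < Y* < alpha_h.  The grand mean is
absorbed into the thresholds, so reported thresholds are alpha_h - mu.  The
latent residual variance is fixed at 1 for identification, the standard
probit convention.

Fitting maximises the Laplace approximation to the marginal likelihood:
the crossed random-effect vector b is profiled out by an inner Newton
maximisation of the (strictly concave) joint log-density, with a
log-determinant curvature correction; the outer parameters (thresholds via
first-cut-point + log-increments, variances via log-sigma) are optimised by
L-BFGS-B with fully analytic gradients obtained by implicit differentiation
of the inner mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.linalg.lapack import dpotri
from scipy.optimize import minimize
from scipy.special import ndtri

from ._probit import interval_prob, interval_stats
from .data import FACTORS, CategoryRange, MMIDataset

_LOG_2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """Raised when the inner Newton solver fails; carries an iteration trace."""

    def __init__(self, message: str, trace: list[tuple[int, float, float]]):
        self.trace = trace
        lines = "\n".join(f"  iter {i}: f={f:.6f} |grad|={g:.3e}" for i, f, g in trace)
        super().__init__(f"{message}\n{lines}")


# --------------------------------------------------------------------------
# model types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Model structure: score range, random-effect factors, intercept policy.

    ``absorb_intercept`` records that the grand mean mu is fixed at zero and
    absorbed into the thresholds (the only identifiable parameterisation
    when all thresholds are free).
    """

    range: CategoryRange = CategoryRange()
    factors: tuple[str, ...] = FACTORS
    absorb_intercept: bool = True

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("at least one random-effect factor is required")
        if len(set(self.factors)) != len(self.factors):
            raise ValueError(f"duplicate factors in {self.factors}")


@dataclass(frozen=True)
class Thresholds:
    """Strictly increasing latent cut-points alpha_h between adjacent categories.

    For a range lo..hi there are hi - lo finite cut-points; the outermost
    boundaries are implicitly -inf and +inf.
    """

    alpha: np.ndarray

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        object.__setattr__(self, "alpha", alpha)
        if alpha.ndim != 1 or len(alpha) < 1:
            raise ValueError("alpha must be a 1-d vector of cut-points")
        if not np.all(np.diff(alpha) > 0):
            raise ValueError(f"thresholds must be strictly increasing, got {alpha}")

    @property
    def extended(self) -> np.ndarray:
        """Cut-points padded with -inf / +inf for category lookup."""
        return np.concatenate(([-np.inf], self.alpha, [np.inf]))


@dataclass(frozen=True)
class VarianceComponents:
    """Per-factor latent variances; residual fixed at 1 (probit identification)."""

    sigma2: dict[str, float]
    residual: float = 1.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.sigma2.values()):
            raise ValueError(f"negative variance in {self.sigma2}")
        if self.residual != 1.0:
            raise ValueError("latent residual variance is fixed at 1 in a probit model")

    @property
    def total(self) -> float:
        """Total latent variance 1 + sum of components."""
        return self.residual + sum(self.sigma2.values())


@dataclass(frozen=True)
class RandomEffectEstimates:
    """Posterior-mode (empirical Bayes) effect per registered level, by factor.

    Values are on the latent scale, in units of the residual SD.
    """

    effects: dict[str, pd.Series]

    def __getitem__(self, factor: str) -> pd.Series:
        return self.effects[factor]

    def standardised(self, total_variance: float) -> dict[str, pd.Series]:
        """Effects divided by the total latent SD sqrt(1 + sum sigma2)."""
        s = np.sqrt(total_variance)
        return {f: v / s for f, v in self.effects.items()}


@dataclass(frozen=True)
class FitOptions:
    """Optimisation controls for :func:`fit_cpmm`.

    outer_gtol: projected-gradient infinity-norm for outer convergence, on
    the working scale (first cut-point, log-increments, log-sigma).
    inner_tol: gradient infinity-norm for the inner Newton mode search.
    sigma_floor: lower bound for sigma during optimisation (log-scale box).
    boundary_zero: fitted sigma below this is reported as variance 0 with a
    boundary flag (and its predicted effects zeroed).
    """

    outer_gtol: float = 1e-5
    #: relative part of the outer tolerance: the effective tolerance is
    #: max(outer_gtol, outer_gtol_rel * |loglik|), acknowledging that the
    #: attainable gradient norm at double precision grows with |loglik|
    outer_gtol_rel: float = 1e-7
    inner_tol: float = 1e-9
    max_outer: int = 500
    max_inner: int = 100
    sigma_floor: float = 1e-6
    boundary_zero: float = 1e-3
    start_log_sigma: float = float(np.log(0.3))
    restarts: int = 2


@dataclass(frozen=True)
class FittedModel:
    spec: ModelSpec
    thresholds: Thresholds
    variances: VarianceComponents
    effects: RandomEffectEstimates
    loglik: float
    converged: bool
    n_obs: int
    n_levels: dict[str, int]
    boundary: dict[str, bool]
    grad_norm: float
    message: str = ""
    #: working-scale parameter vector, used to warm-start refits
    theta: np.ndarray = field(default=None, repr=False)
    #: factors dropped before fitting (single level)
    dropped_factors: tuple[str, ...] = ()

    @property
    def total_variance(self) -> float:
        return self.variances.total

    def standardised_effects(self) -> dict[str, pd.Series]:
        return self.effects.standardised(self.total_variance)


# --------------------------------------------------------------------------
# category probabilities and joint density
# --------------------------------------------------------------------------


def category_probability(
    score: int | np.ndarray,
    eta: float | np.ndarray,
    thresholds: Thresholds,
    score_range: CategoryRange = CategoryRange(),
) -> float | np.ndarray:
    """P(Y = score | eta) = Phi(alpha_h - eta) - Phi(alpha_{h-1} - eta).

    Summing over all scores in the range at fixed eta gives exactly 1.
    """
    score = np.asarray(score)
    if np.any((score < score_range.lo) | (score > score_range.hi)):
        raise ValueError(f"score outside range [{score_range.lo}, {score_range.hi}]")
    if len(thresholds.alpha) != score_range.n_categories - 1:
        raise ValueError(
            f"{len(thresholds.alpha)} cut-points incompatible with "
            f"{score_range.n_categories} categories"
        )
    cat = score - score_range.lo
    ext = thresholds.extended
    p = interval_prob(ext[cat + 1] - eta, ext[cat] - eta)
    return float(p) if p.ndim == 0 else p


def joint_log_density(
    dataset: MMIDataset,
    thresholds: Thresholds,
    variances: VarianceComponents,
    effects: Mapping[str, np.ndarray | pd.Series | Sequence[float]],
) -> float:
    """Log joint density of the data and a candidate random-effect vector.

    Sum over observations of the log category probability at
    eta = sum of the record's factor effects, plus the log N(0, sigma2_f)
    prior density of every effect coordinate.  Returns -inf when a factor
    has sigma2 = 0 but a nonzero effect coordinate.
    """
    factors = list(effects.keys())
    eta = np.zeros(dataset.n_records)
    prior = 0.0
    for f in factors:
        b = np.asarray(
            effects[f].to_numpy() if isinstance(effects[f], pd.Series) else effects[f],
            dtype=float,
        )
        if len(b) != dataset.n_levels(f):
            raise ValueError(
                f"effects for {f!r} have {len(b)} entries, expected {dataset.n_levels(f)}"
            )
        eta += b[dataset.codes[f]]
        s2 = variances.sigma2[f]
        if s2 == 0.0:
            if np.any(b != 0.0):
                return -np.inf
            continue
        prior += -0.5 * (b @ b / s2 + len(b) * (_LOG_2PI + np.log(s2)))
    cat = dataset.scores - dataset.range.lo
    ext = thresholds.extended
    u = np.log(interval_prob(ext[cat + 1] - eta, ext[cat] - eta))
    return float(u.sum() + prior)


# --------------------------------------------------------------------------
# design and Laplace engine
# --------------------------------------------------------------------------


class _Design:
    """Index structures for the crossed random-effect design."""

    def __init__(self, dataset: MMIDataset, factors: Sequence[str]):
        self.factors = list(factors)
        self.n = dataset.n_records
        self.n_levels = [dataset.n_levels(f) for f in self.factors]
        self.offsets = np.concatenate(([0], np.cumsum(self.n_levels)))
        self.d = int(self.offsets[-1])
        self.F = len(self.factors)
        # (n, F) global coordinate of each record's level per factor
        self.idx = np.column_stack(
            [dataset.codes[f] + self.offsets[i] for i, f in enumerate(self.factors)]
        )
        # linear indices for the dense Hessian scatter, per-obs F x F block
        self.hess_lin = (
            self.idx[:, :, None] * self.d + self.idx[:, None, :]
        ).reshape(-1)
        K = dataset.range.n_categories
        self.K = K
        self.cat = dataset.scores - dataset.range.lo
        self.has_upper = self.cat <= K - 2
        self.has_lower = self.cat >= 1
        self.upper_idx = self.cat[self.has_upper]  # cut-point index per obs
        self.lower_idx = self.cat[self.has_lower] - 1
        # factor membership of each coordinate
        self.coord_factor = np.repeat(np.arange(self.F), self.n_levels)

    def eta(self, b: np.ndarray) -> np.ndarray:
        return b[self.idx].sum(axis=1)

    def zt(self, x: np.ndarray) -> np.ndarray:
        """Z' x: scatter an n-vector onto the d coordinates."""
        return np.bincount(self.idx.ravel(), weights=np.repeat(x, self.F), minlength=self.d)

    def z(self, v: np.ndarray) -> np.ndarray:
        """Z v: per-record sum of coordinate values."""
        return v[self.idx].sum(axis=1)

    def prior_precision(self, sigma2: np.ndarray) -> np.ndarray:
        """Diagonal prior precision per coordinate from per-factor variances."""
        return (1.0 / sigma2)[self.coord_factor]


class LaplaceEngine:
    """Laplace-approximated marginal log-likelihood for one dataset/design.

    Stateful only through the warm-start mode ``b_warm``; all evaluations
    are deterministic functions of the parameters.
    """

    def __init__(self, dataset: MMIDataset, factors: Sequence[str], options: FitOptions):
        self.design = _Design(dataset, factors)
        self.options = options
        self.b_warm = np.zeros(self.design.d)

    # -- joint log-density pieces -----------------------------------------
    def _za_zb(self, alpha: np.ndarray, eta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ext = np.concatenate(([-np.inf], alpha, [np.inf]))
        cat = self.design.cat
        return ext[cat + 1] - eta, ext[cat] - eta

    def _penalised(self, alpha, sigma2, b) -> float:
        za, zb = self._za_zb(alpha, self.design.eta(b))
        u = np.log(interval_prob(za, zb))
        prior = 0.0
        for i, nf in enumerate(self.design.n_levels):
            bf = b[self.design.offsets[i] : self.design.offsets[i + 1]]
            prior += -0.5 * (bf @ bf / sigma2[i] + nf * (_LOG_2PI + np.log(sigma2[i])))
        return float(u.sum() + prior)

    # -- inner Newton ------------------------------------------------------
    def inner_mode(
        self, alpha: np.ndarray, sigma2: np.ndarray, b0: np.ndarray | None = None
    ) -> tuple[np.ndarray, tuple, dict]:
        """Maximise the joint log-density over b (strictly concave).

        Returns the mode, the Cholesky factor of the negative Hessian H,
        and the per-observation link statistics at the mode.
        """
        des = self.design
        opt = self.options
        prec = des.prior_precision(sigma2)
        b = self.b_warm.copy() if b0 is None else np.asarray(b0, dtype=float).copy()
        f = self._penalised(alpha, sigma2, b)
        if not np.isfinite(f):
            b = np.zeros(des.d)
            f = self._penalised(alpha, sigma2, b)
        trace: list[tuple[int, float, float]] = []
        chol = None
        st: dict = {}
        for it in range(opt.max_inner):
            za, zb = self._za_zb(alpha, des.eta(b))
            st = interval_stats(za, zb, order=2)
            grad = des.zt(st["g"]) - prec * b
            gnorm = float(np.max(np.abs(grad))) if des.d else 0.0
            # gradient tolerance relative to the objective magnitude: near
            # the optimum float rounding of f caps attainable accuracy
            tol_eff = opt.inner_tol * max(1.0, abs(f))
            trace.append((it, f, gnorm))
            H = np.bincount(
                des.hess_lin,
                weights=np.repeat(st["w"], des.F * des.F),
                minlength=des.d * des.d,
            ).reshape(des.d, des.d)
            H[np.diag_indices_from(H)] += prec
            chol = cho_factor(H, lower=True)
            if gnorm <= tol_eff:
                break
            step = cho_solve(chol, grad)
            # backtracking line search on the concave objective
            t, f_new = 1.0, -np.inf
            g_dot_s = float(grad @ step)
            searched = False
            for _ in range(40):
                f_new = self._penalised(alpha, sigma2, b + t * step)
                if f_new >= f + 1e-4 * t * g_dot_s or abs(f_new - f) < 1e-14:
                    searched = True
                    break
                t *= 0.5
            if not searched:
                # no step registers an improvement at float resolution
                break
            stagnant = abs(f_new - f) <= 1e-13 * max(1.0, abs(f))
            b = b + t * step
            f = f_new
            if stagnant:
                # at the numerical optimum; floating error blocks progress
                break
        # a residual gradient that is material relative to the objective
        # means genuine non-convergence, not float saturation
        if gnorm > 1e-3 * max(1.0, abs(f)):
            raise ConvergenceError("inner Newton did not converge", trace)
        self.b_warm = b.copy()
        return b, chol, st

    # -- Laplace value and analytic gradient -------------------------------
    def value(self, alpha: np.ndarray, sigma2: np.ndarray, b0=None) -> tuple[float, np.ndarray]:
        """Laplace marginal log-likelihood and the inner mode."""
        b, chol, _ = self.inner_mode(alpha, sigma2, b0=b0)
        f = self._penalised(alpha, sigma2, b)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        return f + 0.5 * self.design.d * _LOG_2PI - 0.5 * logdet, b

    def value_and_grad(
        self, alpha: np.ndarray, sigma2: np.ndarray
    ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
        """Laplace log-likelihood, d/d alpha, d/d log sigma, and the mode.

        The gradient accounts for the direct parameter dependence, the
        log-determinant term, and the movement of the inner mode (implicit
        differentiation; third derivatives of the link enter through t).
        """
        des = self.design
        b, chol, _ = self.inner_mode(alpha, sigma2)
        za, zb = self._za_zb(alpha, des.eta(b))
        st = interval_stats(za, zb, order=3)
        f = self._penalised(alpha, sigma2, b)
        logdet = 2.0 * float(np.sum(np.log(np.diag(chol[0]))))
        value = f + 0.5 * des.d * _LOG_2PI - 0.5 * logdet

        Hinv = _chol_inverse(chol)
        # c_o = z_o' Hinv z_o over the F nonzeros of each record row
        c = np.zeros(des.n)
        for p in range(des.F):
            for q in range(des.F):
                c += Hinv[des.idx[:, p], des.idx[:, q]]
        v = des.zt(st["t"] * c)
        vt = Hinv @ v
        Zvt = des.z(vt)

        ncut = des.K - 1
        hu, hl = des.has_upper, des.has_lower
        iu, il = des.upper_idx, des.lower_idx

        def cut_sum(weights_u, weights_l):
            return np.bincount(iu, weights=weights_u[hu], minlength=ncut) + np.bincount(
                il, weights=weights_l[hl], minlength=ncut
            )

        d_direct = cut_sum(st["ra"], -st["rb"])
        d_trace = cut_sum(c * st["w_a"], c * st["w_b"])
        d_indirect = cut_sum(Zvt * st["g_a"], Zvt * st["g_b"])
        d_alpha = d_direct - 0.5 * (d_trace + d_indirect)

        d_logsig = np.zeros(des.F)
        diagH = np.diag(Hinv)
        for i in range(des.F):
            sl = slice(des.offsets[i], des.offsets[i + 1])
            bf = b[sl]
            s2 = sigma2[i]
            d_f = bf @ bf / s2 - des.n_levels[i]
            tr = -2.0 / s2 * float(np.sum(diagH[sl]))
            ind = 2.0 / s2 * float(vt[sl] @ bf)
            d_logsig[i] = d_f - 0.5 * (tr + ind)
        return value, d_alpha, d_logsig, b


def _chol_inverse(chol) -> np.ndarray:
    """Full symmetric inverse from a Cholesky factorisation (LAPACK dpotri)."""
    c, lower = chol
    tri, info = dpotri(c, lower=lower)
    if info != 0:
        return cho_solve(chol, np.eye(c.shape[0]))
    if lower:  # the opposite triangle holds leftovers of the factor
        return np.tril(tri) + np.tril(tri, -1).T
    return np.triu(tri) + np.triu(tri, 1).T


# --------------------------------------------------------------------------
# public fitting API
# --------------------------------------------------------------------------


def laplace_marginal_loglik(
    dataset: MMIDataset,
    thresholds: Thresholds,
    variances: VarianceComponents,
    factors: Sequence[str] | None = None,
    options: FitOptions = FitOptions(),
) -> tuple[float, RandomEffectEstimates]:
    """Laplace approximation to the marginal log-likelihood at fixed parameters.

    Returns the approximate log integral of the joint density over the
    random effects, and the inner-mode effect predictions.  Requires
    sigma2 > 0 for every active factor.
    """
    factors = list(factors) if factors is not None else [
        f for f in variances.sigma2 if dataset.n_levels(f) >= 1
    ]
    sigma2 = np.array([variances.sigma2[f] for f in factors], dtype=float)
    if np.any(sigma2 <= 0):
        raise ValueError("laplace_marginal_loglik requires sigma2 > 0 for active factors")
    engine = LaplaceEngine(dataset, factors, options)
    value, b = engine.value(thresholds.alpha, sigma2, b0=np.zeros(engine.design.d))
    return value, _effects_from_vector(b, engine.design, dataset)


def _effects_from_vector(
    b: np.ndarray, design: _Design, dataset: MMIDataset
) -> RandomEffectEstimates:
    eff = {}
    for i, f in enumerate(design.factors):
        sl = slice(design.offsets[i], design.offsets[i + 1])
        eff[f] = pd.Series(b[sl].copy(), index=dataset.levels[f], name=f)
    return RandomEffectEstimates(eff)


def _start_thresholds(dataset: MMIDataset) -> np.ndarray:
    """Phi-inverse of the (clipped) empirical cumulative score distribution."""
    K = dataset.range.n_categories
    counts = np.bincount(dataset.scores - dataset.range.lo, minlength=K)
    n = counts.sum()
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 0.5 / n, 1 - 0.5 / n)
    alpha = ndtri(cum)
    # unobserved categories give tied cut-points; force a small minimum gap
    for m in range(1, len(alpha)):
        alpha[m] = max(alpha[m], alpha[m - 1] + 0.05)
    return alpha


def _pack(alpha: np.ndarray, log_sigma: np.ndarray) -> np.ndarray:
    return np.concatenate(([alpha[0]], np.log(np.diff(alpha)), log_sigma))


def _unpack(theta: np.ndarray, ncut: int) -> tuple[np.ndarray, np.ndarray]:
    alpha = theta[0] + np.concatenate(([0.0], np.cumsum(np.exp(theta[1:ncut]))))
    return alpha, theta[ncut:]


def fit_cpmm(
    dataset: MMIDataset,
    spec: ModelSpec | None = None,
    options: FitOptions = FitOptions(),
    start: FittedModel | np.ndarray | None = None,
) -> FittedModel:
    """Fit the CPMM by maximising the Laplace marginal log-likelihood.

    Thresholds are optimised through an unconstrained first-cut-point +
    log-increment parameterisation (strict monotonicity by construction);
    variances through log-sigma with a floor.  Factors with a single level
    are dropped with a warning.  The fit is deterministic given the data,
    spec, options, and starting values.

    Parameters
    ----------
    start
        Optional warm start: a previous :class:`FittedModel` on a
        structurally identical problem, or a raw working-scale vector.
    """
    spec = spec if spec is not None else ModelSpec(range=dataset.range)
    if spec.range != dataset.range:
        raise ValueError("spec.range disagrees with dataset.range")
    if len(np.unique(dataset.scores)) < 2:
        raise ValueError("all scores fall in one category; the model is not identified")
    if dataset.n_levels("candidate") < 2:
        raise ValueError("need at least 2 candidates")

    factors = []
    dropped = []
    for f in spec.factors:
        if dataset.n_levels(f) >= 2:
            factors.append(f)
        else:
            dropped.append(f)
            warnings.warn(f"factor {f!r} has a single level and was dropped", stacklevel=2)
    if not factors:
        raise ValueError("no factor has 2 or more levels")

    engine = LaplaceEngine(dataset, factors, options)
    ncut = dataset.range.n_categories - 1
    F = len(factors)

    if start is None:
        theta0 = _pack(_start_thresholds(dataset), np.full(F, options.start_log_sigma))
    elif isinstance(start, FittedModel):
        theta0 = np.asarray(start.theta, dtype=float).copy()
        if len(theta0) != ncut + F:
            raise ValueError("warm-start parameter vector has the wrong length")
    else:
        theta0 = np.asarray(start, dtype=float).copy()

    lo_s = np.log(options.sigma_floor)
    bounds = (
        [(-30.0, 30.0)]
        + [(-12.0, 5.0)] * (ncut - 1)
        + [(lo_s, np.log(30.0))] * F
    )
    theta0 = np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds])

    def negloglik(theta: np.ndarray) -> tuple[float, np.ndarray]:
        alpha, log_sigma = _unpack(theta, ncut)
        sigma2 = np.exp(2.0 * log_sigma)
        value, d_alpha, d_logsig, _ = engine.value_and_grad(alpha, sigma2)
        # chain rule to (alpha_1, log-increments)
        tail = np.cumsum(d_alpha[::-1])[::-1]
        g = np.concatenate(([tail[0]], np.exp(theta[1:ncut]) * tail[1:], d_logsig))
        return -value, -g

    res = None
    theta = theta0
    message = ""
    # the L-BFGS stopping tolerance mirrors the scale-aware convergence
    # criterion; |loglik| is estimated from the starting point
    f0, _ = negloglik(theta0)
    gtol_eff = max(options.outer_gtol, options.outer_gtol_rel * abs(float(f0)))
    for attempt in range(options.restarts + 1):
        res = minimize(
            negloglik,
            theta,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": options.max_outer,
                "gtol": gtol_eff,
                "ftol": 1e-13,
                "maxcor": 25,
            },
        )
        theta = res.x
        message = str(res.message)
        gtol_eff = max(options.outer_gtol, options.outer_gtol_rel * abs(float(res.fun)))
        if _projected_gnorm(res.x, -res.jac, bounds) <= gtol_eff:
            break

    nll, grad = negloglik(theta)
    gnorm = _projected_gnorm(theta, -grad, bounds)
    gtol_eff = max(options.outer_gtol, options.outer_gtol_rel * abs(float(nll)))
    converged = bool(gnorm <= gtol_eff)

    alpha, log_sigma = _unpack(theta, ncut)
    sigma_hat = np.exp(log_sigma)
    sigma2_hat = sigma_hat**2
    loglik, b_mode = engine.value(alpha, sigma2_hat)

    boundary = {f: bool(sigma_hat[i] < options.boundary_zero) for i, f in enumerate(factors)}
    sigma2_rep = {
        f: (0.0 if boundary[f] else float(sigma2_hat[i])) for i, f in enumerate(factors)
    }
    effects = _effects_from_vector(b_mode, engine.design, dataset)
    for f in factors:
        if boundary[f]:
            effects.effects[f][:] = 0.0

    return FittedModel(
        spec=spec,
        thresholds=Thresholds(alpha),
        variances=VarianceComponents(sigma2_rep),
        effects=effects,
        loglik=float(loglik),
        converged=converged,
        n_obs=dataset.n_records,
        n_levels={f: dataset.n_levels(f) for f in factors},
        boundary=boundary,
        grad_norm=float(gnorm),
        message=message,
        theta=theta.copy(),
        dropped_factors=tuple(dropped),
    )


def _projected_gnorm(theta: np.ndarray, grad: np.ndarray, bounds) -> float:
    """Infinity-norm of the gradient projected onto the feasible box."""
    g = np.asarray(grad, dtype=float).copy()
    for i, (lo, hi) in enumerate(bounds):
        if theta[i] <= lo and g[i] < 0:  # ascent direction points outside the box
            g[i] = 0.0
        if theta[i] >= hi and g[i] > 0:
            g[i] = 0.0
    return float(np.max(np.abs(g)))


def predict_random_effects(model: FittedModel, dataset: MMIDataset) -> RandomEffectEstimates:
    """Empirical-Bayes (inner posterior mode) effects for every level.

    Effects shrink toward zero: for each factor the spread of the
    predictions does not exceed the fitted variance.  Levels present in the
    model but absent from the dataset are an error.
    """
    factors = [f for f in model.spec.factors if f not in model.dropped_factors]
    for f in factors:
        missing = set(model.effects[f].index) - set(dataset.levels[f])
        if missing:
            raise ValueError(f"levels {sorted(missing)} of {f!r} absent from dataset")
    active = [f for f in factors if not model.boundary[f]]
    if not active:
        return RandomEffectEstimates(
            {f: pd.Series(0.0, index=dataset.levels[f], name=f) for f in factors}
        )
    opts = FitOptions()
    engine = LaplaceEngine(dataset, active, opts)
    sigma2 = np.array([model.variances.sigma2[f] for f in active])
    b, _, _ = engine.inner_mode(model.thresholds.alpha, sigma2, b0=np.zeros(engine.design.d))
    est = _effects_from_vector(b, engine.design, dataset)
    out = dict(est.effects)
    for f in factors:
        if model.boundary[f]:
            out[f] = pd.Series(0.0, index=dataset.levels[f], name=f)
    return RandomEffectEstimates(out)
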