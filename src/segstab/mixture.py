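"""Two-component mixture models for per-gene log-expression.

The expression of a gene across single cells is modelled on the
log2(x + 1) scale as a two-component mixture

    f(x) = lambda * Gamma(x; alpha, beta) + (1 - lambda) * N(x; mu, sigma2)

where the Gamma component captures the low end of the distribution
(lowly expressed / dropout-adjacent cells) and the Gaussian component the
cells that express the gene.  ``lambda`` is the mixing proportion: the
fraction of cells attributed to the Gamma component.  A competing
Gamma + Gamma family is available; the two are compared by BIC.

Both fits are deterministic: initialisation splits the values at the 25th
percentile, the low part seeding the Gamma component by method of moments
and the high part the second component.  The EM log-likelihood is tracked
per iteration and is non-decreasing up to floating-point noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import gamma as gamma_dist

__all__ = [
    "EMConfig",
    "MixtureFit",
    "FamilySelection",
    "DegenerateInputError",
    "FitFailureError",
    "fit_gamma_gaussian",
    "fit_gamma_gamma",
    "select_family",
]

GAMMA_GAUSSIAN = "gamma_gaussian"
GAMMA_GAMMA = "gamma_gamma"

# free parameters per family: lambda plus two per component
_N_PARAMS = 5


class DegenerateInputError(ValueError):
    """Too few points or too little variation to fit a mixture."""


class FitFailureError(RuntimeError):
    """EM produced a non-finite likelihood; carries the last valid state."""

    def __init__(self, message: str, last_state: "MixtureFit | None" = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class EMConfig:
    """EM control parameters.

    tol is the relative log-likelihood change declaring convergence;
    sigma2_floor and gamma_floor prevent component collapse.
    """

    tol: float = 1e-8
    max_iter: int = 1000
    min_points: int = 20
    sigma2_floor: float = 1e-6
    gamma_floor: float = 1e-4
    # Parsimony guard: a two-component mixture can split a genuinely
    # unimodal sample (the Gamma mimicking the lower shoulder of the
    # Gaussian) with a spurious lambda around 0.3-0.4.  When the
    # single-component fit has the lower BIC, the lambda -> 0 limit is
    # returned instead so unimodal genes read as such.
    collapse_unimodal: bool = True


@dataclass
class MixtureFit:
    """A fitted two-component mixture for one gene.

    For the gamma_gaussian family, (alpha, beta) parameterise the Gamma
    (shape, rate) and (mu, sigma2) the Gaussian.  For gamma_gamma the
    second component's shape/rate are stored as (alpha2, beta2) and
    mu/sigma2 hold that component's implied mean alpha2/beta2 and
    variance alpha2/beta2**2 for feature extraction.
    """

    family: str
    lambda_: float
    alpha: float
    beta: float
    mu: float
    sigma2: float
    loglik: float
    n_points: int
    bic: float
    converged: bool
    n_iter: int
    alpha2: float | None = None
    beta2: float | None = None
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0), repr=False)


def _check_values(values: np.ndarray, config: EMConfig) -> np.ndarray:
    values = np.asarray(values, dtype=float).ravel()
    if values.size < config.min_points:
        raise DegenerateInputError(
            f"{values.size} points < min_points={config.min_points}"
        )
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise DegenerateInputError("values must be finite and strictly positive")
    if np.unique(values).size < 3:
        raise DegenerateInputError("need at least 3 distinct values")
    return values


def _gamma_logpdf(x: np.ndarray, lnx: np.ndarray, shape: float, rate: float) -> np.ndarray:
    return shape * np.log(rate) - gammaln(shape) + (shape - 1.0) * lnx - rate * x


def _normal_logpdf(x: np.ndarray, mu: float, sigma2: float) -> np.ndarray:
    return -0.5 * (np.log(2.0 * np.pi * sigma2) + (x - mu) ** 2 / sigma2)


def _gamma_moments(x: np.ndarray, floor: float) -> tuple[float, float]:
    """Method-of-moments (shape, rate) with flooring."""
    m = float(np.mean(x))
    v = float(np.var(x))
    if v <= 0 or m <= 0:
        return max(1.0, floor), max(1.0 / max(m, floor), floor)
    return max(m * m / v, floor), max(m / v, floor)


def _gamma_weighted_mle(
    x: np.ndarray, lnx: np.ndarray, w: np.ndarray, floor: float
) -> tuple[float, float]:
    """Weighted Gamma MLE: Newton iteration on the shape via digamma.

    Solves ln(a) - psi(a) = ln(wmean(x)) - wmean(ln x); the rate follows
    from the weighted-mean identity beta = alpha / wmean(x).
    """
    wsum = float(w.sum())
    if wsum <= 1e-12:
        return max(1.0, floor), max(1.0, floor)
    xbar = float(w @ x) / wsum
    lnbar = float(w @ lnx) / wsum
    s = np.log(xbar) - lnbar
    if not np.isfinite(s) or s <= 1e-10:
        # (near-)degenerate weighted sample: huge shape, tight around xbar
        a = 1e6
        return a, a / max(xbar, floor)
    a = (3.0 - s + np.sqrt((s - 3.0) ** 2 + 24.0 * s)) / (12.0 * s)
    a = min(max(a, floor), 1e6)
    for _ in range(25):
        f = np.log(a) - digamma(a) - s
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        a_new = min(max(a_new, floor), 1e6)
        if abs(a_new - a) < 1e-10 * a:
            a = a_new
            break
        a = a_new
    b = max(a / xbar, floor)
    return a, b


def _em(
    values: np.ndarray, family: str, config: EMConfig
) -> MixtureFit:
    x = values
    lnx = np.log(x)
    n = x.size

    # deterministic initialisation: split at the 25th percentile
    q = np.quantile(x, 0.25)
    low = x <= q
    if low.sum() < 2:
        low = x <= np.sort(x)[1]
    high = ~low
    if high.sum() < 2:
        high = x >= np.sort(x)[-2]
    lam = float(np.clip(low.mean(), 0.05, 0.95))
    a1, b1 = _gamma_moments(x[low], config.gamma_floor)
    if family == GAMMA_GAUSSIAN:
        mu = float(np.mean(x[high]))
        sigma2 = max(float(np.var(x[high])), config.sigma2_floor)
        a2 = b2 = None
    else:
        a2, b2 = _gamma_moments(x[high], config.gamma_floor)
        mu = sigma2 = None

    loglik = -np.inf
    trace = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        lam_c = min(max(lam, 1e-12), 1.0 - 1e-12)
        log1 = np.log(lam_c) + _gamma_logpdf(x, lnx, a1, b1)
        if family == GAMMA_GAUSSIAN:
            log2 = np.log1p(-lam_c) + _normal_logpdf(x, mu, sigma2)
        else:
            log2 = np.log1p(-lam_c) + _gamma_logpdf(x, lnx, a2, b2)
        m = np.maximum(log1, log2)
        lse = m + np.log(np.exp(log1 - m) + np.exp(log2 - m))
        new_loglik = float(lse.sum())
        if not np.isfinite(new_loglik):
            raise FitFailureError(
                "non-finite likelihood during EM",
                last_state=_pack(family, lam, a1, b1, mu, sigma2, a2, b2,
                                 loglik, n, False, it, trace),
            )
        trace.append(new_loglik)
        rel = abs(new_loglik - loglik) / max(1.0, abs(new_loglik))
        loglik = new_loglik
        if rel < config.tol:
            converged = True
            break

        # E-step responsibilities for the first (Gamma) component
        r1 = np.exp(log1 - lse)
        # M-step
        lam = float(np.clip(r1.mean(), 0.0, 1.0))
        a1, b1 = _gamma_weighted_mle(x, lnx, r1, config.gamma_floor)
        r2 = 1.0 - r1
        w2 = float(r2.sum())
        if family == GAMMA_GAUSSIAN:
            if w2 > 1e-12:
                mu = float(r2 @ x) / w2
                sigma2 = max(float(r2 @ (x - mu) ** 2) / w2, config.sigma2_floor)
        else:
            a2, b2 = _gamma_weighted_mle(x, lnx, r2, config.gamma_floor)

    fit = _pack(family, lam, a1, b1, mu, sigma2, a2, b2, loglik, n,
                converged, it, trace)
    if config.collapse_unimodal:
        fit = _maybe_collapse(x, fit, config)
    return fit


def _maybe_collapse(x: np.ndarray, fit: MixtureFit, config: EMConfig) -> MixtureFit:
    """Return the lambda -> 0 limit when one component suffices by BIC."""
    n = x.size
    if fit.family == GAMMA_GAUSSIAN:
        mu = float(np.mean(x))
        sigma2 = max(float(np.var(x)), config.sigma2_floor)
        ll_single = float(_normal_logpdf(x, mu, sigma2).sum())
        single = dict(mu=mu, sigma2=sigma2)
    else:
        shape, _, scale = gamma_dist.fit(x, floc=0)
        ll_single = float(gamma_dist.logpdf(x, shape, scale=scale).sum())
        single = dict(alpha2=shape, beta2=1.0 / scale,
                      mu=shape * scale, sigma2=shape * scale**2)
    # mixture BIC uses k=5; the one-component alternative uses k=2
    if 2.0 * np.log(n) - 2.0 * ll_single >= fit.bic:
        return fit
    return MixtureFit(
        family=fit.family,
        lambda_=0.0,
        alpha=fit.alpha,
        beta=fit.beta,
        mu=single["mu"],
        sigma2=single["sigma2"],
        alpha2=single.get("alpha2", fit.alpha2),
        beta2=single.get("beta2", fit.beta2),
        loglik=ll_single,
        n_points=n,
        bic=_N_PARAMS * np.log(n) - 2.0 * ll_single,
        converged=True,
        n_iter=fit.n_iter,
        loglik_trace=fit.loglik_trace,
    )


def _pack(family, lam, a1, b1, mu, sigma2, a2, b2, loglik, n, converged, it, trace):
    if family == GAMMA_GAMMA:
        # order components by mean so the first is the low end
        m1, m2 = a1 / b1, a2 / b2
        if m1 > m2:
            a1, b1, a2, b2 = a2, b2, a1, b1
            lam = 1.0 - lam
        mu = a2 / b2
        sigma2 = a2 / b2**2
    bic = _N_PARAMS * np.log(n) - 2.0 * loglik
    return MixtureFit(
        family=family,
        lambda_=float(lam),
        alpha=float(a1),
        beta=float(b1),
        mu=float(mu),
        sigma2=float(sigma2),
        alpha2=None if a2 is None else float(a2),
        beta2=None if b2 is None else float(b2),
        loglik=float(loglik),
        n_points=int(n),
        bic=float(bic),
        converged=bool(converged),
        n_iter=int(it),
        loglik_trace=np.asarray(trace),
    )


def fit_gamma_gaussian(values, config: EMConfig | None = None) -> MixtureFit:
    """Fit the Gamma + Gaussian mixture to strictly positive log values.

    Zeros are handled upstream (summarised by the zero-fraction feature);
    the mixture describes the positive part of the distribution only.
    """
    config = config or EMConfig()
    values = _check_values(np.asarray(values), config)
    return _em(values, GAMMA_GAUSSIAN, config)


def fit_gamma_gamma(values, config: EMConfig | None = None) -> MixtureFit:
    """Fit the competing Gamma + Gamma mixture (both components Gamma)."""
    config = config or EMConfig()
    values = _check_values(np.asarray(values), config)
    return _em(values, GAMMA_GAMMA, config)


@dataclass
class FamilySelection:
    family: str
    fits: dict


def select_family(values, config: EMConfig | None = None) -> FamilySelection:
    """Choose between the two mixture families by BIC (smaller wins).

    Ties within 1e-9 resolve to gamma_gaussian.  If one family fails to
    fit, the other is returned with a warning; if both fail the error of
    the Gamma-Gaussian fit propagates.
    """
    config = config or EMConfig()
    fits: dict[str, MixtureFit] = {}
    errors: dict[str, Exception] = {}
    for name, fn in ((GAMMA_GAUSSIAN, fit_gamma_gaussian), (GAMMA_GAMMA, fit_gamma_gamma)):
        try:
            fits[name] = fn(values, config)
        except (DegenerateInputError, FitFailureError) as exc:
            errors[name] = exc
    if not fits:
        raise FitFailureError(f"both mixture families failed: {errors}")
    if len(fits) == 1:
        (name,) = fits
        warnings.warn(f"only the {name} family could be fitted ({errors})")
        return FamilySelection(family=name, fits=fits)
    d = fits[GAMMA_GAUSSIAN].bic - fits[GAMMA_GAMMA].bic
    family = GAMMA_GAUSSIAN if (abs(d) < 1e-9 or d < 0) else GAMMA_GAMMA
    return FamilySelection(family=family, fits=fits)


def single_gamma_loglik(values) -> float:
    """Maximum log-likelihood of a single Gamma fit (nesting reference)."""
    x = np.asarray(values, dtype=float).ravel()
    shape, loc, scale = gamma_dist.fit(x, floc=0)
    return float(gamma_dist.logpdf(x, shape, loc=loc, scale=scale).sum())
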