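"""Maximum-likelihood inference of droplet-formation parameters.

The classifier observes, for each sample ``l``, the number ``z_l`` of GEMs
containing cells from ``l``.  Under the formation model, the number of
``l``-cell-enclosing droplets is Binomial(``X``, ``p_l``) with
``p_l = 1 - (1 - 1/X)^{y_l}``, of which a fraction ``r_cap`` is captured;
``z_l / r_cap`` is therefore treated as the (generally non-integer)
binomial draw and scored with the Gamma-function extension of the binomial
pmf.  The latent parameters ``(X, r_cap, y_1..y_M)`` are the constrained
maximizer of the product likelihood over samples, subject to
``sum_l y_l = Y`` with ``Y`` supplied by the user (hemocytometer count).

With ``M`` observations and ``M + 1`` free parameters the per-sample
likelihood alone is unidentified along a ridge trading ``X`` against
``r_cap`` (every ``X`` on a wide range fits the ``z_l`` exactly).  The
estimator therefore anchors the joint fit, by default, on one more
classifier observable: the total number of cell-enclosing GEMs, whose
expectation is ``r_cap * X * (1 - (1 - 1/X)^Y)``.  Alternatively, pass
``fix_X`` with a profiled equipment value to pin the droplet count, and
use :func:`profile_likelihood_X` to inspect the ridge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln

from .formation import FormationParams, ObservedCounts

__all__ = [
    "EstimateResult",
    "log_likelihood",
    "anchored_log_likelihood",
    "estimate_params",
    "profile_likelihood_X",
]


def _log_binom_pmf(k, X: float, p):
    """Continuous-binomial log pmf via the Gamma extension.

    The coefficient is evaluated as ``-log(X+1) - betaln(X-k+1, k+1)``,
    which stays accurate for very large ``X`` where differencing
    ``gammaln`` terms loses all precision.
    """
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    coeff = -np.log(X + 1.0) - betaln(X - k + 1.0, k + 1.0)
    return coeff + k * np.log(p) + (X - k) * np.log1p(-p)


def log_likelihood(params: FormationParams, observed: ObservedCounts) -> float:
    """Log-likelihood of per-sample cell-enclosing GEM counts.

    Sum over samples of the continuous-binomial log pmf at
    ``k_l = z_l / r_cap`` with ``X`` trials and success probability
    ``p_l = 1 - (1 - 1/X)^{y_l}``.  Returns ``-inf`` outside the support
    (``k_l > X``) and raises if the capture rate is zero.
    """
    if params.r_cap <= 0:
        raise ValueError("r_cap must be positive to scale observed counts")
    if observed.M != params.M:
        raise ValueError(
            f"observation/sample mismatch: {observed.M} vs {params.M}"
        )
    X = params.X
    z = np.asarray(observed.z, dtype=float)
    k = z / params.r_cap
    if np.any(k > X):
        return -np.inf
    y = np.asarray(params.y, dtype=float)
    log_q = np.log1p(-1.0 / X)  # log(1 - 1/X)
    p = -np.expm1(y * log_q)  # 1 - (1-1/X)^y_l
    if np.any((p <= 0) | (p >= 1)):
        return -np.inf
    return float(_log_binom_pmf(k, X, p).sum())


def anchored_log_likelihood(params: FormationParams, observed: ObservedCounts) -> float:
    """Per-sample likelihood plus the total-GEM-count anchor term.

    The number of captured cell-enclosing GEMs is ``r_cap`` times a
    Binomial(``X``, ``1 - (1 - 1/X)^Y``) draw; scoring ``n_gems / r_cap``
    against that distribution supplies the extra observation that makes
    the joint ``(X, r_cap, y)`` problem identified.
    """
    ll = log_likelihood(params, observed)
    if observed.n_gems is None or not np.isfinite(ll):
        return ll
    X = params.X
    k0 = observed.n_gems / params.r_cap
    if k0 > X:
        return -np.inf
    p0 = -np.expm1(params.Y * np.log1p(-1.0 / X))
    if not 0.0 < p0 < 1.0:
        return -np.inf
    return ll + float(_log_binom_pmf(k0, X, p0))


@dataclass
class EstimateResult:
    """Outcome of the constrained maximum-likelihood fit."""

    params: FormationParams
    log_likelihood: float
    n_starts: int
    converged: bool
    X_fixed: bool
    profile: list[tuple[float, float]] = field(default_factory=list)  # (X, ll)


def _unpack(theta: np.ndarray, Y: float, M: int, fix_X: float | None):
    i = 0
    if fix_X is None:
        X = float(np.exp(theta[i]))
        i += 1
    else:
        X = float(fix_X)
    r_cap = float(1.0 / (1.0 + np.exp(-theta[i])))
    i += 1
    if M > 1:
        a = np.concatenate([theta[i:], [0.0]])
        a = a - a.max()
        w = np.exp(a)
        y = Y * w / w.sum()
    else:
        y = np.array([Y])
    return X, r_cap, y


def estimate_params(
    observed: ObservedCounts,
    Y: float,
    fix_X: float | None = None,
    seed: int | None = 0,
    n_starts: int = 12,
    profile: bool = False,
) -> EstimateResult:
    """Constrained MLE of ``(X, r_cap, y_1..y_M)`` from observed counts.

    The simplex constraint ``sum y_l = Y`` is enforced by a softmax
    reparameterization and ``X``/``r_cap`` by log/logit transforms, so the
    search is unconstrained; Nelder-Mead is run from ``n_starts`` seeded
    starting points spanning ``X`` in ``[max_l z_l, 10 Y]`` (scaled by the
    start's capture rate) and ``r_cap`` in ``[0.05, 1]``, and the best
    optimum is polished.  Set ``profile=True`` to also record the profile
    log-likelihood over a grid of pinned ``X`` values.
    """
    if Y <= 0:
        raise ValueError("total cell count Y must be positive")
    M = observed.M
    z = np.asarray(observed.z, dtype=float)
    if not np.any(z >= 1):
        raise ValueError("need at least one sample with an observed GEM count")
    if fix_X is not None and fix_X < z.max():
        raise ValueError("fix_X is below the largest observed count")
    rng = np.random.default_rng(seed)
    # the anchor is redundant (and the problem identified) once X is pinned
    score = anchored_log_likelihood if fix_X is None else log_likelihood

    def objective(theta: np.ndarray) -> float:
        X, r_cap, y = _unpack(theta, Y, M, fix_X)
        if r_cap < 1e-6 or np.any(y <= 0):
            return 1e300
        try:
            ll = score(FormationParams(X=X, r_cap=r_cap, y=tuple(y)), observed)
        except ValueError:
            return 1e300
        if not np.isfinite(ll):
            return 1e300
        return -ll

    zfrac = np.maximum(z, 0.5) / max(z.sum(), 1.0)
    best: tuple[float, np.ndarray] | None = None
    for s in range(n_starts):
        r0 = rng.uniform(0.05, 1.0) if s else min(0.9, max(0.1, z.sum() / Y))
        theta0 = []
        if fix_X is None:
            x_lo = max(z.max() / r0, 1.5 * z.max())
            x_hi = 10.0 * Y
            X0 = np.exp(rng.uniform(np.log(x_lo), np.log(max(x_hi, x_lo * 1.1))))
            theta0.append(np.log(X0))
        theta0.append(np.log(r0 / (1.0 - r0 + 1e-12)))
        if M > 1:
            a0 = np.log(zfrac[:-1] / zfrac[-1]) + rng.normal(0, 0.05, M - 1)
            theta0.extend(a0)
        res = minimize(
            objective,
            np.array(theta0),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
        )
        if best is None or res.fun < best[0]:
            best = (res.fun, res.x)
    assert best is not None
    # polish the winner
    res = minimize(
        objective,
        best[1],
        method="Nelder-Mead",
        options={"maxiter": 8000, "xatol": 1e-10, "fatol": 1e-12},
    )
    if res.fun > best[0]:
        res_x, res_fun = best[1], best[0]
    else:
        res_x, res_fun = res.x, res.fun
    X, r_cap, y = _unpack(res_x, Y, M, fix_X)
    params = FormationParams(X=X, r_cap=r_cap, y=tuple(y))

    prof: list[tuple[float, float]] = []
    if profile and fix_X is None:
        for Xg in np.geomspace(max(z.max() * 1.2, 10.0), 10.0 * Y, 15):
            sub = estimate_params(
                observed, Y, fix_X=float(Xg), seed=seed, n_starts=4, profile=False
            )
            prof.append((float(Xg), sub.log_likelihood))

    return EstimateResult(
        params=params,
        log_likelihood=-res_fun,
        n_starts=n_starts,
        converged=bool(np.isfinite(res_fun) and res_fun < 1e299),
        X_fixed=fix_X is not None,
        profile=prof,
    )


def profile_likelihood_X(
    observed: ObservedCounts,
    Y: float,
    X_grid: np.ndarray,
    seed: int | None = 0,
) -> list[tuple[float, float]]:
    """Profile log-likelihood over pinned droplet counts ``X``."""
    out = []
    for Xg in np.asarray(X_grid, dtype=float):
        res = estimate_params(observed, Y, fix_X=float(Xg), seed=seed, n_starts=4)
        out.append((float(Xg), res.log_likelihood))
    return out
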