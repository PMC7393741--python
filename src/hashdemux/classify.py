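"""Multi-sample multiplet (MSM) classification of hashtag-barcoded GEMs.

Pipeline: centered-log-ratio (CLR) transform each hashtag column across
GEMs, fit a two-component univariate Gaussian mixture per sample by EM
(the low component models background antibody binding on sample-foreign
droplets, the high component genuine sample-tagged droplets), convert each
value to a posterior probability of tag presence, and assign every GEM the
most probable sample subset: the empty set (negative), a singleton
(single-sample droplet, SSD), or a multi-sample combination (MSM).  GEMs
whose best subset probability falls below a confidence cutoff ``c`` are
labelled unclear, giving at most ``2^M + 1`` distinct labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formation import ObservedCounts
from .io import HTOMatrix

__all__ = [
    "SampleMixtureModel",
    "GEMClassification",
    "clr_normalize",
    "fit_sample_mixture",
    "posterior_high",
    "classify_gems",
    "count_observed",
    "NEGATIVE",
    "UNCLEAR",
]

NEGATIVE = "negative"
UNCLEAR = "unclear"

_LOG_2PI = math.log(2.0 * math.pi)


def clr_normalize(hto: HTOMatrix | np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Centered-log-ratio transform of hashtag counts, column-wise.

    Each entry becomes ``log((x + pc) / g_l)`` where ``g_l`` is the
    geometric mean of ``x + pc`` over all GEMs in column ``l``; every
    column of the result has mean zero.  The pseudocount keeps the log
    finite at zero counts; it must be positive whenever zeros are present.
    """
    counts = hto.counts if isinstance(hto, HTOMatrix) else np.asarray(hto)
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    shifted = counts.astype(float) + pseudocount
    if (shifted <= 0).any():
        raise ValueError("zero counts require a positive pseudocount")
    logs = np.log(shifted)
    return logs - logs.mean(axis=0, keepdims=True)


@dataclass(frozen=True)
class SampleMixtureModel:
    """Two-component univariate Gaussian mixture for one hashtag column."""

    mu_low: float
    sigma_low: float
    mu_high: float
    sigma_high: float
    pi_low: float
    pi_high: float
    log_likelihood: float = float("nan")
    n_iter: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.sigma_low > 0 and self.sigma_high > 0):
            raise ValueError("component sigmas must be positive")
        if not math.isclose(self.pi_low + self.pi_high, 1.0, abs_tol=1e-9):
            raise ValueError("mixture priors must sum to 1")
        if not self.mu_low < self.mu_high:
            raise ValueError("components must be ordered: mu_low < mu_high")


def _log_normal_pdf(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    z = (x - mu) / sigma
    return -0.5 * z * z - math.log(sigma) - 0.5 * _LOG_2PI


def fit_sample_mixture(
    values: np.ndarray,
    seed: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-6,
    var_floor: float = 1e-6,
) -> SampleMixtureModel:
    """Fit a two-component Gaussian mixture to one CLR column by EM.

    Initialization splits the column at its median and moment-matches each
    half with priors 0.5/0.5, which is deterministic and lands near the
    bimodal structure of hashtag data; ``seed`` is accepted for interface
    symmetry but unused.  EM stops when the relative log-likelihood change
    drops below ``tol``.  Component variances are floored at ``var_floor``
    so point-mass halves (e.g. an all-zero background) remain fittable.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"need at least 4 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate column: all values identical")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # heavy ties at the median
        lo, hi = x[x < med], x[x >= med]
    mu = np.array([lo.mean(), hi.mean()])
    var = np.array([max(lo.var(), var_floor), max(hi.var(), var_floor)])
    pi = np.array([0.5, 0.5])

    prev_ll = -np.inf
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        # E-step in log space
        log_comp = np.stack(
            [
                np.log(pi[k]) + _log_normal_pdf(x, mu[k], math.sqrt(var[k]))
                for k in range(2)
            ]
        )
        log_norm = np.logaddexp(log_comp[0], log_comp[1])
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm)
        # M-step
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        mu = (resp @ x) / nk
        var = np.array([max((resp[k] @ (x - mu[k]) ** 2) / nk[k], var_floor) for k in range(2)])
        pi = nk / x.size
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll
    order = np.argsort(mu)
    lo_i, hi_i = int(order[0]), int(order[1])
    if mu[lo_i] == mu[hi_i]:
        raise ValueError("EM collapsed to identical components")
    return SampleMixtureModel(
        mu_low=float(mu[lo_i]),
        sigma_low=float(math.sqrt(var[lo_i])),
        mu_high=float(mu[hi_i]),
        sigma_high=float(math.sqrt(var[hi_i])),
        pi_low=float(pi[lo_i]),
        pi_high=float(pi[hi_i]),
        log_likelihood=ll,
        n_iter=n_iter,
        converged=converged,
    )


def posterior_high(model: SampleMixtureModel, x: float | np.ndarray) -> np.ndarray | float:
    """Posterior probability that a CLR value comes from the high component.

    Bayes' rule on the two weighted component densities, evaluated in log
    space so extreme values far outside both components stay well defined.
    """
    arr = np.asarray(x, dtype=float)
    log_hi = math.log(max(model.pi_high, 1e-300)) + _log_normal_pdf(
        arr, model.mu_high, model.sigma_high
    )
    log_lo = math.log(max(model.pi_low, 1e-300)) + _log_normal_pdf(
        arr, model.mu_low, model.sigma_low
    )
    post = np.exp(log_hi - np.logaddexp(log_hi, log_lo))
    return float(post) if np.isscalar(x) or arr.ndim == 0 else post


@dataclass
class GEMClassification:
    """Per-GEM class assignments with confidence scores.

    ``subsets[i]`` is the assigned sample-index subset for GEM ``i``
    (empty frozenset = negative) or ``None`` when the GEM is unclear.
    ``table`` is the two-column output view (label, confidence) indexed by
    barcode; labels join sample names with ``+``.
    """

    barcodes: list[str]
    sample_names: list[str]
    subsets: list[frozenset[int] | None]
    confidence: np.ndarray

    def label(self, subset: frozenset[int] | None) -> str:
        if subset is None:
            return UNCLEAR
        if not subset:
            return NEGATIVE
        return "+".join(self.sample_names[l] for l in sorted(subset))

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "classification": [self.label(u) for u in self.subsets],
                "confidence": self.confidence,
            },
            index=pd.Index(self.barcodes, name="barcode"),
        )

    def is_msm(self) -> np.ndarray:
        return np.array([u is not None and len(u) >= 2 for u in self.subsets])

    def is_ssd(self) -> np.ndarray:
        return np.array([u is not None and len(u) == 1 for u in self.subsets])

    def is_unclear(self) -> np.ndarray:
        return np.array([u is None for u in self.subsets])

    def is_negative(self) -> np.ndarray:
        return np.array([u is not None and len(u) == 0 for u in self.subsets])


def classify_gems(
    posteriors: np.ndarray,
    barcodes: list[str] | None = None,
    sample_names: list[str] | None = None,
    c: float = 0.8,
) -> GEMClassification:
    """Assign every GEM its most probable sample subset.

    The probability of subset ``U`` is ``prod_{l in U} p_l * prod_{l not
    in U} (1 - p_l)`` with ``p_l`` the per-sample high posteriors; these
    factor per sample, so the argmax over all ``2^M`` subsets is obtained
    by including exactly the samples with ``p_l > 0.5`` (at ``p_l = 0.5``
    the sample is excluded — ties prefer the smaller subset) and the
    confidence is ``prod_l max(p_l, 1 - p_l)``.  GEMs with confidence
    below the cutoff ``c`` are labelled unclear.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.ndim != 2:
        raise ValueError("posteriors must be a GEMs x samples matrix")
    if ((post < 0) | (post > 1)).any():
        raise ValueError("posteriors must lie in [0, 1]")
    if not 0.0 <= c <= 1.0:
        raise ValueError("confidence cutoff must be in [0, 1]")
    n, m = post.shape
    if barcodes is None:
        barcodes = [f"GEM{i:07d}" for i in range(n)]
    if sample_names is None:
        sample_names = [f"sample{l + 1}" for l in range(m)]

    include = post > 0.5
    confidence = np.prod(np.maximum(post, 1.0 - post), axis=1)
    subsets: list[frozenset[int] | None] = []
    for i in range(n):
        if confidence[i] < c:
            subsets.append(None)
        else:
            subsets.append(frozenset(np.nonzero(include[i])[0].tolist()))
    return GEMClassification(
        barcodes=list(barcodes),
        sample_names=list(sample_names),
        subsets=subsets,
        confidence=confidence,
    )


def subset_log_probabilities(posteriors_row: np.ndarray) -> dict[frozenset[int], float]:
    """Probability of every sample subset for one GEM, by full enumeration.

    Exponential in the number of samples; intended for inspection and for
    validating the factorized argmax used by :func:`classify_gems`.
    """
    p = np.asarray(posteriors_row, dtype=float).ravel()
    m = p.size
    if m > 20:
        raise ValueError("enumeration is limited to 20 samples")
    out: dict[frozenset[int], float] = {}
    for mask in range(1 << m):
        prob = 1.0
        for l in range(m):
            prob *= p[l] if mask >> l & 1 else 1.0 - p[l]
        out[frozenset(l for l in range(m) if mask >> l & 1)] = prob
    return out


def count_observed(classification: GEMClassification) -> ObservedCounts:
    """Tally classifier observations for the formation-model estimator.

    ``z[l]`` counts GEMs whose class contains sample ``l``; the venn map
    counts GEMs per MSM sample combination; negatives and unclears are
    counted separately and take no part in the likelihood.
    """
    m = len(classification.sample_names)
    z = np.zeros(m, dtype=int)
    venn: dict[frozenset[int], int] = {}
    n_negative = n_unclear = 0
    for u in classification.subsets:
        if u is None:
            n_unclear += 1
        elif not u:
            n_negative += 1
        else:
            for l in u:
                z[l] += 1
            if len(u) >= 2:
                venn[u] = venn.get(u, 0) + 1
    n_cell_gems = sum(
        1 for u in classification.subsets if u is not None and len(u) >= 1
    )
    return ObservedCounts(
        z=tuple(int(v) for v in z),
        venn=venn,
        n_negative=n_negative,
        n_unclear=n_unclear,
        n_gems=n_cell_gems,
    )
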