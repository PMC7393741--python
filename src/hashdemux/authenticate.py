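"""Authentication of putative cell-type clusters via their MSM content.

A cluster of GEMs proposed as a novel cell type can instead be an artifact
of multiplets: droplets holding cells of two or more real types form
"phony-type" GEMs whose merged expression profile clusters apart from any
real type.  Because such a cluster consists entirely of multiplets, the
fraction of its GEMs that are multi-sample multiplets (MSMs) is governed by
the sample proportions alone: a multiplet of ``k`` cells is *not* an MSM
only when all ``k`` cells carry the same sample tag, probability
``sum_l q_l^k`` under sample proportions ``q``.  For doublets with ``M``
even samples the expected MSM fraction is therefore ``1 - 1/M`` (~75% at
``M = 4``), far above the MSM fraction of a genuine ("pure-type") cluster,
which collides with itself only as often as the formation model allows for
its population size.

Both hypotheses are scored with one-sided exact binomial tests on the
observed MSM count and combined into a verdict: pure, phony, mixture (both
rejected) or indeterminate (neither).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .classify import GEMClassification
from .formation import FormationParams, droplet_rates

__all__ = [
    "ClusterReport",
    "phony_msm_expectation",
    "pure_msm_expectation",
    "authenticate",
    "authenticate_cluster",
]

PURE = "pure"
PHONY = "phony"
MIXTURE = "mixture"
INDETERMINATE = "indeterminate"


@dataclass
class ClusterReport:
    """Authentication result for one GEM cluster."""

    n_gems: int
    n_msm: int
    msm_ratio: float
    p_pure_expected: float
    p_phony_expected: float
    p_value_pure: float
    p_value_phony: float
    verdict: str


def phony_msm_expectation(
    q: np.ndarray,
    order: int = 2,
    params: FormationParams | None = None,
    max_k: int = 30,
) -> float:
    """Expected MSM fraction of a phony-type (multi-cell-type) cluster.

    Every GEM in a phony cluster holds at least ``order`` cells (one per
    member cell type).  A ``k``-cell multiplet evades MSM detection with
    probability ``sum_l q_l^k``, so the doublet-only floor is
    ``1 - sum_l q_l^2`` — exactly ``1 - 1/M`` for even proportions — and
    higher-order multiplets only push the fraction up.  Without formation
    parameters the conservative floor at ``k = order`` is returned; with
    them, the per-droplet cell count is averaged over its truncated
    binomial distribution ``k ~ Binomial(Y, 1/X) | k >= order``.
    """
    q = np.asarray(q, dtype=float)
    if order < 2:
        raise ValueError("a phony GEM holds at least two cells (order >= 2)")
    if not np.isclose(q.sum(), 1.0):
        raise ValueError("sample proportions must sum to 1")
    if params is None:
        return float(1.0 - np.sum(q**order))
    Y, X = params.Y, params.X
    ks = np.arange(order, max_k + 1)
    with np.errstate(under="ignore"):
        log_w = stats.binom.logpmf(ks, int(round(Y)), 1.0 / X)
    w = np.exp(log_w - log_w.max())
    w /= w.sum()
    same = np.array([np.sum(q**k) for k in ks])
    return float(np.sum(w * (1.0 - same)))


def pure_msm_expectation(
    n_gems: int,
    q: np.ndarray,
    params: FormationParams,
) -> float:
    """Expected MSM fraction of a genuine cell-type cluster.

    The cluster's underlying cell population ``y_t`` is inferred by
    inverting the expected captured-GEM count of the formation model,
    ``n_gems = r_cap * X * (1 - (1 - 1/X)^{y_t})``; the cluster's MSM
    fraction is then the model MSM rate for a population of ``y_t`` cells
    split across samples with proportions ``q`` — small for rare types and
    growing with cluster size, since only self-collisions of the type
    produce multiplets that stay inside the cluster.
    """
    q = np.asarray(q, dtype=float)
    if n_gems < 1:
        raise ValueError("cluster must contain at least one GEM")
    if not np.isclose(q.sum(), 1.0):
        raise ValueError("sample proportions must sum to 1")
    cap = params.r_cap * params.X
    if n_gems >= cap:
        raise ValueError(
            f"cluster GEM count {n_gems} exceeds the expected captured "
            f"droplet capacity {cap:.0f}"
        )
    # invert E[#captured non-empty] for the type's cell count
    y_t = np.log1p(-n_gems / cap) / np.log1p(-1.0 / params.X)
    y = np.maximum(q * y_t, 1e-9)
    sub = FormationParams(X=params.X, r_cap=params.r_cap, y=tuple(y))
    return droplet_rates(sub).p_msm


def authenticate(
    n_gems: int,
    n_msm: int,
    p_pure_expected: float,
    p_phony_expected: float,
    alpha: float = 0.05,
) -> ClusterReport:
    """Binomial hypothesis tests of cluster identity.

    The pure hypothesis is rejected when the observed MSM count is
    implausibly *high* for a genuine type (upper-tail test at
    ``p_pure_expected``); the phony hypothesis when it is implausibly *low*
    for an all-multiplet cluster (lower-tail test at ``p_phony_expected``).
    """
    if n_gems < 1:
        raise ValueError("cluster must contain at least one GEM")
    if not 0 <= n_msm <= n_gems:
        raise ValueError("MSM count must lie between 0 and the cluster size")
    if not (0.0 < p_pure_expected < 1.0 and 0.0 < p_phony_expected < 1.0):
        raise ValueError("expected MSM fractions must lie strictly in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    p_pure = stats.binomtest(
        n_msm, n_gems, p_pure_expected, alternative="greater"
    ).pvalue
    p_phony = stats.binomtest(
        n_msm, n_gems, p_phony_expected, alternative="less"
    ).pvalue
    pure_rejected = p_pure < alpha
    phony_rejected = p_phony < alpha
    if phony_rejected and not pure_rejected:
        verdict = PURE
    elif pure_rejected and not phony_rejected:
        verdict = PHONY
    elif pure_rejected and phony_rejected:
        verdict = MIXTURE
    else:
        verdict = INDETERMINATE
    return ClusterReport(
        n_gems=n_gems,
        n_msm=n_msm,
        msm_ratio=n_msm / n_gems,
        p_pure_expected=p_pure_expected,
        p_phony_expected=p_phony_expected,
        p_value_pure=float(p_pure),
        p_value_phony=float(p_phony),
        verdict=verdict,
    )


def authenticate_cluster(
    classification: GEMClassification,
    cluster_barcodes: set[str],
    params: FormationParams,
    alpha: float = 0.05,
) -> ClusterReport:
    """Authenticate a cluster given a prior classification run.

    Negative and unclear GEMs are excluded from the cluster tally; sample
    proportions come from the formation-model estimate (``y_l / Y``).
    """
    idx = {b: i for i, b in enumerate(classification.barcodes)}
    members = [idx[b] for b in cluster_barcodes if b in idx]
    n_gems = n_msm = 0
    for i in members:
        u = classification.subsets[i]
        if u is None or len(u) == 0:
            continue
        n_gems += 1
        if len(u) >= 2:
            n_msm += 1
    if n_gems == 0:
        raise ValueError("cluster has no classified (non-negative, clear) GEMs")
    q = np.asarray(params.y) / params.Y
    return authenticate(
        n_gems,
        n_msm,
        p_pure_expected=pure_msm_expectation(n_gems, q, params),
        p_phony_expected=phony_msm_expectation(q, order=2),
        alpha=alpha,
    )
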