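"""Generative model of droplet (GEM) formation in droplet-based single-cell assays.

The model describes library preparation as an augmented binomial process:
``Y`` cells, split across ``M`` barcoded samples (``y_l`` cells in sample
``l``), are partitioned independently and uniformly at random into ``X``
cell-assay droplets.  A droplet is *captured* (combined with a barcoded gel
bead and sequenced as a GEM) independently with probability ``r_cap``.

Conditional on a droplet being non-empty, it is exactly one of

* a **singlet** — one cell;
* a **same-sample multiplet (SSM)** — two or more cells, all from one sample
  (indistinguishable from a singlet in hashtag space);
* a **multi-sample multiplet (MSM)** — cells from at least two samples
  (detectable from hashtag counts).

A **single-sample droplet (SSD)** is a singlet or an SSM.  All closed-form
rates below follow from the binomial occupancy of a single droplet:

    P(non-empty)      = 1 - (1 - 1/X)^Y
    P(singlet)        = Y * (1/X) * (1 - 1/X)^(Y-1)
    P(SSD_l)          = (1 - (1 - 1/X)^y_l) * (1 - 1/X)^(Y - y_l)

and conditional rates divide by ``P(non-empty)``.  The module also provides
a Monte-Carlo simulator of the same process, used as an independent
correctness oracle and as a source of synthetic observed counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

__all__ = [
    "FormationParams",
    "RateReport",
    "FormationSimResult",
    "singlet_rate",
    "droplet_rates",
    "expected_msm_venn",
    "simulate_formation",
]


@dataclass(frozen=True)
class FormationParams:
    """Latent parameters of the droplet-formation model.

    Parameters
    ----------
    X : float
        Total number of cell-assay droplets formed during library
        preparation.  Real-valued: maximum-likelihood estimates live on a
        continuous domain.
    r_cap : float
        Droplet capture rate — probability that a cell-assay droplet is
        combined with a gel bead and sequenced as a GEM.
    y : tuple of float
        Cells loaded per barcoded sample, ``y_l > 0``.
    """

    X: float
    r_cap: float
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", tuple(float(v) for v in self.y))
        if self.X <= 0:
            raise ValueError(f"X must be positive, got {self.X}")
        if not 0.0 <= self.r_cap <= 1.0:
            raise ValueError(f"r_cap must be in [0, 1], got {self.r_cap}")
        if len(self.y) < 1:
            raise ValueError("need at least one sample")
        if any(v <= 0 for v in self.y):
            raise ValueError(f"all y_l must be positive, got {self.y}")

    @property
    def Y(self) -> float:
        """Total number of loaded cells, sum over samples."""
        return float(sum(self.y))

    @property
    def M(self) -> int:
        """Number of barcoded samples."""
        return len(self.y)


@dataclass
class RateReport:
    """Multiplet rates of a (planned or fitted) experiment.

    All probabilities are conditional on a droplet being non-empty, so
    ``p_singlet + p_ssm + p_msm = 1``.  ``p_rssm`` is the *relative* SSM
    rate: the fraction of SSMs among SSDs — the irreducible multiplet noise
    left after removing all MSMs.  Expected counts are over captured
    (sequenced) droplets.
    """

    p_singlet: float
    p_msm: float
    p_ssm: float
    p_rssm: float
    p_ssd: float
    p_ssm_by_sample: tuple[float, ...]
    p_ssd_by_sample: tuple[float, ...]
    p_rssm_by_sample: tuple[float, ...]
    n_gem: float
    n_ssd: float
    venn: dict[frozenset[int], float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "singlet_rate": self.p_singlet,
            "msm_rate": self.p_msm,
            "ssm_rate": self.p_ssm,
            "rssm_rate": self.p_rssm,
            "ssd_rate": self.p_ssd,
            "expected_gems": self.n_gem,
            "expected_ssds": self.n_ssd,
        }


def _log1m_inv(X: float) -> float:
    # log(1 - 1/X), accurate for large X; -inf at X = 1
    if X == 1:
        return -math.inf
    return math.log1p(-1.0 / X)


def _q_pow(lq: float, e) -> float | np.ndarray:
    """(1 - 1/X) ** e given lq = log(1 - 1/X), with 0^0 = 1 at X = 1."""
    if math.isinf(lq):
        return np.where(np.asarray(e) == 0, 1.0, 0.0)[()] * 1.0
    return np.exp(np.asarray(e, dtype=float) * lq)[()]


def singlet_rate(X: float, Y: float) -> float:
    """Probability that a non-empty droplet holds exactly one cell.

    Equals ``Y (1-1/X)^(Y-1) / (X (1 - (1-1/X)^Y))`` — the ratio of the
    expected number of singlets to the expected number of non-empty
    droplets, which for a single droplet is also the exact conditional
    probability.  Independent of how cells are split across samples.
    """
    if X <= 0:
        raise ValueError(f"X must be positive, got {X}")
    if Y < 1:
        raise ValueError(f"Y must be at least 1, got {Y}")
    lq = _log1m_inv(X)
    p_singlet = Y / X * _q_pow(lq, Y - 1)
    p_nonempty = 1.0 - _q_pow(lq, Y)
    return p_singlet / p_nonempty


def droplet_rates(params: FormationParams) -> RateReport:
    """Closed-form singlet/SSM/MSM/RSSM rates for the formation model.

    The same-sample multiplet rate is computed per sample as
    ``P(SSM_l) = P(SSD_l) * (1 - E[#singlets_l] / E[#SSD_l])`` and the
    aggregate is cross-checked against the complement route
    ``1 - P(singlet) - P(MSM)``; the two are algebraically identical.
    """
    X, y = params.X, np.asarray(params.y, dtype=float)
    Y = params.Y
    lq = _log1m_inv(X)

    p_nonempty = 1.0 - _q_pow(lq, Y)
    # unconditional per-sample SSD probability for one droplet
    p_ssd_l = (1.0 - _q_pow(lq, y)) * _q_pow(lq, Y - y)
    # singlets of sample l: exactly one l-cell, no other cell at all
    p_singlet_l = y / X * _q_pow(lq, Y - 1)

    p_ssd = float(p_ssd_l.sum() / p_nonempty)
    p_msm = 1.0 - p_ssd
    p_sing = float(p_singlet_l.sum() / p_nonempty)

    # per-sample SSM via the conditional-exhaustive decomposition of SSDs
    with np.errstate(invalid="ignore"):
        frac_singlet = np.where(p_ssd_l > 0, p_singlet_l / p_ssd_l, 1.0)
    p_ssm_l = p_ssd_l * (1.0 - frac_singlet) / p_nonempty
    p_ssm = float(p_ssm_l.sum())

    p_ssd_l_cond = p_ssd_l / p_nonempty
    with np.errstate(divide="ignore", invalid="ignore"):
        rssm_l = np.where(p_ssd_l_cond > 0, p_ssm_l / p_ssd_l_cond, 0.0)

    p_rssm = p_ssm / p_ssd if p_ssd > 0 else 0.0
    n_gem = X * p_nonempty * params.r_cap
    n_ssd = n_gem * (1.0 - p_msm)

    return RateReport(
        p_singlet=p_sing,
        p_msm=p_msm,
        p_ssm=p_ssm,
        p_rssm=p_rssm,
        p_ssd=p_ssd,
        p_ssm_by_sample=tuple(p_ssm_l),
        p_ssd_by_sample=tuple(p_ssd_l_cond),
        p_rssm_by_sample=tuple(rssm_l),
        n_gem=n_gem,
        n_ssd=n_ssd,
    )


def expected_msm_venn(
    params: FormationParams, min_size: int = 1
) -> dict[frozenset[int], float]:
    """Expected captured-GEM count for every sample combination.

    For a subset ``U`` of samples the expected number of captured droplets
    containing cells from exactly the samples in ``U`` is

        r_cap * X * prod_{l in U} (1 - (1-1/X)^y_l) * (1-1/X)^(sum_{l not in U} y_l)

    ``|U| = 1`` entries are expected SSD counts; ``|U| >= 2`` entries are the
    per-combination MSM expectations drawn as a Venn diagram when validating
    the model against classifier-observed counts.
    """
    X, y = params.X, params.y
    M = params.M
    if M > 20:
        raise ValueError("subset enumeration is limited to 20 samples")
    lq = _log1m_inv(X)
    p_in = [1.0 - _q_pow(lq, v) for v in y]  # P(droplet holds a cell of l)
    p_out = [float(_q_pow(lq, v)) for v in y]
    out: dict[frozenset[int], float] = {}
    for mask in range(1, 1 << M):
        members = [l for l in range(M) if mask >> l & 1]
        if len(members) < min_size:
            continue
        p = 1.0
        for l in range(M):
            p *= p_in[l] if mask >> l & 1 else p_out[l]
        out[frozenset(members)] = params.r_cap * X * p
    return out


@dataclass
class ObservedCounts:
    """Classifier-observed per-sample GEM counts.

    ``z[l]`` is the number of GEMs whose assigned class contains sample
    ``l`` (SSDs of ``l`` plus every MSM combination involving ``l``).
    ``venn`` holds per-combination MSM counts (subsets of size >= 2), kept
    for model validation only — the likelihood uses ``z`` alone.
    """

    z: tuple[int, ...]
    venn: dict[frozenset[int], int] = field(default_factory=dict)
    n_negative: int = 0
    n_unclear: int = 0
    n_gems: int | None = None  # total cell-enclosing GEMs (SSDs + MSMs)

    def __post_init__(self) -> None:
        self.z = tuple(int(v) for v in self.z)
        if any(v < 0 for v in self.z):
            raise ValueError("observed counts must be non-negative")
        if any(len(u) < 2 for u in self.venn):
            raise ValueError("venn subsets must have at least two samples")

    @property
    def M(self) -> int:
        return len(self.z)


@dataclass
class FormationSimResult:
    """Empirical tallies from Monte-Carlo droplet formation.

    Counts are totals over all repetitions, restricted to captured
    droplets.  ``per_rep`` holds per-repetition (singlet, msm, ssm)
    fractions among captured non-empty droplets, for confidence intervals.
    """

    reps: int
    n_captured_nonempty: int
    n_singlet: int
    n_msm: int
    n_ssm: int
    z: tuple[int, ...]
    venn: dict[frozenset[int], int]
    singlet_by_sample: tuple[int, ...]
    per_rep: np.ndarray  # (reps, 3) singlet/msm/ssm fractions

    @property
    def p_singlet(self) -> float:
        return self.n_singlet / self.n_captured_nonempty

    @property
    def p_msm(self) -> float:
        return self.n_msm / self.n_captured_nonempty

    @property
    def p_ssm(self) -> float:
        return self.n_ssm / self.n_captured_nonempty

    def observed_counts(self) -> ObservedCounts:
        """Average per-sample cell-enclosing GEM counts, rounded, as one
        observation (sensible mainly for ``reps=1``)."""
        z = tuple(int(round(v / self.reps)) for v in self.z)
        venn = {u: int(round(c / self.reps)) for u, c in self.venn.items()}
        return ObservedCounts(
            z=z, venn=venn, n_gems=int(round(self.n_captured_nonempty / self.reps))
        )


def simulate_formation(
    params: FormationParams,
    reps: int = 1,
    seed: int | np.random.Generator | None = None,
    max_chunk_cells: int = 4_000_000,
) -> FormationSimResult:
    """Monte-Carlo simulation of the droplet-formation process.

    Each repetition partitions every cell independently and uniformly into
    one of ``round(X)`` droplets, captures each droplet with probability
    ``r_cap``, and tallies singlets, SSMs and MSMs among captured non-empty
    droplets.  ``X`` and ``y_l`` are rounded to integers.

    Repetitions are processed in chunks to bound memory; results are exact
    tallies, independent of the chunking.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = int(round(params.X))
    y = np.array([int(round(v)) for v in params.y], dtype=np.int64)
    if X < 1:
        raise ValueError("X must round to at least 1")
    M = len(y)
    Y = int(y.sum())
    sample_of_cell = np.repeat(np.arange(M), y)

    tot_nonempty = tot_singlet = tot_msm = tot_ssm = 0
    z = np.zeros(M, dtype=np.int64)
    singlet_by_sample = np.zeros(M, dtype=np.int64)
    venn: dict[frozenset[int], int] = {}
    per_rep = np.zeros((reps, 3), dtype=float)

    chunk = max(1, min(reps, max_chunk_cells // max(Y, 1)))
    done = 0
    while done < reps:
        r = min(chunk, reps - done)
        # droplet index of every cell, all reps of the chunk at once
        drop = rng.integers(0, X, size=(r, Y), dtype=np.int64)
        keys = drop + (np.arange(r) * X)[:, None]  # disjoint id space per rep
        nbins = r * X
        total = np.zeros(nbins, dtype=np.int32)
        mask = np.zeros(nbins, dtype=np.int32)
        n_present = np.zeros(nbins, dtype=np.int8)
        for l in range(M):
            cnt = np.bincount(keys[:, sample_of_cell == l].ravel(), minlength=nbins)
            present = cnt > 0
            total += cnt.astype(np.int32)
            mask += present.astype(np.int32) << l
            n_present += present
        captured = rng.random(nbins) < params.r_cap
        nonempty = total > 0
        keep = captured & nonempty
        singlet = keep & (total == 1)
        msm = keep & (n_present >= 2)
        ssm = keep & ~singlet & ~msm

        tot_nonempty += int(keep.sum())
        tot_singlet += int(singlet.sum())
        tot_msm += int(msm.sum())
        tot_ssm += int(ssm.sum())

        venn_counts = np.bincount(mask[keep], minlength=1 << M if M <= 20 else 0)
        for m in np.nonzero(venn_counts)[0]:
            if m == 0:
                continue
            members = frozenset(l for l in range(M) if m >> l & 1)
            c = int(venn_counts[m])
            if len(members) >= 2:
                venn[members] = venn.get(members, 0) + c
            for l in members:
                z[l] += c
        sm = mask[singlet]
        for l in range(M):
            singlet_by_sample[l] += int(np.count_nonzero(sm == 1 << l))

        keep2 = keep.reshape(r, X)
        denom = keep2.sum(axis=1).astype(float)
        denom[denom == 0] = np.nan
        per_rep[done : done + r, 0] = singlet.reshape(r, X).sum(axis=1) / denom
        per_rep[done : done + r, 1] = msm.reshape(r, X).sum(axis=1) / denom
        per_rep[done : done + r, 2] = ssm.reshape(r, X).sum(axis=1) / denom
        done += r

    return FormationSimResult(
        reps=reps,
        n_captured_nonempty=tot_nonempty,
        n_singlet=tot_singlet,
        n_msm=tot_msm,
        n_ssm=tot_ssm,
        z=tuple(int(v) for v in z),
        venn=venn,
        singlet_by_sample=tuple(int(v) for v in singlet_by_sample),
        per_rep=per_rep,
    )
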