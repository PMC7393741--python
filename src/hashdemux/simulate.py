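"""Synthetic sample-barcoding datasets with ground truth.

The generator mirrors how benchmark datasets for hashtag demultiplexing
are built from real single-sample droplets: first draw per-sample SSD
hashtag profiles (a high on-target count and low off-target background
per column, each from a moment-matched log-normal), then assemble droplets
— most holding a single SSD, a controlled fraction holding two SSDs from
distinct samples (ground-truth MSMs), optionally some holding two SSDs
from the same sample (ground-truth SSMs).  Multi-SSD droplet counts are
the weighted sum of their members' counts, with weights drawn from
``N(1, 0.04)`` to emulate sequencing-depth variation, rounded to integers.

The default per-sample count statistics follow a published 4-sample
cell-hashing PBMC benchmark: on-target means in the hundreds-to-thousands
with comparable spread, off-target background means around 15–80.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import HTOMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_profiles",
    "generate_ssd_profiles",
    "assemble_dataset",
    "simulate_dataset",
    "DEFAULT_MEANS",
    "DEFAULT_STDS",
]

# per-sample SSD hashtag count statistics of a 4-sample cell-hashing PBMC
# benchmark: row = sample of origin, column = hashtag; diagonal = on-target
DEFAULT_MEANS = np.array(
    [
        [2789.10, 20.94, 38.99, 17.34],
        [76.91, 831.75, 36.06, 15.86],
        [77.66, 19.92, 1117.05, 16.12],
        [75.56, 19.33, 36.25, 717.48],
    ]
)
DEFAULT_STDS = np.array(
    [
        [1637.15, 11.85, 18.33, 9.94],
        [43.92, 680.13, 17.56, 10.09],
        [43.16, 12.04, 783.55, 10.23],
        [43.34, 11.66, 18.22, 457.40],
    ]
)


def default_profiles(M: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (means, stds) matrices for ``M`` samples.

    Up to four samples, sub-blocks of the benchmark statistics are used;
    beyond four, additional samples reuse the benchmark rows cyclically
    for their on/off-target scale.
    """
    if M < 1:
        raise ValueError("need at least one sample")
    if M <= 4:
        return DEFAULT_MEANS[:M, :M].copy(), DEFAULT_STDS[:M, :M].copy()
    means = np.empty((M, M))
    stds = np.empty((M, M))
    for s in range(M):
        for l in range(M):
            src_s, src_l = s % 4, (s if l == s else l) % 4
            if l == s:
                means[s, l] = DEFAULT_MEANS[src_s, src_s]
                stds[s, l] = DEFAULT_STDS[src_s, src_s]
            else:
                means[s, l] = DEFAULT_MEANS[src_s, src_l if src_l != src_s else (src_l + 1) % 4]
                stds[s, l] = DEFAULT_STDS[src_s, src_l if src_l != src_s else (src_l + 1) % 4]
    return means, stds


@dataclass
class SimConfig:
    """Configuration of a synthetic sample-barcoding dataset.

    ``msm_fraction`` is the fraction of droplets that are cross-sample
    doublets (ground-truth MSMs); ``ssm_fraction`` adds same-sample
    doublets, which no hashtag classifier can detect.  ``sample_ratios``
    sets the relative SSD population of each sample (e.g. 9:3:1).
    """

    M: int = 4
    n_droplets: int = 20_000
    msm_fraction: float = 0.10
    ssm_fraction: float = 0.0
    sample_ratios: tuple[float, ...] | None = None
    means: np.ndarray | None = None
    stds: np.ndarray | None = None
    weight_mean: float = 1.0
    weight_sd: float = 0.2  # variance 0.04
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("need at least one sample")
        if not 0.0 <= self.msm_fraction < 1.0:
            raise ValueError("msm_fraction must lie in [0, 1)")
        if not 0.0 <= self.ssm_fraction < 1.0:
            raise ValueError("ssm_fraction must lie in [0, 1)")
        if self.msm_fraction + self.ssm_fraction >= 1.0:
            raise ValueError("doublet fractions must sum below 1")
        if self.M == 1 and self.msm_fraction > 0:
            raise ValueError("cross-sample doublets need at least two samples")
        if self.sample_ratios is None:
            self.sample_ratios = (1.0,) * self.M
        self.sample_ratios = tuple(float(r) for r in self.sample_ratios)
        if len(self.sample_ratios) != self.M:
            raise ValueError("one ratio per sample required")
        if any(r <= 0 for r in self.sample_ratios):
            raise ValueError("sample ratios must be positive")
        if self.means is None or self.stds is None:
            m, s = default_profiles(self.M)
            self.means = m if self.means is None else np.asarray(self.means, float)
            self.stds = s if self.stds is None else np.asarray(self.stds, float)
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if self.means.shape != (self.M, self.M) or self.stds.shape != (self.M, self.M):
            raise ValueError("means/stds must be M x M (sample x hashtag)")
        if (self.means <= 0).any() or (self.stds < 0).any():
            raise ValueError("means must be positive and stds non-negative")

    @property
    def sample_probs(self) -> np.ndarray:
        r = np.asarray(self.sample_ratios, dtype=float)
        return r / r.sum()


@dataclass
class SimTruth:
    """Ground-truth droplet composition of a synthetic dataset."""

    members: list[tuple[int, ...]]  # sample index of each member SSD

    @property
    def is_msm(self) -> np.ndarray:
        return np.array([len(set(m)) >= 2 for m in self.members])

    @property
    def is_ssm(self) -> np.ndarray:
        return np.array([len(m) >= 2 and len(set(m)) == 1 for m in self.members])

    @property
    def is_singlet(self) -> np.ndarray:
        return np.array([len(m) == 1 for m in self.members])

    def to_frame(self, barcodes: list[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "members": ["+".join(str(s) for s in m) for m in self.members],
                "is_msm": self.is_msm,
                "is_ssm": self.is_ssm,
                "is_singlet": self.is_singlet,
            },
            index=pd.Index(barcodes, name="barcode"),
        )


def _lognormal_counts(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer counts from a log-normal moment-matched to (mean, sd)."""
    if sd == 0:
        return np.full(size, round(mean), dtype=np.int64)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    draws = rng.lognormal(mu, np.sqrt(sigma2), size=size)
    return np.maximum(np.rint(draws), 0).astype(np.int64)


def generate_ssd_profiles(
    config: SimConfig,
    labels: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Hashtag count vectors for single-sample droplets.

    ``labels[i]`` is the sample of origin of SSD ``i``; its on-target
    column is drawn from the sample's high distribution and every other
    column from that sample's background distribution.
    """
    rng = rng or np.random.default_rng(config.seed)
    labels = np.asarray(labels)
    n = labels.size
    counts = np.zeros((n, config.M), dtype=np.int64)
    for s in range(config.M):
        rows = np.nonzero(labels == s)[0]
        if rows.size == 0:
            continue
        for l in range(config.M):
            counts[rows, l] = _lognormal_counts(
                config.means[s, l], config.stds[s, l], rows.size, rng
            )
    return counts


def assemble_dataset(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[HTOMatrix, SimTruth]:
    """Assemble droplets from SSD profiles according to the configuration.

    Exactly ``ceil(msm_fraction * n)`` droplets are cross-sample doublets
    and ``round(ssm_fraction * n)`` are same-sample doublets; the rest hold
    one SSD.  Droplet counts of multi-SSD droplets are the weighted sums of
    their members' counts with weights from ``N(weight_mean, weight_sd^2)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    n = config.n_droplets
    n_msm = int(np.ceil(config.msm_fraction * n))
    n_ssm = int(round(config.ssm_fraction * n))
    n_single = n - n_msm - n_ssm
    if n_single < 0:
        raise ValueError("doublet fractions exceed the droplet budget")
    probs = config.sample_probs

    members: list[tuple[int, ...]] = []
    members += [(int(s),) for s in rng.choice(config.M, size=n_single, p=probs)]
    for _ in range(n_msm):
        a = int(rng.choice(config.M, p=probs))
        b = int(rng.choice(config.M, p=probs))
        while b == a:
            b = int(rng.choice(config.M, p=probs))
        members.append((a, b))
    for _ in range(n_ssm):
        s = int(rng.choice(config.M, p=probs))
        members.append((s, s))
    order = rng.permutation(n)
    members = [members[i] for i in order]

    flat_labels = np.array([s for m in members for s in m])
    ssd_counts = generate_ssd_profiles(config, flat_labels, rng)

    counts = np.zeros((n, config.M), dtype=np.int64)
    pos = 0
    for i, m in enumerate(members):
        k = len(m)
        block = ssd_counts[pos : pos + k].astype(float)
        if k == 1:
            counts[i] = block[0]
        else:
            w = rng.normal(config.weight_mean, config.weight_sd, size=k)
            w = np.maximum(w, 0.0)
            counts[i] = np.maximum(np.rint(w @ block), 0).astype(np.int64)
        pos += k

    barcodes = [f"GEM{i:07d}" for i in range(n)]
    sample_names = [f"HTO{l + 1}" for l in range(config.M)]
    hto = HTOMatrix(barcodes=barcodes, sample_names=sample_names, counts=counts)
    return hto, SimTruth(members=members)


def simulate_dataset(
    config: SimConfig, seed: int | None = None
) -> tuple[HTOMatrix, SimTruth]:
    """Generate a complete synthetic dataset from a configuration."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    return assemble_dataset(config, rng)
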