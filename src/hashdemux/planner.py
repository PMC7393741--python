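"""Experiment planner: anticipated multiplet rates for a planned run.

Given the number of cell-assay droplets ``X`` (an equipment property,
typically profiled once), the planned cell load ``Y``, the number of
barcoded samples ``M`` and the droplet capture rate ``r_cap``, the planner
evaluates the droplet-formation model under an even split of cells across
samples and reports singlet, MSM, SSM and relative-SSM rates together with
expected GEM and SSD yields.  Sweeps over any parameter support choosing
the cheapest design that meets a noise (RSSM) target.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .formation import FormationParams, RateReport, droplet_rates

__all__ = ["PlannerConfig", "plan", "sweep"]

# typical interactive ranges; values outside them warn but still compute
_SLIDER_RANGES = {
    "X": (60_000.0, 100_000.0),
    "Y": (1_000.0, 80_000.0),
    "M": (1, 20),
    "r_cap": (0.0, 1.0),
}


@dataclass(frozen=True)
class PlannerConfig:
    """A planned sample-barcoding experiment (even split across samples)."""

    X: float
    Y: float
    M: int
    r_cap: float = 1.0

    def __post_init__(self) -> None:
        if self.Y <= 0:
            raise ValueError("planned cell count Y must be positive")
        if self.M < 1:
            raise ValueError("need at least one sample")
        if not 0.0 <= self.r_cap <= 1.0:
            raise ValueError("capture rate must be in [0, 1]")
        for name, (lo, hi) in _SLIDER_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                warnings.warn(
                    f"{name}={v} is outside the typical range [{lo}, {hi}]",
                    stacklevel=3,
                )

    def formation_params(self) -> FormationParams:
        return FormationParams(
            X=self.X, r_cap=self.r_cap, y=(self.Y / self.M,) * self.M
        )


def plan(config: PlannerConfig) -> RateReport:
    """Anticipated rates and yields for one planned experiment."""
    return droplet_rates(config.formation_params())


def sweep(base: PlannerConfig, **ranges: Iterable[float]) -> pd.DataFrame:
    """Evaluate the planner over a grid of parameter values.

    ``ranges`` maps parameter names (``X``, ``Y``, ``M``, ``r_cap``) to
    iterables; the cartesian product is evaluated and returned as one row
    per grid point with the swept parameters as leading columns.
    """
    bad = set(ranges) - set(_SLIDER_RANGES)
    if bad:
        raise ValueError(f"unknown planner parameters: {sorted(bad)}")
    names = list(ranges)
    grids = [list(ranges[n]) for n in names]
    if any(len(g) == 0 for g in grids) or not names:
        raise ValueError("sweep requires at least one non-empty range")
    rows = []
    for combo in itertools.product(*grids):
        kwargs = {"X": base.X, "Y": base.Y, "M": base.M, "r_cap": base.r_cap}
        kwargs.update(dict(zip(names, combo)))
        kwargs["M"] = int(kwargs["M"])
        report = plan(PlannerConfig(**kwargs))
        row: dict[str, float] = {n: v for n, v in zip(names, combo)}
        row.update(report.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
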