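"""hashdemux — demultiplexing and multiplet modelling for sample-barcoded
(cell hashing / MULTI-seq) single-cell data.

Core pieces:

* :mod:`hashdemux.classify` — CLR + per-sample Gaussian-mixture MSM classifier;
* :mod:`hashdemux.formation` — generative droplet-formation model (analytic
  rates and a Monte-Carlo simulator);
* :mod:`hashdemux.estimate` — maximum-likelihood latent-parameter inference;
* :mod:`hashdemux.planner` — anticipated multiplet rates of planned runs;
* :mod:`hashdemux.authenticate` — pure-/phony-type cluster authentication;
* :mod:`hashdemux.simulate` — synthetic datasets with ground truth;
* :mod:`hashdemux.io` — matrix readers and report writers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .authenticate import (
    ClusterReport,
    authenticate,
    authenticate_cluster,
    phony_msm_expectation,
    pure_msm_expectation,
)
from .classify import (
    GEMClassification,
    SampleMixtureModel,
    classify_gems,
    clr_normalize,
    count_observed,
    fit_sample_mixture,
    posterior_high,
)
from .estimate import EstimateResult, estimate_params, log_likelihood
from .formation import (
    FormationParams,
    ObservedCounts,
    RateReport,
    droplet_rates,
    expected_msm_venn,
    simulate_formation,
    singlet_rate,
)
from .io import HTOMatrix, read_hto_csv, read_hto_mtx, write_outputs
from .planner import PlannerConfig, plan, sweep
from .simulate import SimConfig, SimTruth, assemble_dataset, simulate_dataset

__version__ = "0.1.0"

__all__ = [
    "HTOMatrix",
    "read_hto_csv",
    "read_hto_mtx",
    "write_outputs",
    "clr_normalize",
    "fit_sample_mixture",
    "posterior_high",
    "classify_gems",
    "count_observed",
    "SampleMixtureModel",
    "GEMClassification",
    "FormationParams",
    "ObservedCounts",
    "RateReport",
    "singlet_rate",
    "droplet_rates",
    "expected_msm_venn",
    "simulate_formation",
    "log_likelihood",
    "estimate_params",
    "EstimateResult",
    "PlannerConfig",
    "plan",
    "sweep",
    "ClusterReport",
    "phony_msm_expectation",
    "pure_msm_expectation",
    "authenticate",
    "authenticate_cluster",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "assemble_dataset",
    "demultiplex",
    "DemuxResult",
]


@dataclass
class DemuxResult:
    """End-to-end result of a classification + rate-estimation run."""

    classification: GEMClassification
    observed: ObservedCounts
    params: FormationParams | None
    rates: RateReport | None
    mixtures: list[SampleMixtureModel]


def demultiplex(
    hto: HTOMatrix,
    total_cells: float | None,
    confidence_cutoff: float = 0.8,
    pseudocount: float = 1.0,
    seed: int | None = 0,
    fix_X: float | None = None,
    estimate_rates: bool = True,
) -> DemuxResult:
    """Classify GEMs and, optionally, estimate formation-model rates.

    Runs CLR normalization, per-sample mixture fits, subset classification
    at the given confidence cutoff, observation tallies and — when
    ``estimate_rates`` is true and ``total_cells`` given — the
    maximum-likelihood fit of the droplet-formation parameters with the
    implied singlet/MSM/SSM/RSSM rates.
    """
    clr = clr_normalize(hto, pseudocount=pseudocount)
    mixtures = [fit_sample_mixture(clr[:, l], seed=seed) for l in range(hto.n_samples)]
    post = np.column_stack(
        [posterior_high(mixtures[l], clr[:, l]) for l in range(hto.n_samples)]
    )
    classification = classify_gems(
        post, barcodes=hto.barcodes, sample_names=hto.sample_names, c=confidence_cutoff
    )
    observed = count_observed(classification)
    params = rates = None
    if estimate_rates:
        if total_cells is None:
            raise ValueError("total_cells is required to estimate rates")
        params = estimate_params(observed, Y=total_cells, fix_X=fix_X, seed=seed).params
        rates = droplet_rates(params)
    return DemuxResult(
        classification=classification,
        observed=observed,
        params=params,
        rates=rates,
        mixtures=mixtures,
    )

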