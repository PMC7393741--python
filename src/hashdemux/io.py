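"""Reading hashtag (HTO) count matrices and writing classification outputs.

Two input dialects are supported: the CellRanger-style MatrixMarket triplet
(``matrix.mtx`` plus ``barcodes.tsv``/``features.tsv`` sidecars, optionally
gzipped) and a plain CSV with GEM barcodes as row index and one column per
sample hashtag.  Either way the in-memory object is an :class:`HTOMatrix`
with GEMs as rows.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

if TYPE_CHECKING:  # pragma: no cover
    from .classify import GEMClassification
    from .formation import FormationParams, RateReport

__all__ = ["HTOMatrix", "read_hto_mtx", "read_hto_csv", "write_outputs"]


@dataclass
class HTOMatrix:
    """A GEMs x samples matrix of hashtag UMI counts.

    Rows are droplets (GEMs), identified by unique barcodes; columns are
    sample hashtags.  Counts are non-negative integers.
    """

    barcodes: list[str]
    sample_names: list[str]
    counts: np.ndarray  # (n, M) integer

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n, m = self.counts.shape
        if len(self.barcodes) != n or len(self.sample_names) != m:
            raise ValueError(
                f"shape mismatch: counts {self.counts.shape}, "
                f"{len(self.barcodes)} barcodes, {len(self.sample_names)} samples"
            )
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one GEM and one sample")
        if len(set(self.barcodes)) != n:
            raise ValueError("GEM barcodes must be unique")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = np.rint(self.counts)
            if not np.allclose(self.counts, as_int, atol=1e-8):
                raise ValueError("counts must be integral")
            self.counts = as_int.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_gems(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.barcodes, columns=self.sample_names)


def _read_lines(path: Path) -> list[str]:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return [ln.rstrip("\n").split("\t")[0] for ln in fh if ln.strip()]


def _find_sidecar(path: str | Path) -> Path:
    p = Path(path)
    for cand in (p, p.with_suffix(p.suffix + ".gz")):
        if cand.exists():
            return cand
    raise FileNotFoundError(f"sidecar file not found: {path}(.gz)")


def read_hto_mtx(
    matrix_path: str | Path,
    barcodes_path: str | Path,
    features_path: str | Path,
    hto_features: Sequence[str] | None = None,
) -> HTOMatrix:
    """Read a CellRanger-style MatrixMarket triplet as an :class:`HTOMatrix`.

    CellRanger stores features as rows and barcodes as columns; the matrix
    is transposed so that GEMs are rows.  If the run mixed modalities
    (gene-expression rows alongside antibody-capture rows), pass the
    hashtag feature names via ``hto_features`` to select only those rows.
    """
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat)
    if mat.size == 0:
        raise ValueError(f"empty matrix file: {matrix_path}")
    barcodes = _read_lines(_find_sidecar(barcodes_path))
    features = _read_lines(_find_sidecar(features_path))

    if mat.shape == (len(features), len(barcodes)):
        mat = mat.T  # CellRanger orientation: features x barcodes
    elif mat.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"matrix shape {mat.shape} matches neither "
            f"features x barcodes ({len(features)}, {len(barcodes)}) "
            f"nor its transpose"
        )
    if hto_features is not None:
        missing = [f for f in hto_features if f not in features]
        if missing:
            raise ValueError(f"features not found in sidecar: {missing}")
        idx = [features.index(f) for f in hto_features]
        mat = mat[:, idx]
        features = list(hto_features)
    return HTOMatrix(barcodes=barcodes, sample_names=features, counts=mat)


def read_hto_csv(path: str | Path) -> HTOMatrix:
    """Read a plain CSV hashtag matrix (barcode index, one column per sample)."""
    df = pd.read_csv(path, index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate GEM barcodes: {dups[:5]}")
    try:
        counts = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    if np.isnan(counts).any():
        raise ValueError(f"missing or non-numeric cells in {path}")
    return HTOMatrix(
        barcodes=[str(b) for b in df.index],
        sample_names=[str(c) for c in df.columns],
        counts=counts,
    )


def write_hto_csv(hto: HTOMatrix, path: str | Path) -> Path:
    """Write an :class:`HTOMatrix` in the plain-CSV dialect."""
    path = Path(path)
    hto.to_frame().rename_axis("barcode").to_csv(path)
    return path


def write_outputs(
    classification: "GEMClassification",
    rates: "RateReport | None",
    out_dir: str | Path,
    params: "FormationParams | None" = None,
) -> dict[str, Path]:
    """Write the three report files of a classification run.

    * ``classification.csv`` — barcode, class label, confidence;
    * ``sample_summary.csv`` — per-sample SSM and relative-SSM rates;
    * ``dataset_summary.csv`` — dataset-level rates plus the estimated
      droplet count ``X`` and capture rate ``r_cap``.

    ``rates``/``params`` may be ``None`` (classification-only run), in which
    case only the first file is written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    table = classification.table
    if len(table) == 0:
        raise ValueError("empty classification table")
    paths: dict[str, Path] = {}

    paths["classification"] = out_dir / "classification.csv"
    table.rename_axis("barcode").to_csv(paths["classification"])

    if rates is not None:
        sample_rows = pd.DataFrame(
            {
                "sample": classification.sample_names,
                "ssm_rate": rates.p_ssm_by_sample,
                "rssm_rate": rates.p_rssm_by_sample,
                "ssd_rate": rates.p_ssd_by_sample,
            }
        )
        paths["sample_summary"] = out_dir / "sample_summary.csv"
        sample_rows.to_csv(paths["sample_summary"], index=False)

        summary = dict(rates.as_dict())
        if params is not None:
            summary["estimated_droplets_X"] = params.X
            summary["estimated_capture_rate"] = params.r_cap
            summary["total_cells_Y"] = params.Y
        paths["dataset_summary"] = out_dir / "dataset_summary.csv"
        pd.Series(summary, name="value").rename_axis("quantity").to_csv(
            paths["dataset_summary"]
        )
    return paths
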