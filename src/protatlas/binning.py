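"""Rank-bin transformation and tissue/organ merging.

Comparing ppb abundances across datasets is confounded by dataset-level
batch effects.  The bin transform sidesteps them by replacing each MS
run's detected abundances with rank quantiles: within a batch (the MS
runs of one tissue in one dataset) the detected proteins of each run are
sorted from lowest to highest abundance and split into ``n_bins`` (5)
equal-occupancy bins, bin 1 holding the lowest and bin 5 the highest
abundances among the detected proteins.  Because ranks are invariant to
any positive rescaling of a run, a multiplicative dataset effect cancels
exactly.

Run-level bins are merged to tissue level by the median over the runs of
the (dataset, tissue) batch, and tissue-level values to organ level by
the median over contributing tissue columns; half-integer medians are
kept because downstream thresholds operate on medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import ConsistencyError, SampleAnnotation
from .postprocess import ExpressionMatrix

__all__ = ["BinnedMatrix", "bin_transform", "merge_runs_to_tissue", "merge_tissues_to_organ"]


@dataclass
class BinnedMatrix:
    """Gene × (run | tissue | organ) matrix of bin values on the 1..n_bins scale.

    Run-level values are integers; merged levels may hold half-integer
    medians.  ``run_batches`` keeps the per-run (dataset, tissue, organ)
    assignment recorded at transform time so merging never needs the
    annotation again.
    """

    values: pd.DataFrame
    level: str  # 'run' | 'tissue' | 'organ'
    n_bins: int = 5
    run_batches: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.level not in ("run", "tissue", "organ"):
            raise ValueError(f"unknown level {self.level!r}")
        arr = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (arr < 1) | (arr > self.n_bins)
        if bad.any():
            raise ValueError("bin values outside [1, n_bins]")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)


def _bins_from_ranks(ranks: pd.Series, m: int, n_bins: int) -> pd.Series:
    # ceiling(rank * n_bins / m) in exact integer arithmetic; average-tie
    # ranks are half-integers, so 2*rank is an exact integer.
    r2 = np.round(2 * np.nan_to_num(ranks.to_numpy(dtype=float))).astype(np.int64)
    return pd.Series(-(-r2 * n_bins // (2 * m)), index=ranks.index, dtype=float)


def bin_transform(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    n_bins: int = 5,
    ties: str = "average",
) -> BinnedMatrix:
    """Convert a ppb expression matrix into per-run rank bins.

    Per run, the ``m`` detected values receive ranks 1..m (ties get the
    average rank, or dense ranks with ``ties='dense'``) and bin
    ``ceil(rank * n_bins / m)``; missing values are never binned.  Every
    run must be annotated, since the (dataset, tissue) batches are
    recorded for downstream merging.
    """
    if ties not in ("average", "dense"):
        raise ValueError(f"unknown tie policy {ties!r}")
    annotation.require_runs(matrix.runs)
    values = matrix.values
    out = {}
    for run in values.columns:
        col = values[run]
        m = int(col.count())
        if m == 0:
            out[run] = col.astype(float)
            continue
        if ties == "average":
            ranks = col.rank(method="average")
            out[run] = _bins_from_ranks(ranks, m, n_bins).where(col.notna())
        else:
            dense = col.rank(method="dense")
            k = int(dense.max())
            out[run] = _bins_from_ranks(dense, k, n_bins).where(col.notna())
    binned = pd.DataFrame(out, index=values.index)[list(values.columns)]
    batches = annotation.batches().loc[list(values.columns)]
    return BinnedMatrix(binned, level="run", n_bins=n_bins, run_batches=batches)


def merge_runs_to_tissue(binned: BinnedMatrix) -> BinnedMatrix:
    """Median-merge run-level bins into (dataset, tissue) batch columns.

    A gene unobserved in every run of a batch stays missing for that
    batch; medians ignore missing runs, so half-integers appear for even
    observation counts.
    """
    if binned.level != "run":
        raise ValueError("merge_runs_to_tissue expects a run-level matrix")
    if binned.run_batches is None:
        raise ConsistencyError("run-level matrix carries no batch assignment")
    b = binned.run_batches.loc[list(binned.values.columns)]
    merged = (
        binned.values.T.groupby(
            [b["dataset_id"].to_numpy(), b["tissue"].to_numpy()]
        )
        .median()
        .T
    )
    merged.columns.names = ["dataset_id", "tissue"]
    merged = merged.sort_index(axis=1)
    return BinnedMatrix(merged, level="tissue", n_bins=binned.n_bins, run_batches=b)


def merge_tissues_to_organ(
    binned: BinnedMatrix, annotation: SampleAnnotation | None = None
) -> BinnedMatrix:
    """Median-merge tissue-level bins into organ columns.

    The organ of each (dataset, tissue) column comes from the batch table
    recorded at transform time (or from ``annotation``); all tissue
    columns contributing to an organ — across datasets — enter one
    median.
    """
    if binned.level != "tissue":
        raise ValueError("merge_tissues_to_organ expects a tissue-level matrix")
    b = binned.run_batches if binned.run_batches is not None else (
        annotation.batches() if annotation is not None else None
    )
    if b is None:
        raise ConsistencyError("no batch table available to map tissues to organs")
    organ_of = (
        b.drop_duplicates(["dataset_id", "tissue"])
        .set_index(["dataset_id", "tissue"])["organ"]
    )
    keys = organ_of.reindex(binned.values.columns)
    if keys.isna().any():
        missing = [c for c, k in zip(binned.values.columns, keys) if pd.isna(k)]
        raise ConsistencyError(f"tissue columns without organ assignment: {missing[:5]}")
    merged = binned.values.T.groupby(keys.to_numpy()).median().T
    merged = merged.sort_index(axis=1)
    merged.columns.name = "organ"
    return BinnedMatrix(merged, level="organ", n_bins=binned.n_bins, run_batches=b)
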