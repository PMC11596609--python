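"""Assembly of per-sample feature vectors into labeled analysis matrices.

Low-level data fusion here means plain concatenation of each sample's
normalized per-mode bucket vectors (HILIC MS1, then RP MS1, then any
fragment layers) into one long row — each block is TIC-normalized
before fusion, so a fused row sums to the number of blocks. The fusion
is lossless: the block boundaries are retained, and slicing them back
out recovers the original vectors bit-for-bit.

The train/test split is by honey, not by sample: a honey's pure sample
and all its mixtures travel together, so the test set measures
generalization to unseen honeys rather than interpolation between
dilutions of a honey the model has already seen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bucketing import BucketGrid, FeatureVector

__all__ = [
    "SampleLabel",
    "AnalysisMatrix",
    "MissingBlockError",
    "fuse",
    "assemble_matrix",
    "split_by_honey",
    "drop_empty_runs",
]

SYRUPS = ("none", "rice", "beet", "hfcs")


class MissingBlockError(ValueError):
    """A sample lacks one of the requested fusion blocks."""


@dataclass(frozen=True)
class SampleLabel:
    """Ground-truth annotation of one sample."""

    honey_id: str
    syrup: str
    proportion: float  # percent v/v
    device_id: str = ""

    def __post_init__(self) -> None:
        if self.syrup not in SYRUPS:
            raise ValueError(f"syrup must be one of {SYRUPS}")
        if (self.syrup == "none") != (self.proportion == 0):
            raise ValueError("syrup 'none' must coincide with proportion 0")


@dataclass
class AnalysisMatrix:
    """Samples x buckets matrix with labels and fusion-block bookkeeping.

    ``X`` is indexed by sample id with canonical bucket-id columns;
    ``labels`` shares the index and carries honey_id, syrup,
    proportion_pct, device_id. ``block_slices`` maps each fused block
    name to its column slice, preserving losslessness of the fusion.
    """

    X: pd.DataFrame
    labels: pd.DataFrame
    block_slices: dict[str, slice] = field(default_factory=dict)
    grids: dict[str, BucketGrid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.X.index.equals(self.labels.index):
            raise ValueError("X and labels must share the same sample index")
        if self.X.isna().any().any():
            raise ValueError("analysis matrix must have no missing values")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def block(self, name: str) -> pd.DataFrame:
        """Recover one original block from the fused matrix (lossless)."""
        return self.X.iloc[:, self.block_slices[name]]

    def subset(self, sample_ids: Sequence[str]) -> "AnalysisMatrix":
        ids = list(sample_ids)
        return AnalysisMatrix(
            X=self.X.loc[ids], labels=self.labels.loc[ids],
            block_slices=dict(self.block_slices), grids=dict(self.grids),
        )


def fuse(blocks: Mapping[str, FeatureVector], order: Sequence[str]) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Concatenate one sample's normalized blocks in a fixed order.

    Returns the fused values, the canonical column names (prefixed with
    the block name), and the block -> column-slice map.
    """
    values, columns, slices = [], [], {}
    start = 0
    for name in order:
        if name not in blocks:
            raise MissingBlockError(f"missing block {name!r}")
        fv = blocks[name]
        values.append(fv.values)
        columns.extend(f"{name}:{bid}" for bid in fv.grid.bucket_ids())
        slices[name] = slice(start, start + fv.values.size)
        start += fv.values.size
    return np.concatenate(values), columns, slices


def assemble_matrix(
    per_sample: Mapping[str, Mapping[str, FeatureVector]],
    labels: Mapping[str, SampleLabel],
    order: Sequence[str],
) -> AnalysisMatrix:
    """Fuse every sample's blocks into one labeled analysis matrix.

    Raises :class:`MissingBlockError` naming the first sample that lacks
    a requested block. Row order follows ``per_sample``'s iteration
    order; columns are fixed by the grids and never depend on samples.
    """
    rows, index = [], []
    columns = slices = None
    grids: dict[str, BucketGrid] = {}
    for sid, blocks in per_sample.items():
        try:
            values, cols, sl = fuse(blocks, order)
        except MissingBlockError as exc:
            raise MissingBlockError(f"sample {sid!r}: {exc}") from None
        if columns is None:
            columns, slices = cols, sl
            grids = {name: blocks[name].grid for name in order}
        rows.append(values)
        index.append(sid)
    if columns is None:
        raise ValueError("no samples to assemble")
    X = pd.DataFrame(np.vstack(rows), index=pd.Index(index, name="sample_id"), columns=columns)
    lab = pd.DataFrame(
        {
            "honey_id": [labels[s].honey_id for s in index],
            "syrup": [labels[s].syrup for s in index],
            "proportion_pct": [labels[s].proportion for s in index],
            "device_id": [labels[s].device_id for s in index],
        },
        index=X.index,
    )
    return AnalysisMatrix(X=X, labels=lab, block_slices=slices, grids=grids)


def split_by_honey(
    labels: pd.DataFrame, n_test_honeys: int = 9, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Honey-disjoint train/test split.

    ``n_test_honeys`` honeys are drawn (seeded) and *all* their samples
    — pure and every mixture — form the test set. Returns
    ``(train_sample_ids, test_sample_ids)`` in row order.
    """
    honeys = sorted(labels["honey_id"].unique())
    if n_test_honeys > len(honeys):
        raise ValueError(f"requested {n_test_honeys} test honeys but only {len(honeys)} exist")
    rng = np.random.default_rng(seed)
    test_honeys = set(rng.choice(honeys, size=n_test_honeys, replace=False)) if n_test_honeys else set()
    is_test = labels["honey_id"].isin(test_honeys)
    return list(labels.index[~is_test]), list(labels.index[is_test])


def drop_empty_runs(matrix: AnalysisMatrix) -> tuple[AnalysisMatrix, list[str]]:
    """Remove samples with any all-zero constituent block.

    Mirrors the quality gate applied to real cohorts, where a run
    without signals (e.g., an injection failure) is removed rather than
    normalized. Returns the filtered matrix and the dropped sample ids.
    """
    bad: list[str] = []
    for sid in matrix.X.index:
        row = matrix.X.loc[sid]
        for name, sl in matrix.block_slices.items():
            if not np.any(row.values[sl]):
                bad.append(sid)
                break
    keep = [s for s in matrix.X.index if s not in set(bad)]
    if not bad:
        return matrix, []
    if not keep:
        empty = AnalysisMatrix(
            X=matrix.X.iloc[0:0], labels=matrix.labels.iloc[0:0],
            block_slices=dict(matrix.block_slices), grids=dict(matrix.grids),
        )
        return empty, bad
    return matrix.subset(keep), bad
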