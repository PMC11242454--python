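"""Core in-memory containers shared by every stage of the pipeline.

The central object is the :class:`FeatureTable`, a samples × taxa abundance
matrix (ASV counts after denoising, or relative abundances after total-sum
scaling).  Samples are rows everywhere in this package; this is the transpose
of some ecosystem tools, so IO helpers state the orientation in file headers.

Phylogenies are plain :class:`skbio.TreeNode` objects and distance matrices
plain :class:`skbio.DistanceMatrix`; no wrapping is done for either.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FeatureTable"]

_REL_TOL = 1e-9


@dataclass
class FeatureTable:
    """Samples × taxa abundance matrix.

    Parameters
    ----------
    data:
        DataFrame with sample identifiers as the index and taxon identifiers
        as columns.  Values must be non-negative; counts for raw tables,
        proportions for relative ones.
    is_relative:
        Whether rows are within-sample proportions (every non-empty row sums
        to 1) rather than counts.
    """

    data: pd.DataFrame
    is_relative: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon ids: {dupes}")
        values = self.data.to_numpy()
        if values.size and np.nanmin(values) < 0:
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative abundance at sample {self.data.index[r]!r}, "
                f"taxon {self.data.columns[c]!r}"
            )
        if self.is_relative:
            sums = values.sum(axis=1)
            bad = np.flatnonzero((sums > 0) & (np.abs(sums - 1.0) > _REL_TOL))
            if bad.size:
                raise ValueError(
                    f"relative table has rows not summing to 1: "
                    f"{self.data.index[bad].tolist()[:5]}"
                )

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def to_numpy(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def proportions(self) -> np.ndarray:
        """Within-sample proportions, recomputed regardless of the flag."""
        x = self.to_numpy()
        sums = x.sum(axis=1, keepdims=True)
        if np.any(sums == 0):
            empty = self.data.index[np.flatnonzero(sums[:, 0] == 0)].tolist()
            raise ValueError(f"samples with zero total abundance: {empty}")
        return x / sums

    def select_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return FeatureTable(self.data.loc[list(sample_ids)], self.is_relative)

    def select_taxa(self, taxon_ids) -> "FeatureTable":
        missing = [t for t in taxon_ids if t not in self.data.columns]
        if missing:
            raise KeyError(f"unknown taxon ids: {missing}")
        # subsetting taxa breaks the row-sum-1 invariant of relative tables
        return FeatureTable(self.data.loc[:, list(taxon_ids)], is_relative=False)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.is_relative)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, FeatureTable)
            and self.is_relative == other.is_relative
            and self.data.equals(other.data)
        )
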