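"""In-memory containers for the joint dynamic + static phenotype data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth import TimeGrid

__all__ = ["LongitudinalDataset", "MarkerPartition"]


@dataclass
class LongitudinalDataset:
    """Phenotypes for n individuals: an (n, T) longitudinal trait matrix, a
    length-n terminal static trait, and the shared measurement grid.

    Individuals must share the time grid (complete-case rule: callers drop
    individuals with any missing time point before constructing this).
    """

    y: np.ndarray
    z: np.ndarray
    grid: TimeGrid
    ids: np.ndarray | None = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.y.ndim != 2:
            raise ValueError("y must be 2-D (individuals x time points)")
        if self.y.shape[1] != len(self.grid):
            raise ValueError(
                f"y has {self.y.shape[1]} columns but grid has {len(self.grid)} times"
            )
        if self.z.shape != (self.y.shape[0],):
            raise ValueError("z must be a vector with one entry per individual")
        if not (np.all(np.isfinite(self.y)) and np.all(np.isfinite(self.z))):
            raise ValueError("phenotypes must be finite (apply complete-case filtering first)")
        if self.ids is None:
            self.ids = np.array([f"ind{i}" for i in range(self.n)])

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def T(self) -> int:
        return self.y.shape[1]

    @property
    def joint(self) -> np.ndarray:
        """The stacked (n, T+1) observation matrix (y(t_1..t_T), z)."""
        key = "joint"
        if key not in self._cache:
            self._cache[key] = np.column_stack([self.y, self.z])
        return self._cache[key]

    def subset(self, idx: np.ndarray) -> "LongitudinalDataset":
        idx = np.asarray(idx)
        return LongitudinalDataset(
            y=self.y[idx], z=self.z[idx], grid=self.grid, ids=self.ids[idx]
        )

    def permuted(self, order: np.ndarray) -> "LongitudinalDataset":
        """Rows reshuffled as whole (y, z) records — the permutation unit for
        empirical thresholds, preserving the dynamic-static correlation."""
        return self.subset(np.asarray(order))


@dataclass
class MarkerPartition:
    """Genotype classes at one marker over the individuals entering the fit.

    labels are contiguous class indices 0..J-1; `kept` maps them back to row
    indices of the parent dataset (individuals with missing genotype at the
    marker are excluded here).
    """

    labels: np.ndarray
    kept: np.ndarray
    class_counts: np.ndarray
    class_values: np.ndarray  # original genotype codes per class

    @property
    def J(self) -> int:
        return int(self.class_counts.size)

    @property
    def n(self) -> int:
        return int(self.labels.size)

    @staticmethod
    def from_genotypes(g: np.ndarray, min_class_size: int = 5) -> "MarkerPartition | None":
        """Build a partition from one marker's genotype column.

        Codes >= 0 are genotype classes; negative codes mark missing calls.
        Returns None (marker skipped) if any observed class is rarer than
        ``min_class_size`` or fewer than two classes segregate.
        """
        g = np.asarray(g)
        kept = np.flatnonzero(g >= 0)
        vals, labels = np.unique(g[kept], return_inverse=True)
        counts = np.bincount(labels)
        if vals.size < 2 or np.any(counts < min_class_size):
            return None
        return MarkerPartition(
            labels=labels, kept=kept, class_counts=counts, class_values=vals
        )
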