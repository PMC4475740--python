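"""Per-subject connectivity matrices and group-level summaries.

Functional connectivity between two regions is the Pearson correlation of
their conditioned time series.  For group statistics each coefficient is
mapped through Fisher's variance-stabilizing r-to-z transform
``z = atanh(r)``, which makes the sampling distribution approximately normal.
The matrix diagonal is stored as 0 and excluded from every mean, test and
count: an N-region matrix contributes N(N-1)/2 upper-triangle edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import Atlas
from .preprocess import SubjectTimeSeries

__all__ = [
    "ConnectivityMatrix",
    "CohortStack",
    "correlation_matrix",
    "fisher_z",
    "subject_connectivity",
    "group_mean_matrix",
    "group_difference_matrix",
    "mean_connectivity_strength",
]

logger = logging.getLogger(__name__)

_R_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class ConnectivityMatrix:
    """One subject's symmetric N x N Fisher-z matrix (diagonal fixed at 0)."""

    z: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 2 or z.shape[0] != z.shape[1]:
            raise ValueError(f"z must be square, got shape {z.shape}")
        if not np.allclose(z, z.T, atol=1e-10):
            raise ValueError("z matrix is not symmetric")
        if not np.all(np.isfinite(z)):
            raise ValueError("z matrix contains non-finite values")
        z = 0.5 * (z + z.T)
        np.fill_diagonal(z, 0.0)
        object.__setattr__(self, "z", z)

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]


def correlation_matrix(ts: SubjectTimeSeries) -> np.ndarray:
    """Pearson correlation between every pair of regional signals."""
    sd = ts.values.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = (
            [ts.region_names[k] for k in dead] if ts.region_names is not None else list(map(int, dead))
        )
        raise ValueError(f"zero-variance regions: {names}")
    r = np.corrcoef(ts.values, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return r


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher r-to-z transform, elementwise atanh with clipping at |r| = 1 - 1e-7.

    Square matrix input has its diagonal forced to 0 (self-connectivity is
    excluded by convention).  |r| beyond 1 + 1e-12 is a hard error; values
    clipped at the boundary are logged.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError(f"|r| > 1: max |r| = {np.max(np.abs(arr))}")
    n_clipped = int(np.count_nonzero(np.abs(arr) > _R_CLIP))
    clipped = np.clip(arr, -_R_CLIP, _R_CLIP)
    z = np.arctanh(clipped)
    if arr.ndim == 2 and arr.shape[0] == arr.shape[1]:
        n_clipped -= int(np.count_nonzero(np.abs(np.diag(arr)) > _R_CLIP))
        np.fill_diagonal(z, 0.0)
    if n_clipped > 0:
        logger.warning("fisher_z clipped %d off-diagonal coefficients at |r| = %g", n_clipped, _R_CLIP)
    if np.isscalar(r):
        return float(z)
    return z


def subject_connectivity(ts: SubjectTimeSeries, subject_id: str = "") -> ConnectivityMatrix:
    """Pearson correlation followed by the Fisher transform for one subject."""
    return ConnectivityMatrix(fisher_z(correlation_matrix(ts)), subject_id)


@dataclass(frozen=True)
class CohortStack:
    """Aligned subject matrices plus covariates (subject_id, group, mmse).

    ``z`` has shape (S, N, N) with subject order matching ``covariates`` rows;
    all matrices share one atlas node order.
    """

    z: np.ndarray
    covariates: pd.DataFrame
    atlas: Atlas

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        if z.ndim != 3 or z.shape[1] != z.shape[2]:
            raise ValueError(f"z must be (S, N, N), got shape {z.shape}")
        if z.shape[0] != len(self.covariates):
            raise ValueError(
                f"{z.shape[0]} matrices but {len(self.covariates)} covariate rows"
            )
        if z.shape[1] != self.atlas.n_regions:
            raise ValueError("matrix size does not match atlas")
        for col in ("subject_id", "group"):
            if col not in self.covariates.columns:
                raise ValueError(f"covariates missing column {col!r}")
        object.__setattr__(self, "z", z)

    @classmethod
    def from_matrices(
        cls, matrices: list[ConnectivityMatrix], covariates: pd.DataFrame, atlas: Atlas
    ) -> "CohortStack":
        return cls(np.stack([m.z for m in matrices]), covariates.reset_index(drop=True), atlas)

    @property
    def n_subjects(self) -> int:
        return self.z.shape[0]

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.covariates["group"]))

    def group_indices(self, group: str) -> np.ndarray:
        idx = np.flatnonzero((self.covariates["group"] == group).to_numpy())
        return idx

    def group_z(self, group: str) -> np.ndarray:
        idx = self.group_indices(group)
        if idx.size == 0:
            raise ValueError(f"group {group!r} has no subjects")
        return self.z[idx]

    def edge_values(self, group: str | None = None) -> np.ndarray:
        """Subjects x edges matrix of upper-triangle z values."""
        z = self.z if group is None else self.group_z(group)
        iu = np.triu_indices(self.atlas.n_regions, k=1)
        return z[:, iu[0], iu[1]]


def group_mean_matrix(stack: CohortStack, group: str, absolute: bool = True) -> np.ndarray:
    """Elementwise mean of z (or |z|) over a group's subjects."""
    z = stack.group_z(group)
    m = np.abs(z).mean(axis=0) if absolute else z.mean(axis=0)
    np.fill_diagonal(m, 0.0)
    return m


def group_difference_matrix(stack: CohortStack, group_a: str, group_b: str) -> np.ndarray:
    """Signed difference of group mean z matrices, A minus B."""
    return group_mean_matrix(stack, group_a, absolute=False) - group_mean_matrix(
        stack, group_b, absolute=False
    )


def mean_connectivity_strength(matrix: ConnectivityMatrix | np.ndarray, absolute: bool = True) -> float:
    """Mean over the N(N-1)/2 upper-triangle z values (|z| by default)."""
    z = matrix.z if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix, dtype=float)
    iu = np.triu_indices(z.shape[0], k=1)
    vals = z[iu]
    return float(np.abs(vals).mean() if absolute else vals.mean())
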