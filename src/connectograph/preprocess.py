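"""Signal conditioning for regional BOLD time series.

Two denoising stages, applied in this order:

1. Nuisance regression — ordinary least-squares projection of every regional
   signal onto the orthogonal complement of a design matrix holding an
   intercept, a linear drift term, the six rigid-body motion parameters, and
   the mean white-matter and CSF signals (10 columns).  When no nuisance set
   is available (e.g. synthetic regional data), the design degrades to
   intercept + drift; this mode is logged.
2. Temporal band-pass filtering, by default 0.01-0.08 Hz: a 2nd-order
   Butterworth band-pass applied forward-backward (zero phase) with reflective
   padding, the de-facto standard for resting-state pipelines.

Also provides regional extraction: averaging a 4D image over the voxels of
each labeled region, producing one representative time series per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .atlas import Atlas

__all__ = [
    "SubjectTimeSeries",
    "NuisanceSet",
    "regress_nuisance",
    "bandpass",
    "extract_regional_series",
    "read_nifti_pair",
    "write_nifti_pair",
    "read_motion_parameters",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectTimeSeries:
    """One subject's T x N regional signal matrix.

    ``values[t, k]`` is region ``k``'s signal at timepoint ``t``;
    ``sampling_interval`` is the repetition time in seconds (default 2.0 s).
    """

    values: np.ndarray
    sampling_interval: float = 2.0
    region_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError(f"values must be 2-D (T x N), got shape {v.shape}")
        if v.shape[0] < 10:
            raise ValueError(f"need at least 10 timepoints, got {v.shape[0]}")
        if not np.all(np.isfinite(v)):
            raise ValueError("time series contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.region_names is not None and len(self.region_names) != v.shape[1]:
            raise ValueError("region_names length does not match column count")
        object.__setattr__(self, "values", v)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "SubjectTimeSeries":
        return SubjectTimeSeries(values, self.sampling_interval, self.region_names)


@dataclass(frozen=True)
class NuisanceSet:
    """Nuisance regressors for one subject: 6 motion parameters + WM and CSF means."""

    motion: np.ndarray
    wm_mean: np.ndarray
    csf_mean: np.ndarray

    def __post_init__(self) -> None:
        motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
        if motion.shape[1] != 6:
            raise ValueError(f"motion must be T x 6, got shape {motion.shape}")
        wm = np.asarray(self.wm_mean, dtype=float).ravel()
        csf = np.asarray(self.csf_mean, dtype=float).ravel()
        if not (motion.shape[0] == wm.size == csf.size):
            raise ValueError("motion, wm_mean and csf_mean must share the same T")
        object.__setattr__(self, "motion", motion)
        object.__setattr__(self, "wm_mean", wm)
        object.__setattr__(self, "csf_mean", csf)

    @property
    def n_timepoints(self) -> int:
        return self.motion.shape[0]


def _design_matrix(n_timepoints: int, nuisance: NuisanceSet | None) -> tuple[np.ndarray, list[str]]:
    t = np.linspace(-1.0, 1.0, n_timepoints)
    cols = [np.ones(n_timepoints), t]
    names = ["intercept", "drift"]
    if nuisance is not None:
        for k in range(6):
            cols.append(nuisance.motion[:, k])
            names.append(f"motion{k + 1}")
        cols.append(nuisance.wm_mean)
        names.append("wm_mean")
        cols.append(nuisance.csf_mean)
        names.append("csf_mean")
    return np.column_stack(cols), names


def _collinear_columns(design: np.ndarray, names: list[str]) -> list[str]:
    """Name columns that add no rank beyond the preceding ones."""
    bad = []
    rank = 0
    for k in range(design.shape[1]):
        new_rank = np.linalg.matrix_rank(design[:, : k + 1])
        if new_rank == rank:
            bad.append(names[k])
        rank = new_rank
    return bad


def regress_nuisance(ts: SubjectTimeSeries, nuisance: NuisanceSet | None = None) -> SubjectTimeSeries:
    """Remove nuisance effects by least-squares projection.

    Each output column is the residual of the corresponding input column on
    the design matrix (intercept + linear drift + motion + WM + CSF when a
    :class:`NuisanceSet` is given, intercept + drift otherwise).  Residuals
    are orthogonal to every regressor, so the operation is idempotent.
    """
    if nuisance is None:
        logger.info("no nuisance set supplied; regressing intercept + linear drift only")
    elif nuisance.n_timepoints != ts.n_timepoints:
        raise ValueError(
            f"nuisance rows ({nuisance.n_timepoints}) do not match time series length ({ts.n_timepoints})"
        )
    design, names = _design_matrix(ts.n_timepoints, nuisance)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(design, names)
        raise ValueError(f"nuisance design matrix is rank deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, ts.values, rcond=None)
    return ts.with_values(ts.values - design @ beta)


def bandpass(ts: SubjectTimeSeries, low: float = 0.01, high: float = 0.08) -> SubjectTimeSeries:
    """Zero-phase Butterworth band-pass of every regional signal.

    A 2nd-order band-pass (4 poles) run forward and backward with reflective
    padding, so the pass band is preserved near unit gain, out-of-band
    components (including DC) are attenuated, and no phase shift is
    introduced.  ``high`` must lie below the Nyquist frequency
    1 / (2 * sampling_interval).
    """
    nyquist = 0.5 / ts.sampling_interval
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyquist} Hz")
    sos = sps.butter(2, [low, high], btype="bandpass", fs=1.0 / ts.sampling_interval, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if ts.n_timepoints <= padlen:
        raise ValueError(
            f"time series too short for stable filtering: T={ts.n_timepoints} <= padding {padlen}"
        )
    filtered = sps.sosfiltfilt(sos, ts.values, axis=0, padtype="even")
    return ts.with_values(np.ascontiguousarray(filtered))


def extract_regional_series(
    image: np.ndarray,
    labels: np.ndarray,
    atlas: Atlas,
    sampling_interval: float = 2.0,
) -> SubjectTimeSeries:
    """Average a 4D image over the voxels of each atlas region.

    Column ``k`` of the result is the unweighted mean over voxels whose label
    equals region ``k``'s ``label_value``, in atlas order.  Label codes absent
    from the atlas (background 0 always included) are ignored with a warning.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.ndim != 4:
        raise ValueError(f"image must be 4-D (X, Y, Z, T), got shape {image.shape}")
    if labels.shape != image.shape[:3]:
        raise ValueError(
            f"label volume shape {labels.shape} does not match image spatial shape {image.shape[:3]}"
        )
    known = set(int(v) for v in atlas.label_values)
    present = set(int(v) for v in np.unique(labels)) - {0}
    unknown = sorted(present - known)
    if unknown:
        logger.warning("ignoring label codes absent from atlas: %s", unknown)
    missing = [r.name for r in atlas.regions if r.label_value not in present]
    if missing:
        raise ValueError(f"atlas regions with zero voxels in label image: {missing}")
    n_t = image.shape[3]
    out = np.empty((n_t, atlas.n_regions))
    flat = image.reshape(-1, n_t)
    flat_labels = labels.ravel()
    for region in atlas.regions:
        mask = flat_labels == region.label_value
        out[:, region.index] = flat[mask].mean(axis=0)
    return SubjectTimeSeries(out, sampling_interval, tuple(atlas.names))


def read_nifti_pair(image_path, labels_path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4D functional image and its 3D integer label volume from NIfTI."""
    import nibabel as nib

    image = np.asarray(nib.load(str(image_path)).get_fdata(), dtype=float)
    labels = np.asarray(np.rint(nib.load(str(labels_path)).get_fdata()), dtype=int)
    return image, labels


def write_nifti_pair(image: np.ndarray, labels: np.ndarray, image_path, labels_path) -> None:
    """Write a (4D image, 3D label) pair as NIfTI with an identity affine."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), np.eye(4)), str(image_path))
    nib.save(nib.Nifti1Image(np.asarray(labels, dtype=np.int16), np.eye(4)), str(labels_path))


def read_motion_parameters(path) -> np.ndarray:
    """Read six rigid-body motion parameters from whitespace-delimited text (T x 6)."""
    motion = np.loadtxt(path, dtype=float)
    motion = np.atleast_2d(motion)
    if motion.shape[1] != 6:
        raise ValueError(f"expected 6 motion columns, got {motion.shape[1]}")
    return motion


def preprocess_subject(
    ts: SubjectTimeSeries,
    nuisance: NuisanceSet | None = None,
    low: float = 0.01,
    high: float = 0.08,
    skip_bandpass: bool = False,
) -> SubjectTimeSeries:
    """Full conditioning: nuisance regression, then band-pass filtering.

    The order (regression before filtering) is part of the contract: swapping
    the stages changes the output because filtering is not a projection onto
    the nuisance complement.
    """
    out = regress_nuisance(ts, nuisance)
    if not skip_bandpass:
        out = bandpass(out, low=low, high=high)
    return out
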