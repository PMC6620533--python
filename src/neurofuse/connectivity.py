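"""Functional-connectivity matrices from region time courses.

A subject's functional connectivity is the 68 × 68 matrix of Pearson
correlation coefficients between the mean BOLD time courses of every pair
of Desikan–Killiany regions.  Mean time courses may be supplied directly
(one row per region) or extracted here from a preprocessed 4-D volume and
an integer atlas labelmap on the same grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .atlas import AtlasDefinition, dk_atlas

__all__ = [
    "ConnectivityMatrix",
    "extract_mean_timecourses",
    "connectivity_matrix",
    "load_nifti_pair",
]

N_REGIONS = 68


@dataclass
class ConnectivityMatrix:
    """Symmetric 68 × 68 Pearson correlation matrix with unit diagonal.

    ``constant_regions`` lists canonical indices of regions whose time
    course was constant: their correlations are undefined and recorded as 0
    (off-diagonal) by documented convention.
    """

    values: np.ndarray
    constant_regions: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (N_REGIONS, N_REGIONS):
            raise ValueError(f"connectivity matrix must be {N_REGIONS}x{N_REGIONS}")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.nanmax(np.abs(v)) > 1 + 1e-9:
            raise ValueError("correlations must lie in [-1, 1]")


def extract_mean_timecourses(
    volume: np.ndarray,
    labelmap: np.ndarray,
    atlas: AtlasDefinition | None = None,
) -> np.ndarray:
    """Average a 4-D volume over each atlas region.

    Parameters
    ----------
    volume:
        4-D intensity array, shape ``(X, Y, Z, T)``.
    labelmap:
        3-D integer array on the same spatial grid; voxels are assigned to
        a region by exact label equality (no partial-volume weighting).

    Returns
    -------
    A ``(68, T)`` matrix, row ``r`` = mean over voxels labelled with atlas
    region ``r`` at each time point, rows in canonical atlas order.
    """
    atlas = atlas or dk_atlas()
    volume = np.asarray(volume, dtype=float)
    labelmap = np.asarray(labelmap)
    if volume.ndim != 4:
        raise ValueError(f"volume must be 4-D, got {volume.ndim}-D")
    if labelmap.shape != volume.shape[:3]:
        raise ValueError(
            f"labelmap shape {labelmap.shape} does not match volume grid {volume.shape[:3]}"
        )
    t = volume.shape[3]
    out = np.empty((atlas.n_regions, t))
    flat_vol = volume.reshape(-1, t)
    flat_lab = labelmap.reshape(-1)
    for idx, rid in enumerate(atlas.region_ids):
        mask = flat_lab == rid
        if not mask.any():
            raise ValueError(
                f"atlas region {atlas.region_names[idx]!r} (id {rid}) absent from labelmap"
            )
        out[idx] = flat_vol[mask].mean(axis=0)
    return out


def connectivity_matrix(timecourses: np.ndarray) -> ConnectivityMatrix:
    """Pearson functional connectivity between every pair of regions.

    Constant (zero-variance) rows make the correlation undefined; those
    entries are set to 0 with a warning rather than aborting, so one
    degenerate region cannot kill a cohort run.  The diagonal is exactly 1.
    """
    tc = np.asarray(timecourses, dtype=float)
    if tc.shape[0] != N_REGIONS:
        raise ValueError(f"expected {N_REGIONS} region rows, got {tc.shape[0]}")
    if tc.shape[1] < 3:
        raise ValueError(f"need at least 3 time points, got {tc.shape[1]}")
    sd = tc.std(axis=1)
    constant = np.flatnonzero(sd == 0.0)
    if constant.size:
        warnings.warn(
            f"{constant.size} region(s) have constant time courses; "
            "their correlations are recorded as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(tc)
    corr[~np.isfinite(corr)] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(values=corr, constant_regions=constant.tolist())


def load_nifti_pair(
    bold_path: str | Path, labels_path: str | Path
) -> tuple[np.ndarray, np.ndarray]:
    """Load a 4-D BOLD NIfTI and its 3-D integer labelmap."""
    import nibabel as nib

    bold = np.asanyarray(nib.load(str(bold_path)).dataobj, dtype=float)
    labels = np.asanyarray(nib.load(str(labels_path)).dataobj)
    labels = np.rint(labels).astype(int)
    return bold, labels


def connectivity_stack(timecourse_list: list[np.ndarray]) -> np.ndarray:
    """Connectivity matrices for a cohort: (n_subjects, 68, 68)."""
    return np.stack([connectivity_matrix(tc).values for tc in timecourse_list], axis=0)
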