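"""Morphometric features and the pairwise delta tensor.

Each Desikan–Killiany region is summarised by eight scalars computed from
the reconstructed cortical surface: surface area A (mm²), gray-matter
volume V (mm³), mean and SD of cortical thickness (mm), and four
curvature-derived quantities averaged over the region's vertices —

* mean-curvature index      MCI = (k1 + k2) / 2
* Gaussian curvature        K   = k1 · k2
* intrinsic curvature index ICI = max(K, 0)
* folding index             FI  = |k1| · (|k1| − |k2|)

with k1, k2 the principal curvatures at a vertex, ordered so |k1| ≥ |k2|
(hence FI ≥ 0, the surface-reconstruction tool's convention).

Rather than feeding raw region values to the classifiers, each subject is
represented by a 68 × 68 × 8 *delta tensor* of signed pairwise region
differences, Δ[i, j, f] = x[i, f] − x[j, f].  Any per-subject additive
offset shared by all regions (head size, age, scanner gain …) cancels in
the difference, which is the point of the construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import FEATURE_COLUMNS

__all__ = [
    "vertex_curvature_features",
    "summarize_region_features",
    "DeltaTensor",
    "build_delta_tensor",
]

N_REGIONS = 68
N_FEATURES = 8


def vertex_curvature_features(k1, k2):
    """Per-vertex curvature features (MCI, K, ICI, FI).

    Accepts scalars or arrays.  Principal curvatures are reordered by
    magnitude (|k1| ≥ |k2|) before the folding index, so FI is nonnegative.
    """
    k1 = np.asarray(k1, dtype=float)
    k2 = np.asarray(k2, dtype=float)
    if not (np.all(np.isfinite(k1)) and np.all(np.isfinite(k2))):
        raise ValueError("principal curvatures must be finite")
    a1, a2 = np.abs(k1), np.abs(k2)
    hi = np.maximum(a1, a2)
    lo = np.minimum(a1, a2)
    mci = (k1 + k2) / 2.0
    gauss = k1 * k2
    ici = np.maximum(gauss, 0.0)
    fi = hi * (hi - lo)
    return mci, gauss, ici, fi


def summarize_region_features(
    vertices: pd.DataFrame,
    region_volume: float,
    *,
    area_weighted: bool = False,
) -> pd.Series:
    """Aggregate vertex-level geometry into one region's feature vector.

    Parameters
    ----------
    vertices:
        Frame with columns ``k1``, ``k2``, ``thickness``, ``vertex_area``.
    region_volume:
        Gray-matter volume of the region in mm³ (computed upstream from the
        segmentation; passed through).
    area_weighted:
        If true, weight the curvature averages by vertex area instead of
        the default unweighted vertex mean.
    """
    if len(vertices) == 0:
        raise ValueError("region has no vertices")
    required = {"k1", "k2", "thickness", "vertex_area"}
    missing = required - set(vertices.columns)
    if missing:
        raise ValueError(f"vertex table missing columns: {sorted(missing)}")
    thick = vertices["thickness"].to_numpy(dtype=float)
    areas = vertices["vertex_area"].to_numpy(dtype=float)
    if np.any(areas < 0) or np.any(thick < 0):
        raise ValueError("vertex_area and thickness must be nonnegative")
    mci, gauss, ici, fi = vertex_curvature_features(
        vertices["k1"].to_numpy(dtype=float), vertices["k2"].to_numpy(dtype=float)
    )
    if area_weighted:
        if areas.sum() <= 0:
            raise ValueError("area weighting requires positive total vertex area")
        w = areas / areas.sum()
        avg = lambda v: float(np.sum(w * v))  # noqa: E731
    else:
        avg = lambda v: float(np.mean(v))  # noqa: E731
    t_sd = float(np.std(thick, ddof=1)) if len(thick) > 1 else 0.0
    return pd.Series(
        {
            "A": float(areas.sum()),
            "V": float(region_volume),
            "T_mean": float(np.mean(thick)),
            "T_sd": t_sd,
            "MCI": avg(mci),
            "K": avg(gauss),
            "ICI": avg(ici),
            "FI": avg(fi),
        },
        index=list(FEATURE_COLUMNS),
    )


@dataclass
class DeltaTensor:
    """Antisymmetric 68 × 68 × 8 pairwise region-difference tensor."""

    values: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        if self.values.shape != (N_REGIONS, N_REGIONS, len(self.feature_names)):
            raise ValueError(
                f"delta tensor must be {N_REGIONS}x{N_REGIONS}x{len(self.feature_names)},"
                f" got {self.values.shape}"
            )

    def slab(self, feature: str) -> np.ndarray:
        """The 68 × 68 antisymmetric matrix of one feature."""
        return self.values[:, :, self.feature_names.index(feature)]


def build_delta_tensor(features: pd.DataFrame | np.ndarray) -> DeltaTensor:
    """Build a subject's delta tensor from its 68 × 8 region feature table.

    ``values[i, j, f] = feature_f(region_i) − feature_f(region_j)``; the
    result is exactly antisymmetric in (i, j) with a zero diagonal.
    """
    if isinstance(features, pd.DataFrame):
        missing = [c for c in FEATURE_COLUMNS if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        x = features[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
        names = FEATURE_COLUMNS
    else:
        x = np.asarray(features, dtype=float)
        names = FEATURE_COLUMNS
    if x.shape != (N_REGIONS, N_FEATURES):
        raise ValueError(f"expected a {N_REGIONS}x{N_FEATURES} table, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature table contains non-finite values")
    delta = x[:, None, :] - x[None, :, :]
    return DeltaTensor(values=delta, feature_names=names)


def delta_stack(tables: list[pd.DataFrame | np.ndarray]) -> np.ndarray:
    """Stack per-subject delta tensors into an (n_subjects, 68, 68, 8) array."""
    return np.stack([build_delta_tensor(t).values for t in tables], axis=0)
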