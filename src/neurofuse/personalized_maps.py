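"""Personalized per-region autism-probability maps.

For each subject, every region i is assigned the highest autism-class
probability among all local classifiers that involve it:

    V_f(i) = max_{j ≠ i} P_F(i, j)                      (connectivity)
    V_s(i) = max_{j ≠ i, f} P_S(i, j, f)                (morphometry)

The two 68-vectors form the subject's personalized map — a region-level
picture of where that individual's features look most autism-like,
regardless of the global diagnosis.  Maps are exported as a tidy CSV and,
optionally, per-subject schematic colormap figures (a 4 × 17 region grid;
surface rendering is out of scope).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import AtlasDefinition, dk_atlas

__all__ = ["PersonalizedMap", "build_personalized_map", "export_map_table"]

N_REGIONS = 68


@dataclass
class PersonalizedMap:
    """A subject's per-region maximal autism probabilities.

    Either vector may be ``None`` when the corresponding modality was not
    available for the subject.
    """

    subject_id: str
    V_f: np.ndarray | None = None
    V_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name, v in (("V_f", self.V_f), ("V_s", self.V_s)):
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.shape != (N_REGIONS,):
                raise ValueError(f"{name} must have {N_REGIONS} entries")
            if np.nanmin(v) < 0 or np.nanmax(v) > 1:
                raise ValueError(f"{name} entries must lie in [0, 1]")


def _row_max(mat: np.ndarray, what: str) -> np.ndarray:
    """Max over each row, ignoring NaN (excluded) entries; all-NaN row errors."""
    valid = np.isfinite(mat)
    flat = valid.reshape(N_REGIONS, -1)
    if not flat.any(axis=1).all():
        bad = int(np.flatnonzero(~flat.any(axis=1))[0]) + 1
        raise ValueError(f"region {bad}: every {what} entry is excluded")
    with np.errstate(invalid="ignore"):
        return np.nanmax(mat.reshape(N_REGIONS, -1), axis=1)


def build_personalized_map(
    subject_id: str,
    P_F: np.ndarray | None = None,
    P_S: np.ndarray | None = None,
) -> PersonalizedMap:
    """Row-wise maxima of a subject's local probability structures.

    ``P_F`` is the subject's 68 × 68 connectivity probability matrix and
    ``P_S`` the 68 × 68 × 8 structural one; excluded entries (the diagonal)
    are NaN and ignored in the max.  The max runs over all partners j ≠ i
    (and all feature slabs for the structural map).
    """
    v_f = v_s = None
    if P_F is not None:
        P_F = np.asarray(P_F, dtype=float)
        if P_F.shape != (N_REGIONS, N_REGIONS):
            raise ValueError("P_F must be 68x68")
        v_f = _row_max(P_F, "connectivity")
    if P_S is not None:
        P_S = np.asarray(P_S, dtype=float)
        if P_S.shape != (N_REGIONS, N_REGIONS, 8):
            raise ValueError("P_S must be 68x68x8")
        v_s = _row_max(P_S, "structural")
    return PersonalizedMap(subject_id=subject_id, V_f=v_f, V_s=v_s)


def export_map_table(
    maps: Sequence[PersonalizedMap] | Iterable[PersonalizedMap],
    path: str | Path,
    *,
    atlas: AtlasDefinition | None = None,
    figures: bool = False,
    figure_dir: str | Path | None = None,
    cmap: str = "viridis",
) -> pd.DataFrame:
    """Write personalized maps to CSV (and optional per-subject figures).

    The CSV has one row per subject × region with columns
    ``subject_id, region, V_f, V_s`` (region names in atlas order; missing
    modality written empty).  When ``figures`` is true, one schematic
    colormap figure per subject is saved under ``figure_dir`` (defaults to
    the CSV's directory), regions laid out on a 4 × 17 grid.
    """
    atlas = atlas or dk_atlas()
    maps = list(maps)
    path = Path(path)
    rows = []
    for m in maps:
        for idx, region in enumerate(atlas.region_names):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "region": region,
                    "V_f": None if m.V_f is None else float(m.V_f[idx]),
                    "V_s": None if m.V_s is None else float(m.V_s[idx]),
                }
            )
    table = pd.DataFrame(rows, columns=["subject_id", "region", "V_f", "V_s"])
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    if figures:
        _write_figures(maps, atlas, Path(figure_dir or path.parent), cmap)
    return table


def _write_figures(
    maps: list[PersonalizedMap],
    atlas: AtlasDefinition,
    outdir: Path,
    cmap: str,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir.mkdir(parents=True, exist_ok=True)
    for m in maps:
        panels = [(t, v) for t, v in (("fMRI", m.V_f), ("sMRI", m.V_s)) if v is not None]
        fig, axes = plt.subplots(
            len(panels), 1, figsize=(10, 3 * len(panels)), squeeze=False
        )
        for ax, (title, vec) in zip(axes[:, 0], panels):
            grid = np.asarray(vec, dtype=float).reshape(4, 17)
            im = ax.imshow(grid, vmin=0, vmax=1, cmap=cmap)
            ax.set_title(f"{m.subject_id} — {title} personalized map")
            ax.set_xticks([])
            ax.set_yticks([])
            fig.colorbar(im, ax=ax, label="autism probability")
        fig.tight_layout()
        fig.savefig(outdir / f"map_{m.subject_id}.png", dpi=100)
        plt.close(fig)
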