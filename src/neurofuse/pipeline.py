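"""End-to-end orchestration: features → local grid → prefix scan → fusion → maps.

`run_pipeline` takes an in-memory cohort (manifest plus per-subject
morphometry tables and time courses), runs both modality branches and the
fusion stage, and returns everything downstream consumers need: ranked
feature lists, prefix-scan curves, per-modality and fused metrics, and the
personalized per-region probability maps.

Two evaluation modes exist for the global stage.  ``"ranked"`` (default)
ranks features once on the whole cohort's out-of-fold local accuracies and
then cross-validates the global classifier on the selected prefixes — the
two-stage protocol as published, which leaks ranking information into the
global estimate.  ``"nested"`` re-ranks features inside every outer
training fold before evaluating that fold's test subjects, giving an
honest (typically lower) estimate.  Both are available so the optimism of
the ranked protocol can be measured rather than guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .ados_stats import flatten_fmri, flatten_smri
from .connectivity import connectivity_matrix
from .fusion import (
    FAST_GRID,
    ClassificationMetrics,
    FusionModel,
    PrefixScanCurve,
    _metrics_from_oof,
    concatenate_prefixes,
    evaluate_feature_prefix,
    incremental_selection,
)
from .io_formats import CohortManifest
from .local_classification import (
    LocalGridResult,
    _as_binary_labels,
    evaluate_local_grid,
    local_probability_matrices,
    rank_features,
)
from .morphometry import build_delta_tensor
from .personalized_maps import PersonalizedMap, build_personalized_map
from .synthetic_cohort import CohortData

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    subject_ids: list[str]
    labels: np.ndarray
    smri_local: LocalGridResult | None
    fmri_local: LocalGridResult | None
    smri_ranking: pd.DataFrame | None
    fmri_ranking: pd.DataFrame | None
    smri_curve: PrefixScanCurve | None
    fmri_curve: PrefixScanCurve | None
    fusion: FusionModel | None
    maps: list[PersonalizedMap] = field(default_factory=list)
    nested_metrics: ClassificationMetrics | None = None

    def metrics_summary(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for name, curve in (("sMRI", self.smri_curve), ("fMRI", self.fmri_curve)):
            if curve is not None:
                at = int(np.flatnonzero(curve.lengths == curve.chosen_length)[0])
                out[name] = {
                    "chosen_length": curve.chosen_length,
                    "accuracy": float(curve.accuracy[at]),
                    "sensitivity": float(curve.sensitivity[at]),
                    "specificity": float(curve.specificity[at]),
                    "auc": float(curve.auc[at]),
                }
        if self.fusion is not None:
            out["fused"] = {
                "fused_length": self.fusion.fused_length,
                **self.fusion.metrics.as_dict(),
            }
        if self.nested_metrics is not None:
            out["fused_nested"] = self.nested_metrics.as_dict()
        return out


def _cohort_matrices(
    cohort: CohortData,
) -> tuple[list[str], np.ndarray, np.ndarray | None, np.ndarray | None, list[str]]:
    manifest = cohort.manifest
    ids = [s.subject_id for s in manifest]
    labels = manifest.labels
    smri_flat = None
    if cohort.morphometry:
        deltas = np.stack(
            [build_delta_tensor(cohort.morphometry[sid]).values for sid in ids]
        )
        smri_flat = flatten_smri(deltas)
    fmri_flat = None
    fmri_ids = [
        sid for sid in ids if manifest.modality_availability[sid][1] and sid in cohort.timecourses
    ]
    if fmri_ids:
        conns = np.stack(
            [connectivity_matrix(cohort.timecourses[sid]).values for sid in fmri_ids]
        )
        fmri_flat = flatten_fmri(conns)
    return ids, labels, smri_flat, fmri_flat, fmri_ids


def run_pipeline(
    cohort: CohortData,
    *,
    k: int = 7,
    folds: int = 4,
    seed: int = 0,
    grid: Mapping[str, Sequence] | None = None,
    max_prefix: int = 100,
    mode: str = "ranked",
    build_maps: bool = True,
) -> PipelineResult:
    """Run the full two-stage diagnosis pipeline on a cohort.

    Fusion uses only subjects with both modalities available; per-modality
    results use every subject with that modality.  ``grid`` defaults to the
    full random-forest search grid; pass :data:`~neurofuse.fusion.FAST_GRID`
    to skip the inner search.
    """
    if mode not in ("ranked", "nested"):
        raise ValueError(f"mode must be 'ranked' or 'nested', got {mode!r}")
    ids, labels, smri_flat, fmri_flat, fmri_ids = _cohort_matrices(cohort)
    y_all = _as_binary_labels(labels)
    id_pos = {sid: p for p, sid in enumerate(ids)}

    smri_local = smri_ranking = smri_curve = None
    if smri_flat is not None:
        smri_local = evaluate_local_grid(
            smri_flat, y_all, n_folds=folds, k=k, seed=seed
        )
        smri_ranking = rank_features(smri_local, "sMRI")

    fmri_local = fmri_ranking = fmri_curve = None
    y_fmri = None
    if fmri_flat is not None:
        y_fmri = y_all[[id_pos[s] for s in fmri_ids]]
        fmri_local = evaluate_local_grid(
            fmri_flat, y_fmri, n_folds=folds, k=k, seed=seed
        )
        fmri_ranking = rank_features(fmri_local, "fMRI")

    # fusion-eligible subjects: both modalities present
    fusion_model = None
    nested_metrics = None
    if smri_flat is not None and fmri_flat is not None:
        fus_ids = [s for s in fmri_ids]
        smri_rows = [id_pos[s] for s in fus_ids]
        fmri_rows = {s: r for r, s in enumerate(fmri_ids)}
        x_s = smri_flat[smri_rows]
        x_f = fmri_flat[[fmri_rows[s] for s in fus_ids]]
        y_fus = y_all[smri_rows]

        smri_cols = smri_ranking["column"].to_numpy()[:max_prefix]
        fmri_cols = fmri_ranking["column"].to_numpy()[:max_prefix]
        smri_curve = incremental_selection(
            smri_flat[:, smri_cols], y_all, max_prefix=max_prefix,
            folds=folds, grid=grid, seed=seed,
        )
        fmri_curve = incremental_selection(
            x_f[:, fmri_cols], y_fus, max_prefix=max_prefix,
            folds=folds, grid=grid, seed=seed,
        )
        fusion_model = FusionModel(
            smri_length=smri_curve.chosen_length,
            fmri_length=fmri_curve.chosen_length,
            fused_length=smri_curve.chosen_length + fmri_curve.chosen_length,
            classifier_spec={
                "type": "random_forest",
                "criterion": "gini",
                "grid": dict(grid if grid is not None else FAST_GRID),
                "folds": folds,
                "seed": seed,
            },
            metrics=evaluate_feature_prefix(
                concatenate_prefixes(
                    x_s[:, smri_cols], x_f[:, fmri_cols],
                    smri_curve.chosen_length, fmri_curve.chosen_length,
                ),
                y_fus, folds=folds, grid=grid, seed=seed,
            ),
        )
        if mode == "nested":
            nested_metrics = _nested_fused_metrics(
                x_s, x_f, y_fus, k=k, folds=folds, seed=seed,
                grid=grid, max_prefix=max_prefix,
            )
    elif smri_flat is not None and smri_ranking is not None:
        smri_cols = smri_ranking["column"].to_numpy()[:max_prefix]
        smri_curve = incremental_selection(
            smri_flat[:, smri_cols], y_all, max_prefix=max_prefix,
            folds=folds, grid=grid, seed=seed,
        )
    elif fmri_flat is not None and fmri_ranking is not None:
        fmri_cols = fmri_ranking["column"].to_numpy()[:max_prefix]
        fmri_curve = incremental_selection(
            fmri_flat[:, fmri_cols], y_fmri, max_prefix=max_prefix,
            folds=folds, grid=grid, seed=seed,
        )

    maps: list[PersonalizedMap] = []
    if build_maps:
        mats = local_probability_matrices(fmri=fmri_local, smri=smri_local)
        fmri_row = {s: r for r, s in enumerate(fmri_ids)}
        for pos, sid in enumerate(ids):
            p_s = mats.P_S[pos] if mats.P_S is not None else None
            p_f = (
                mats.P_F[fmri_row[sid]]
                if mats.P_F is not None and sid in fmri_row
                else None
            )
            if p_s is None and p_f is None:
                continue
            maps.append(build_personalized_map(sid, P_F=p_f, P_S=p_s))

    return PipelineResult(
        subject_ids=ids,
        labels=labels,
        smri_local=smri_local,
        fmri_local=fmri_local,
        smri_ranking=smri_ranking,
        fmri_ranking=fmri_ranking,
        smri_curve=smri_curve,
        fmri_curve=fmri_curve,
        fusion=fusion_model,
        maps=maps,
        nested_metrics=nested_metrics,
    )


def _nested_fused_metrics(
    x_s: np.ndarray,
    x_f: np.ndarray,
    y: np.ndarray,
    *,
    k: int,
    folds: int,
    seed: int,
    grid: Mapping[str, Sequence] | None,
    max_prefix: int,
) -> ClassificationMetrics:
    """Honest fused estimate: rank, scan and select inside each outer fold."""
    grid = dict(grid if grid is not None else FAST_GRID)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    prob = np.empty(y.size)
    for tr, te in skf.split(x_s, y):
        chosen_cols = []
        for flat, modality in ((x_s, "sMRI"), (x_f, "fMRI")):
            local = evaluate_local_grid(
                flat[tr], y[tr], n_folds=folds, k=k, seed=seed
            )
            ranking = rank_features(local, modality)
            cols = ranking["column"].to_numpy()[:max_prefix]
            curve = incremental_selection(
                flat[tr][:, cols], y[tr], max_prefix=max_prefix,
                folds=folds, grid=grid, seed=seed,
            )
            chosen_cols.append(cols[: curve.chosen_length])
        cols_s, cols_f = chosen_cols
        xtr = np.hstack([x_s[tr][:, cols_s], x_f[tr][:, cols_f]])
        xte = np.hstack([x_s[te][:, cols_s], x_f[te][:, cols_f]])
        params = {kk: v[0] for kk, v in grid.items()}
        rf = RandomForestClassifier(
            criterion="gini", random_state=seed, n_jobs=1, **params
        )
        rf.fit(xtr, y[tr])
        prob[te] = rf.predict_proba(xte)[:, 1]
    return _metrics_from_oof(y, prob)
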