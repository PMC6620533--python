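"""Synthetic cohorts with the statistical structure the pipeline assumes.

The study cohort (restricted-access) contained 185 adolescents — 72 ASD
(33 M / 39 F) and 113 TD (49 M / 64 F), ages ≈ 13 ± 3 y, 61 ASD subjects
with an ADOS total score in 1–24, and 7 subjects with unusable resting-
state data.  This module generates cohorts of that shape with *planted*,
recoverable effects:

* morphometry — each region × feature value is a region-specific Gaussian
  baseline shared by both classes, plus a per-subject per-feature global
  offset (a head-size/scanner confound constant across regions, which the
  pairwise delta tensor must cancel), plus noise; ASD subjects receive
  configured mean shifts (in within-subject noise-SD units) at planted
  (region, feature) elements;
* connectivity — region time courses are zero-mean multivariate Gaussian
  draws whose correlation matrix is a low-rank-plus-diagonal base
  structure, with class-specific deltas added on planted region pairs in
  correlation space (kept exactly, subject to a positive-definiteness
  check);
* severity — an ADOS-like integer score for a subset of ASD subjects,
  built as a clipped, rounded affine combination of the subject's realized
  planted-effect deviations plus noise, so configured features genuinely
  correlate with severity.

Ground truth (the planted elements) is returned alongside the data and
written to a sidecar JSON by :func:`generate_cohort`, so recovery can be
scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .atlas import dk_atlas
from .io_formats import FEATURE_COLUMNS, CohortManifest, SubjectRecord

__all__ = [
    "PlantedShift",
    "PlantedEdge",
    "GeneratorConfig",
    "CohortData",
    "generate_morphometry",
    "generate_timecourses",
    "generate_severity",
    "generate_cohort_arrays",
    "generate_cohort",
]

N_REGIONS = 68
N_FEATURES = 8

# Per-feature baseline level, between-region spread, and within-subject
# noise SD, on roughly FreeSurfer-like scales:
# A mm², V mm³, thickness mm, curvatures 1/mm and 1/mm².
_FEATURE_LEVELS = {
    "A": (2500.0, 900.0, 120.0),
    "V": (6500.0, 2200.0, 300.0),
    "T_mean": (2.55, 0.25, 0.10),
    "T_sd": (0.55, 0.08, 0.04),
    "MCI": (0.130, 0.020, 0.008),
    "K": (0.025, 0.012, 0.004),
    "ICI": (0.040, 0.015, 0.005),
    "FI": (0.065, 0.025, 0.009),
}
# Per-subject global offset SD, as a multiple of the within-subject noise
# SD — the confound the delta tensor is there to cancel.
_GLOBAL_OFFSET_SD = 2.0

# Table-1 demographics: (count, age mean, age SD) per (class, sex).
_DEMOGRAPHICS = {
    ("ASD", "M"): (33, 13.07, 2.75),
    ("ASD", "F"): (39, 13.53, 2.58),
    ("TD", "M"): (49, 13.04, 2.68),
    ("TD", "F"): (64, 12.8125, 3.17),
}


@dataclass(frozen=True)
class PlantedShift:
    """A class-discriminative morphometric effect: ASD mean shift at one
    (region, feature) element.

    ``shift_sd`` is measured in SD units of the pairwise delta feature the
    classifier actually sees (a region difference has √2 × the per-region
    noise SD), so ``shift_sd = d`` gives the planted delta features a
    standardized class separation of d."""

    region: int  # 1-based canonical index
    feature: int  # 1-based slab, order of FEATURE_COLUMNS
    shift_sd: float

    def __post_init__(self) -> None:
        if not (1 <= self.region <= N_REGIONS):
            raise ValueError(f"region out of range: {self.region}")
        if not (1 <= self.feature <= N_FEATURES):
            raise ValueError(f"feature slab out of range: {self.feature}")


@dataclass(frozen=True)
class PlantedEdge:
    """A class-discriminative connectivity effect: ASD correlation delta
    on one region pair."""

    i: int
    j: int
    delta: float

    def __post_init__(self) -> None:
        if not (1 <= self.i < self.j <= N_REGIONS):
            raise ValueError(f"edge must satisfy 1 <= i < j <= 68: ({self.i},{self.j})")
        if not (-1.0 < self.delta < 1.0):
            raise ValueError("correlation delta must lie in (-1, 1)")


# Default planted effects: five moderate structural shifts and five
# connectivity deltas on disjoint region pairs, spread over both
# hemispheres and several feature families — the kind of distributed,
# medium-effect-size signal the classifier is designed to aggregate.
_DEFAULT_SHIFTS = (
    PlantedShift(7, 1, 1.5),   # lh inferiorparietal, surface area
    PlantedShift(23, 8, 1.5),  # lh precentral, folding index
    PlantedShift(40, 2, 1.5),  # rh fusiform, volume
    PlantedShift(55, 4, 1.5),  # rh posteriorcingulate, thickness SD
    PlantedShift(62, 5, 1.5),  # rh superiortemporal, mean curvature
)
_DEFAULT_EDGES = (
    PlantedEdge(3, 47, 0.4),
    PlantedEdge(10, 22, 0.4),
    PlantedEdge(15, 60, 0.4),
    PlantedEdge(28, 35, 0.4),
    PlantedEdge(41, 56, 0.4),
)


@dataclass
class GeneratorConfig:
    """Everything the generator needs; defaults mirror the study cohort.

    ``severity_weights`` maps planted elements (by position: ``("smri", k)``
    or ``("fmri", k)``) to affine weights in the severity model; elements
    absent from the map do not drive severity.  ``severity_noise_sd`` is
    the SD of the additive Gaussian noise on the standardized severity
    scale.  With the default two structural + one connectivity driver at
    weight 1 and noise 0.6, each driving pairwise feature has a designed
    severity correlation of about 0.39 (= 1 / (√2 · √3.36) for a delta
    feature); a single driver at weight 1 with the same noise gives ≈ 0.6.
    """

    n_asd: int = 72
    n_td: int = 113
    t_points: int = 180
    planted_smri: tuple[PlantedShift, ...] = _DEFAULT_SHIFTS
    planted_edges: tuple[PlantedEdge, ...] = _DEFAULT_EDGES
    severity_weights: dict = field(
        default_factory=lambda: {("smri", 0): 1.0, ("smri", 1): 1.0, ("fmri", 0): 1.0}
    )
    severity_noise_sd: float = 0.6
    noise_sd: float = 1.0
    n_ados: int = 61
    n_missing_fmri: int = 7
    seed: int = 0
    #: seed of the fixed base structure (region baselines, connectivity
    #: factor model) — deliberately separate from the cohort seed so that
    #: different cohorts share one "population".
    structure_seed: int = 20210


    def __post_init__(self) -> None:
        if self.n_asd < 2 or self.n_td < 2:
            raise ValueError("need at least 2 subjects per class")
        if self.t_points < 3:
            raise ValueError("need at least 3 time points")
        if self.n_ados > self.n_asd:
            raise ValueError("n_ados cannot exceed n_asd")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for key in self.severity_weights:
            mod, k = key
            pool = self.planted_smri if mod == "smri" else self.planted_edges
            if not (0 <= k < len(pool)):
                raise ValueError(f"severity weight refers to missing element {key}")


# ---------------------------------------------------------------------------
# base structures (deterministic given structure_seed)


def _region_baselines(structure_seed: int) -> np.ndarray:
    """(68, 8) baseline means, region-specific, shared by both classes."""
    rng = np.random.default_rng(structure_seed)
    base = np.empty((N_REGIONS, N_FEATURES))
    for f, name in enumerate(FEATURE_COLUMNS):
        level, spread, _ = _FEATURE_LEVELS[name]
        base[:, f] = level + spread * rng.standard_normal(N_REGIONS)
    # keep strictly-positive quantities positive
    for f, name in enumerate(FEATURE_COLUMNS):
        if name in ("A", "V", "T_mean", "T_sd", "ICI", "FI"):
            level = _FEATURE_LEVELS[name][0]
            base[:, f] = np.maximum(base[:, f], 0.05 * level)
    return base


def _noise_scales() -> np.ndarray:
    return np.array([_FEATURE_LEVELS[n][2] for n in FEATURE_COLUMNS])


def _base_correlation(structure_seed: int, rank: int = 6) -> np.ndarray:
    """Low-rank-plus-diagonal base correlation structure (68 × 68)."""
    rng = np.random.default_rng(structure_seed + 1)
    loadings = rng.standard_normal((N_REGIONS, rank)) * 0.35
    cov = loadings @ loadings.T
    cov[np.diag_indices(N_REGIONS)] += 1.0
    d = np.sqrt(np.diag(cov))
    return cov / np.outer(d, d)


def _class_correlation(config: GeneratorConfig, class_label: str) -> np.ndarray:
    corr = _base_correlation(config.structure_seed).copy()
    if class_label == "ASD":
        for e in config.planted_edges:
            i, j = e.i - 1, e.j - 1
            corr[i, j] += e.delta
            corr[j, i] += e.delta
    if np.max(np.abs(corr - np.diag(np.diag(corr)))) >= 1.0:
        raise ValueError(
            "planted correlation deltas push an entry outside (-1, 1); use smaller deltas"
        )
    eigmin = float(np.linalg.eigvalsh(corr)[0])
    if eigmin <= 1e-6:
        raise ValueError(
            f"target correlation matrix not positive definite (min eig {eigmin:.2e});"
            " use smaller planted deltas"
        )
    return corr


# ---------------------------------------------------------------------------
# per-subject draws


def generate_morphometry(
    config: GeneratorConfig,
    class_label: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One subject's 68 × 8 region feature table.

    Baseline + per-subject global offset (constant across regions within a
    feature) + Gaussian noise; ASD subjects additionally receive the
    planted mean shifts.  The global offset is the confound the delta
    tensor cancels by construction.
    """
    base = _region_baselines(config.structure_seed)
    scales = _noise_scales() * config.noise_sd
    offsets = _GLOBAL_OFFSET_SD * scales * rng.standard_normal(N_FEATURES)
    values = base + offsets + scales * rng.standard_normal((N_REGIONS, N_FEATURES))
    if class_label == "ASD":
        # shift_sd is on the delta-feature scale; a region difference has
        # sqrt(2) times the per-region noise SD
        for s in config.planted_smri:
            values[s.region - 1, s.feature - 1] += (
                s.shift_sd * np.sqrt(2.0) * scales[s.feature - 1]
            )
    atlas = dk_atlas()
    return pd.DataFrame(
        values, index=list(atlas.region_names), columns=list(FEATURE_COLUMNS)
    )


def generate_timecourses(
    config: GeneratorConfig,
    class_label: str,
    rng: np.random.Generator,
    *,
    cholesky: np.ndarray | None = None,
) -> np.ndarray:
    """One subject's 68 × T region time courses.

    Zero-mean multivariate Gaussian with the class correlation matrix;
    pass a precomputed ``cholesky`` factor to amortize across a cohort.
    """
    if cholesky is None:
        cholesky = np.linalg.cholesky(_class_correlation(config, class_label))
    return cholesky @ rng.standard_normal((N_REGIONS, config.t_points))


def _severity_deviations(
    config: GeneratorConfig,
    morph: pd.DataFrame,
    conn: np.ndarray,
) -> dict[tuple[str, int], float]:
    """Standardized realized deviations of the severity-driving elements.

    Structural deviations are offset-free: the subject's mean deviation
    across regions (the global confound) is subtracted first, so severity
    tracks the region-specific signal — the same signal the delta features
    carry — rather than head size.
    """
    base = _region_baselines(config.structure_seed)
    scales = _noise_scales() * config.noise_sd
    base_corr = _base_correlation(config.structure_seed)
    values = morph.to_numpy()
    resid = values - base
    resid = resid - resid.mean(axis=0, keepdims=True)  # remove global offset
    devs: dict[tuple[str, int], float] = {}
    for key in config.severity_weights:
        mod, k = key
        if mod == "smri":
            s = config.planted_smri[k]
            r, f = s.region - 1, s.feature - 1
            devs[key] = resid[r, f] / scales[f]
        else:
            e = config.planted_edges[k]
            rho0 = base_corr[e.i - 1, e.j - 1]
            sd = (1.0 - rho0**2) / np.sqrt(max(config.t_points - 3, 1))
            devs[key] = (conn[e.i - 1, e.j - 1] - rho0) / sd
    return devs


def generate_severity(
    config: GeneratorConfig,
    deviations: dict[tuple[str, int], float],
    rng: np.random.Generator,
) -> int:
    """ADOS-like total score from a subject's planted-effect deviations.

    A weighted sum of the standardized deviations plus Gaussian noise is
    mapped affinely onto the ADOS scale and clipped to [1, 24].
    """
    z = sum(
        w * deviations.get(key, 0.0) for key, w in config.severity_weights.items()
    )
    z += config.severity_noise_sd * rng.standard_normal()
    total_var = (
        sum(w**2 for w in config.severity_weights.values())
        + config.severity_noise_sd**2
    )
    z /= np.sqrt(total_var) if total_var > 0 else 1.0
    return int(np.clip(np.rint(12.0 + 4.5 * z), 1, 24))


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class CohortData:
    """An in-memory synthetic cohort plus its ground truth."""

    manifest: CohortManifest
    morphometry: dict[str, pd.DataFrame]
    timecourses: dict[str, np.ndarray]
    ground_truth: dict


def _demographic_plan(config: GeneratorConfig) -> list[tuple[str, str, float, float]]:
    """(label, sex, age_mean, age_sd) per subject, sexes in Table-1 ratio."""
    plan: list[tuple[str, str, float, float]] = []
    for label, n in (("ASD", config.n_asd), ("TD", config.n_td)):
        nm_ref = _DEMOGRAPHICS[(label, "M")][0]
        nf_ref = _DEMOGRAPHICS[(label, "F")][0]
        n_m = int(round(n * nm_ref / (nm_ref + nf_ref)))
        for idx in range(n):
            sex = "M" if idx < n_m else "F"
            _, mean, sd = _DEMOGRAPHICS[(label, sex)]
            plan.append((label, sex, mean, sd))
    return plan


def generate_cohort_arrays(config: GeneratorConfig) -> CohortData:
    """Generate a full cohort in memory, deterministically from the seed."""
    rng = np.random.default_rng(config.seed)
    chol = {
        label: np.linalg.cholesky(_class_correlation(config, label))
        for label in ("ASD", "TD")
    }
    plan = _demographic_plan(config)
    n_total = len(plan)
    width = len(str(n_total))
    # which ASD subjects get an ADOS report, which subjects lose fMRI
    asd_positions = [p for p, (lab, *_rest) in enumerate(plan) if lab == "ASD"]
    ados_set = set(rng.choice(asd_positions, size=config.n_ados, replace=False).tolist())
    missing_fmri = set(
        rng.choice(n_total, size=min(config.n_missing_fmri, n_total), replace=False).tolist()
    )

    records: list[SubjectRecord] = []
    availability: dict[str, tuple[bool, bool]] = {}
    morph: dict[str, pd.DataFrame] = {}
    tcs: dict[str, np.ndarray] = {}
    for pos, (label, sex, age_mean, age_sd) in enumerate(plan):
        sid = f"sub-{pos + 1:0{width}d}"
        age = float(np.clip(age_mean + age_sd * rng.standard_normal(), 5.0, 30.0))
        m = generate_morphometry(config, label, rng)
        tc = generate_timecourses(config, label, rng, cholesky=chol[label])
        morph[sid] = m
        tcs[sid] = tc
        ados_total = ados_sa = ados_rrb = None
        if pos in ados_set:
            conn = np.corrcoef(tc)
            devs = _severity_deviations(config, m, conn)
            ados_total = generate_severity(config, devs, rng)
            ados_sa = int(np.clip(round(ados_total * 0.75), 0, 19))
            ados_rrb = int(np.clip(ados_total - ados_sa, 0, 6))
        records.append(
            SubjectRecord(
                subject_id=sid,
                label=label,
                sex=sex,
                age=round(age, 2),
                ados_total=ados_total,
                ados_sa=ados_sa,
                ados_rrb=ados_rrb,
            )
        )
        availability[sid] = (True, pos not in missing_fmri)

    ground_truth = {
        "planted_smri": [asdict(s) for s in config.planted_smri],
        "planted_edges": [asdict(e) for e in config.planted_edges],
        "severity_weights": {f"{m}:{k}": w for (m, k), w in config.severity_weights.items()},
        "seed": config.seed,
        "structure_seed": config.structure_seed,
    }
    return CohortData(
        manifest=CohortManifest(records, availability),
        morphometry=morph,
        timecourses=tcs,
        ground_truth=ground_truth,
    )


def generate_cohort(config: GeneratorConfig, outdir: str | Path) -> Path:
    """Write a cohort to disk in the package's file formats.

    Layout: ``manifest.csv``, ``smri/<id>.csv`` (region feature tables),
    ``fmri/<id>.csv`` (time courses; omitted for missing-fMRI subjects),
    and ``ground_truth.json`` recording the planted elements.
    """
    outdir = Path(outdir)
    (outdir / "smri").mkdir(parents=True, exist_ok=True)
    (outdir / "fmri").mkdir(parents=True, exist_ok=True)
    data = generate_cohort_arrays(config)
    frame = data.manifest.to_frame()
    frame.to_csv(outdir / "manifest.csv", index=False)
    atlas = dk_atlas()
    for sid, table in data.morphometry.items():
        out = table.copy()
        out.insert(0, "region", list(atlas.region_names))
        out.to_csv(outdir / "smri" / f"{sid}.csv", index=False, float_format="%.10g")
    for sid, tc in data.timecourses.items():
        if not data.manifest.modality_availability[sid][1]:
            continue
        df = pd.DataFrame(tc)
        df.insert(0, "region", list(atlas.region_names))
        df.to_csv(
            outdir / "fmri" / f"{sid}.csv", index=False, header=False,
            float_format="%.8g",
        )
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(data.ground_truth, fh, indent=1, sort_keys=True)
    return outdir


def planted_feature_ids(config: GeneratorConfig) -> dict[str, list[tuple]]:
    """Planted ground truth in screen/ranking coordinates.

    Structural shifts are region-level: shift (r, f) touches every delta
    feature (i, j, f) with r ∈ {i, j}.  Returned as ``("smri", region, f)``
    markers and exact ``("fmri", i, j)`` edges.
    """
    return {
        "smri": [("smri", s.region, s.feature) for s in config.planted_smri],
        "fmri": [("fmri", e.i, e.j) for e in config.planted_edges],
    }
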