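"""Severity-correlation screen and cohort demographic tests.

The screen correlates every pairwise feature — functional-connectivity
entries and structural delta entries — with the ADOS total severity score
across the subjects that have an ADOS report, and flags the features whose
absolute Pearson correlation clears a threshold (default |r| ≥ 0.32, which
at n = 61 corresponds to a two-sided p of about 0.01).  Region frequency
among the significant features ranks brain areas by their involvement.

The feature universe is the strict upper triangle i < j: the lower triangle
is redundant (the connectivity matrix is symmetric and the delta tensor
antisymmetric), giving 68·67/2 = 2 278 connectivity features and
2 278 · 8 = 18 224 structural features.

No multiple-testing correction is applied by default — the raw-|r|
threshold is the screen's operating point — but a Benjamini–Hochberg flag
is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CohortManifest, FEATURE_COLUMNS

__all__ = [
    "fmri_feature_index",
    "smri_feature_index",
    "flatten_fmri",
    "flatten_smri",
    "correlate_with_severity",
    "significance_screen",
    "CorrelationScreenResult",
    "area_frequency_ranking",
    "cohort_demographic_tests",
    "demographic_tests_from_moments",
    "DemographicsResult",
]

N_REGIONS = 68
DEFAULT_THRESHOLD_R = 0.32

_TRIU_I, _TRIU_J = np.triu_indices(N_REGIONS, k=1)


def fmri_feature_index() -> pd.DataFrame:
    """The 2 278 connectivity features (i, j), 1-based, i < j, in (i, j) order."""
    return pd.DataFrame(
        {"modality": "fMRI", "i": _TRIU_I + 1, "j": _TRIU_J + 1, "f": 0}
    )


def smri_feature_index() -> pd.DataFrame:
    """The 18 224 structural delta features (i, j, f), ordered by (f, i, j)."""
    n_pairs = _TRIU_I.size
    f = np.repeat(np.arange(1, 9), n_pairs)
    i = np.tile(_TRIU_I + 1, 8)
    j = np.tile(_TRIU_J + 1, 8)
    return pd.DataFrame({"modality": "sMRI", "i": i, "j": j, "f": f})


def flatten_fmri(conn_stack: np.ndarray) -> np.ndarray:
    """Flatten (n, 68, 68) connectivity matrices to (n, 2 278) upper-triangle columns."""
    conn_stack = np.asarray(conn_stack, dtype=float)
    if conn_stack.ndim == 2:
        conn_stack = conn_stack[None]
    return conn_stack[:, _TRIU_I, _TRIU_J]


def flatten_smri(delta_stack: np.ndarray) -> np.ndarray:
    """Flatten (n, 68, 68, 8) delta tensors to (n, 18 224), matching smri_feature_index."""
    delta_stack = np.asarray(delta_stack, dtype=float)
    if delta_stack.ndim == 3:
        delta_stack = delta_stack[None]
    # (n, pairs, 8) -> f-major ordering to match the index frame
    tri = delta_stack[:, _TRIU_I, _TRIU_J, :]
    return tri.transpose(0, 2, 1).reshape(delta_stack.shape[0], -1)


def correlate_with_severity(
    feature_values: Sequence[float], severity: Sequence[int]
) -> tuple[float, float]:
    """Pearson correlation of one feature with ADOS totals, with two-sided p.

    The p-value uses the exact t transform t = r·√(n−2)/√(1−r²) against a
    Student t with n − 2 degrees of freedom.
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(severity, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature values and severity must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    p = correlation_p_value(r, n)
    return r, p


def correlation_p_value(r: float | np.ndarray, n: int) -> float | np.ndarray:
    """Two-sided p for a Pearson r at sample size n (t transform, n−2 df)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    if np.isscalar(r) or p.ndim == 0:
        return float(p)
    return p


@dataclass
class CorrelationScreenResult:
    """Outcome of the severity screen over a feature universe.

    ``table`` has one row per feature: modality, i, j, f (0 for fMRI),
    r, p, significant.  ``threshold_r`` is the |r| cutoff used;
    ``counts_by_modality`` and ``counts_by_slab`` summarise the significant
    set (the slab breakdown mirrors the eight structural features).
    """

    table: pd.DataFrame
    threshold_r: float
    n_subjects: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    @property
    def counts_by_modality(self) -> dict[str, int]:
        sig = self.significant
        return {
            m: int((sig["modality"] == m).sum())
            for m in self.table["modality"].unique()
        }

    @property
    def counts_by_slab(self) -> dict[str, int]:
        sig = self.significant
        smri = sig[sig["modality"] == "sMRI"]
        return {
            name: int((smri["f"] == f).sum())
            for f, name in enumerate(FEATURE_COLUMNS, start=1)
        }

    @property
    def total_significant(self) -> int:
        return int(self.table["significant"].sum())


def significance_screen(
    features: np.ndarray,
    index: pd.DataFrame,
    severity: Sequence[int],
    threshold_r: float = DEFAULT_THRESHOLD_R,
    *,
    bh_correct: bool = False,
    bh_alpha: float = 0.05,
) -> CorrelationScreenResult:
    """Correlate every feature column with severity and flag significance.

    Parameters
    ----------
    features:
        ``(n_subjects, n_features)`` matrix, columns described by ``index``
        (from :func:`fmri_feature_index` / :func:`smri_feature_index`,
        possibly concatenated).
    severity:
        ADOS totals for the same subjects.
    threshold_r:
        Features with |r| ≥ ``threshold_r`` are flagged significant.
    bh_correct:
        Optionally additionally require a Benjamini–Hochberg adjusted
        p ≤ ``bh_alpha``.  Off by default: the screen's operating point is
        the raw correlation threshold.
    """
    if not (0.0 < threshold_r <= 1.0):
        raise ValueError("threshold_r must lie in (0, 1]")
    x = np.asarray(features, dtype=float)
    y = np.asarray(severity, dtype=float)
    if x.shape[0] != y.size:
        raise ValueError("feature rows and severity length differ")
    if x.shape[1] != len(index):
        raise ValueError("feature columns and index length differ")
    n = y.size
    if n < 4:
        raise ValueError(f"need at least 4 subjects with severity, got {n}")
    if np.ptp(y) == 0:
        raise ValueError("severity is constant; correlations undefined")

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    p = np.asarray(correlation_p_value(r, n))
    constant = sx == 0.0
    r[constant] = np.nan
    p[constant] = np.nan

    significant = np.abs(r) >= threshold_r
    significant &= ~constant
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        valid = ~np.isnan(p)
        reject = np.zeros_like(significant)
        reject[valid] = multipletests(p[valid], alpha=bh_alpha, method="fdr_bh")[0]
        significant &= reject

    table = index.copy()
    table["r"] = r
    table["p"] = p
    table["significant"] = significant
    return CorrelationScreenResult(table=table, threshold_r=threshold_r, n_subjects=n)


def area_frequency_ranking(screen: CorrelationScreenResult) -> pd.DataFrame:
    """Count, per region, the significant features it participates in.

    A region's count is the number of significant features with i = region
    or j = region; the frame is sorted by descending count, ties broken by
    atlas order.  All 68 regions appear, including zero counts.
    """
    counts = np.zeros(N_REGIONS, dtype=int)
    sig = screen.significant
    for col in ("i", "j"):
        vals, c = np.unique(sig[col].to_numpy(), return_counts=True)
        counts[vals - 1] += c
    out = pd.DataFrame({"region": np.arange(1, N_REGIONS + 1), "count": counts})
    return out.sort_values(
        ["count", "region"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# demographics


@dataclass
class DemographicsResult:
    chi2: float
    chi2_p: float
    sex_table: pd.DataFrame
    t_age: float
    t_age_p: float
    ados_summary: dict[str, dict[str, float]]


def _chi2_no_correction(table: np.ndarray) -> tuple[float, float]:
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def cohort_demographic_tests(manifest: CohortManifest) -> DemographicsResult:
    """Sex and age comparisons between diagnostic groups, plus ADOS descriptives.

    Sex × diagnosis is tested by a chi-squared test on the 2 × 2 table
    without continuity correction; age by a pooled-variance two-sample t
    with a two-sided p.  ADOS total/SA/RRB medians and ranges are reported
    over the subjects with a score.
    """
    df = manifest.to_frame()
    for label in ("ASD", "TD"):
        if (df["label"] == label).sum() == 0:
            raise ValueError(f"class {label} absent from cohort")
    sexed = df[df["sex"].isin(["M", "F"])]
    sex_table = pd.crosstab(sexed["label"], sexed["sex"]).reindex(
        index=["ASD", "TD"], columns=["M", "F"], fill_value=0
    )
    chi2, chi2_p = _chi2_no_correction(sex_table.to_numpy())
    asd_age = df.loc[df["label"] == "ASD", "age"].dropna().to_numpy()
    td_age = df.loc[df["label"] == "TD", "age"].dropna().to_numpy()
    t, t_p = stats.ttest_ind(asd_age, td_age, equal_var=True)
    ados: dict[str, dict[str, float]] = {}
    for key in ("ados_total", "ados_sa", "ados_rrb"):
        vals = df[key].dropna().astype(float)
        if len(vals):
            ados[key] = {
                "n": int(len(vals)),
                "median": float(vals.median()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
    return DemographicsResult(
        chi2=chi2,
        chi2_p=chi2_p,
        sex_table=sex_table,
        t_age=float(t),
        t_age_p=float(t_p),
        ados_summary=ados,
    )


def demographic_tests_from_moments(
    subgroups: Mapping[str, Mapping[str, tuple[int, float, float]]],
) -> tuple[float, float]:
    """Pooled two-sample t on age reconstructed from subgroup summaries.

    ``subgroups`` maps group name (e.g. ``"ASD"``/``"TD"``) to a mapping of
    subgroup name to ``(count, mean, sd)``.  Group moments are recombined
    exactly — the combined sum of squares is
    Σ[(nᵢ−1)sᵢ² + nᵢ(mᵢ−m)²] — so the result equals the raw-data pooled t.
    Returns ``(t, two-sided p)`` comparing the two groups in mapping order.
    """
    if len(subgroups) != 2:
        raise ValueError("exactly two groups required")
    moments = []
    for _, parts in subgroups.items():
        ns = np.array([v[0] for v in parts.values()], dtype=float)
        ms = np.array([v[1] for v in parts.values()], dtype=float)
        sds = np.array([v[2] for v in parts.values()], dtype=float)
        if np.any(ns < 1):
            raise ValueError("subgroup counts must be >= 1")
        n = ns.sum()
        mean = float((ns * ms).sum() / n)
        ss = float(((ns - 1) * sds**2 + ns * (ms - mean) ** 2).sum())
        moments.append((n, mean, ss / (n - 1)))
    (n1, m1, v1), (n2, m2, v2) = moments
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return float(t), float(p)
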