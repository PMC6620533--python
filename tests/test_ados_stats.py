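import numpy as np
import pandas as pd
import pytest

from neurofuse.ados_stats import (
    area_frequency_ranking,
    cohort_demographic_tests,
    correlate_with_severity,
    correlation_p_value,
    demographic_tests_from_moments,
    flatten_fmri,
    flatten_smri,
    fmri_feature_index,
    significance_screen,
    smri_feature_index,
)
from neurofuse.io_formats import CohortManifest, SubjectRecord

# Published cohort summary (count, age mean, age SD) per class and sex.
TABLE_MOMENTS = {
    "ASD": {"M": (33, 13.07, 2.75), "F": (39, 13.53, 2.58)},
    "TD": {"M": (49, 13.04, 2.68), "F": (64, 12.8125, 3.17)},
}


class TestFeatureUniverse:
    def test_counts(self):
        assert len(fmri_feature_index()) == 2278
        assert len(smri_feature_index()) == 18224

    def test_strict_upper_triangle(self):
        for idx in (fmri_feature_index(), smri_feature_index()):
            assert (idx["i"] < idx["j"]).all()
            assert idx["i"].min() >= 1 and idx["j"].max() <= 68

    def test_flatteners_match_index(self, rng):
        conn = rng.normal(size=(3, 68, 68))
        conn = (conn + conn.transpose(0, 2, 1)) / 2
        flat = flatten_fmri(conn)
        idx = fmri_feature_index()
        for col in rng.choice(len(idx), size=20, replace=False):
            i, j = idx.iloc[col][["i", "j"]]
            np.testing.assert_allclose(flat[:, col], conn[:, i - 1, j - 1])
        delta = rng.normal(size=(3, 68, 68, 8))
        flat_s = flatten_smri(delta)
        idx_s = smri_feature_index()
        for col in rng.choice(len(idx_s), size=20, replace=False):
            i, j, f = idx_s.iloc[col][["i", "j", "f"]]
            np.testing.assert_allclose(flat_s[:, col], delta[:, i - 1, j - 1, f - 1])


class TestCorrelateWithSeverity:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        r, p = correlate_with_severity(x, 2 * x + 1)
        np.testing.assert_allclose(r, 1.0)
        assert p < 1e-10

    def test_threshold_r_p_value(self):
        # |r| = 0.32 at n = 61 sits at the p ≈ 0.01 operating point
        p = correlation_p_value(0.32, 61)
        assert round(p, 2) == 0.01

    def test_constant_input_errors(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_with_severity([1.0] * 10, list(range(10)))

    def test_p_monotone_in_r_and_n(self):
        rs = np.linspace(0.05, 0.9, 20)
        ps = np.array([correlation_p_value(r, 61) for r in rs])
        assert np.all(np.diff(ps) < 0)
        ns = np.arange(5, 200, 10)
        ps = np.array([correlation_p_value(0.3, n) for n in ns])
        assert np.all(np.diff(ps) < 0)

    def test_type_one_error_calibration(self):
        """Fraction of independent pairs with p < 0.01 is ≈ 0.01."""
        rng = np.random.default_rng(123)
        n, reps = 61, 10_000
        x = rng.normal(size=(reps, n))
        y = rng.normal(size=n)
        xc = x - x.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        r = (xc @ yc) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
        p = correlation_p_value(r, n)
        frac = float((p < 0.01).mean())
        assert abs(frac - 0.01) < 0.003


class TestScreen:
    def test_threshold_one_gives_nothing(self, rng):
        x = rng.normal(size=(61, 100))
        screen = significance_screen(
            x, fmri_feature_index().head(100), rng.integers(1, 25, 61), threshold_r=1.0
        )
        assert screen.total_significant == 0

    def test_planted_high_correlation_is_flagged(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(50):
            sev = rng.normal(size=61)
            x = rng.normal(size=(61, 10))
            x[:, 3] = 0.7 * sev + np.sqrt(1 - 0.49) * rng.normal(size=61)
            screen = significance_screen(
                x, fmri_feature_index().head(10), sev * 3 + 12
            )
            if screen.table.iloc[3]["significant"]:
                hits += 1
        assert hits >= 49  # true r = 0.7 at n = 61: essentially always detected

    def test_slab_counts_partition_smri_significant(self, rng):
        sev = rng.integers(1, 25, 61).astype(float)
        x = rng.normal(size=(61, 18224))
        screen = significance_screen(x, smri_feature_index(), sev)
        assert sum(screen.counts_by_slab.values()) == screen.counts_by_modality["sMRI"]

    def test_null_significant_fraction_matches_threshold_tail(self):
        rng = np.random.default_rng(9)
        sev = rng.normal(size=61)
        x = rng.normal(size=(61, 10_000))
        screen = significance_screen(x, smri_feature_index().head(10_000), sev)
        frac = screen.total_significant / 10_000
        # two-sided tail mass of |r| >= 0.32 at n = 61 is ≈ 0.0119
        assert abs(frac - 0.012) < 0.004


class TestAreaFrequency:
    def test_small_tally(self):
        idx = fmri_feature_index()
        sev_cols = [(1, 2), (1, 3)]
        sig = np.array([(i, j) in sev_cols for i, j in zip(idx["i"], idx["j"])])
        table = idx.copy()
        table["r"] = 0.5
        table["p"] = 0.001
        table["significant"] = sig
        from neurofuse.ados_stats import CorrelationScreenResult

        ranking = area_frequency_ranking(
            CorrelationScreenResult(table, 0.32, 61)
        )
        assert ranking.iloc[0]["region"] == 1 and ranking.iloc[0]["count"] == 2
        counts = dict(zip(ranking["region"], ranking["count"]))
        assert counts[2] == 1 and counts[3] == 1 and counts[4] == 0

    def test_matches_loop_oracle_and_permutation_equivariance(self, rng):
        idx = fmri_feature_index()
        sig = np.zeros(len(idx), dtype=bool)
        sig[rng.choice(len(idx), size=50, replace=False)] = True
        table = idx.copy()
        table["r"], table["p"], table["significant"] = 0.4, 0.005, sig
        from neurofuse.ados_stats import CorrelationScreenResult

        ranking = area_frequency_ranking(CorrelationScreenResult(table, 0.32, 61))
        oracle = {a: 0 for a in range(1, 69)}
        for row in table[table["significant"]].itertuples():
            oracle[row.i] += 1
            oracle[row.j] += 1
        assert dict(zip(ranking["region"], ranking["count"])) == oracle
        assert (np.diff(ranking["count"].to_numpy()) <= 0).all()


class TestDemographics:
    def test_age_t_from_table_moments(self):
        t, p = demographic_tests_from_moments(TABLE_MOMENTS)
        assert round(t, 2) == 0.95
        assert round(p, 2) == 0.34

    def test_moment_reconstruction_matches_raw_data(self, rng):
        groups = {}
        raw = {}
        for g in ("ASD", "TD"):
            parts = {}
            vals = []
            for sub in ("M", "F"):
                x = rng.normal(13, 3, size=rng.integers(10, 40))
                parts[sub] = (len(x), float(x.mean()), float(x.std(ddof=1)))
                vals.append(x)
            groups[g] = parts
            raw[g] = np.concatenate(vals)
        t_mom, _ = demographic_tests_from_moments(groups)
        from scipy import stats

        t_raw, _ = stats.ttest_ind(raw["ASD"], raw["TD"], equal_var=True)
        np.testing.assert_allclose(t_mom, t_raw, atol=1e-10)

    def test_identical_groups_give_t_zero(self):
        groups = {
            "ASD": {"all": (30, 13.0, 2.5)},
            "TD": {"all": (30, 13.0, 2.5)},
        }
        t, p = demographic_tests_from_moments(groups)
        assert t == 0.0 and p == 1.0

    def test_chi2_matches_brute_force(self):
        table = np.array([[33, 39], [49, 64]], dtype=float)
        rowsum = table.sum(axis=1, keepdims=True)
        colsum = table.sum(axis=0, keepdims=True)
        expected = rowsum * colsum / table.sum()
        chi2_oracle = float(((table - expected) ** 2 / expected).sum())

        records = []
        k = 0
        for label, (nm, nf) in (("ASD", (33, 39)), ("TD", (49, 64))):
            for sex, n in (("M", nm), ("F", nf)):
                for _ in range(n):
                    records.append(
                        SubjectRecord(subject_id=f"s{k}", label=label, sex=sex, age=13.0)
                    )
                    k += 1
        result = cohort_demographic_tests(CohortManifest(records))
        np.testing.assert_allclose(result.chi2, chi2_oracle, atol=1e-10)

    def test_single_class_cohort_errors(self):
        records = [
            SubjectRecord(subject_id=f"s{i}", label="ASD", age=13.0) for i in range(5)
        ]
        with pytest.raises(ValueError, match="TD"):
            cohort_demographic_tests(CohortManifest(records))
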