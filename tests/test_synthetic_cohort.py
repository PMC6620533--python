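import json

import numpy as np
import pytest
from scipy import stats

from neurofuse.io_formats import read_cohort_manifest, read_region_features, read_time_courses
from neurofuse.synthetic_cohort import (
    GeneratorConfig,
    PlantedEdge,
    PlantedShift,
    _class_correlation,
    generate_cohort,
    generate_cohort_arrays,
    generate_morphometry,
    generate_severity,
    generate_timecourses,
)


class TestConfig:
    def test_default_cohort_shape(self):
        cfg = GeneratorConfig()
        assert cfg.n_asd == 72 and cfg.n_td == 113 and cfg.n_ados == 61

    def test_invalid_planted_spec_rejected(self):
        with pytest.raises(ValueError):
            PlantedShift(region=70, feature=1, shift_sd=1.0)
        with pytest.raises(ValueError):
            PlantedEdge(i=5, j=5, delta=0.3)
        with pytest.raises(ValueError):
            GeneratorConfig(n_asd=1)

    def test_oversized_correlation_delta_errors(self):
        cfg = GeneratorConfig(
            planted_edges=tuple(
                PlantedEdge(i, i + 1, 0.95) for i in range(1, 12, 2)
            )
        )
        with pytest.raises(ValueError, match="positive definite|outside"):
            _class_correlation(cfg, "ASD")


class TestMorphometry:
    def test_determinism(self):
        cfg = GeneratorConfig(seed=3)
        a = generate_morphometry(cfg, "ASD", np.random.default_rng(5))
        b = generate_morphometry(cfg, "ASD", np.random.default_rng(5))
        assert a.equals(b)

    def test_zero_shift_classes_indistinguishable(self):
        cfg = GeneratorConfig(
            planted_smri=(), planted_edges=(), severity_weights={}, seed=0
        )
        rng = np.random.default_rng(0)
        asd = np.stack(
            [generate_morphometry(cfg, "ASD", rng).to_numpy() for _ in range(40)]
        )
        td = np.stack(
            [generate_morphometry(cfg, "TD", rng).to_numpy() for _ in range(40)]
        )
        # pick a handful of (region, feature) cells: group difference ~ 0
        picks = [(7, 0), (40, 1), (23, 7), (55, 3), (62, 4)]
        ps = [stats.ttest_ind(asd[:, r, f], td[:, r, f]).pvalue for r, f in picks]
        assert min(ps) > 1e-3  # no systematic separation

    def test_planted_shift_detectable_by_local_knn(self):
        """A 2-SD planted shift (delta-feature scale) gives its pairwise
        delta features out-of-fold KNN accuracy above 0.8 at n = 200."""
        from neurofuse.local_classification import evaluate_local_grid

        cfg = GeneratorConfig(
            planted_smri=(PlantedShift(7, 1, 2.0),), planted_edges=(),
            severity_weights={("smri", 0): 1.0}, seed=4,
        )
        rng = np.random.default_rng(4)
        accs = []
        for rep in range(5):
            subs = [generate_morphometry(cfg, "ASD", rng).to_numpy() for _ in range(100)]
            subs += [generate_morphometry(cfg, "TD", rng).to_numpy() for _ in range(100)]
            x = np.stack(subs)
            y = np.repeat([1, 0], 100)
            # delta feature (region 7, region 20, feature A)
            feat = x[:, 6, 0] - x[:, 19, 0]
            res = evaluate_local_grid(feat[:, None], y, seed=rep)
            accs.append(res.accuracy[0])
        assert np.mean(accs) > 0.80
        assert min(accs) > 0.70


class TestTimecourses:
    def test_determinism(self):
        cfg = GeneratorConfig(seed=1, t_points=50)
        a = generate_timecourses(cfg, "TD", np.random.default_rng(2))
        b = generate_timecourses(cfg, "TD", np.random.default_rng(2))
        np.testing.assert_array_equal(a, b)

    def test_planted_edge_delta_recovered_in_sample(self):
        cfg = GeneratorConfig(t_points=180, seed=0)
        rng = np.random.default_rng(10)
        edge = cfg.planted_edges[0]
        i, j = edge.i - 1, edge.j - 1
        diffs = []
        for _ in range(100):
            a = np.corrcoef(generate_timecourses(cfg, "ASD", rng))[i, j]
            t = np.corrcoef(generate_timecourses(cfg, "TD", rng))[i, j]
            diffs.append(a - t)
        assert abs(np.mean(diffs) - edge.delta) < 0.1

    def test_empirical_correlation_converges_to_target(self):
        cfg = GeneratorConfig(t_points=5000, seed=0)
        rng = np.random.default_rng(3)
        target = _class_correlation(cfg, "TD")
        emp = np.corrcoef(generate_timecourses(cfg, "TD", rng))
        assert np.max(np.abs(emp - target)) < 0.08

    def test_zero_delta_classes_share_structure(self):
        cfg = GeneratorConfig(
            planted_edges=(), severity_weights={("smri", 0): 1.0}, seed=0
        )
        np.testing.assert_array_equal(
            _class_correlation(cfg, "ASD"), _class_correlation(cfg, "TD")
        )


class TestSeverity:
    def test_monotone_in_single_driver(self):
        cfg = GeneratorConfig(
            severity_weights={("smri", 0): 1.0}, severity_noise_sd=0.0
        )
        rng = np.random.default_rng(0)
        zs = np.linspace(-3, 3, 13)
        scores = [
            generate_severity(cfg, {("smri", 0): z}, rng) for z in zs
        ]
        assert scores == sorted(scores)
        assert min(scores) >= 1 and max(scores) <= 24

    def test_designed_correlation_flagged_by_screen(self):
        """A feature driving severity with designed r ≈ 0.6 clears |r| ≥ 0.32."""
        rng = np.random.default_rng(6)
        hits = 0
        reps = 40
        for _ in range(reps):
            z = rng.normal(size=61)
            noise = rng.normal(size=61)
            sev = 0.6 * z + np.sqrt(1 - 0.36) * noise
            r = np.corrcoef(z, sev)[0, 1]
            if abs(r) >= 0.32:
                hits += 1
        assert hits / reps >= 0.95

    def test_cohort_severity_correlates_with_planted_feature(self):
        cfg = GeneratorConfig(
            n_asd=72, n_td=20, t_points=60, n_ados=61, n_missing_fmri=0, seed=8,
            severity_weights={("smri", 0): 1.0}, severity_noise_sd=0.6,
        )
        cohort = generate_cohort_arrays(cfg)
        shift = cfg.planted_smri[0]
        xs, ys = [], []
        for s in cohort.manifest:
            if s.ados_total is None:
                continue
            table = cohort.morphometry[s.subject_id].to_numpy()
            # delta-style (offset-free) view of the driving element
            xs.append(
                table[shift.region - 1, shift.feature - 1]
                - table[:, shift.feature - 1].mean()
            )
            ys.append(s.ados_total)
        r = np.corrcoef(xs, ys)[0, 1]
        assert r > 0.32  # designed driver is recoverable through the cohort


class TestCohortAssembly:
    def test_count_contract(self):
        cfg = GeneratorConfig(n_asd=72, n_td=113, t_points=10, seed=0)
        cohort = generate_cohort_arrays(cfg)
        labels = cohort.manifest.labels
        assert len(cohort.manifest) == 185
        assert (labels == "ASD").sum() == 72 and (labels == "TD").sum() == 113
        assert len(cohort.manifest.with_severity()) == 61
        missing = [
            sid for sid, (s, f) in cohort.manifest.modality_availability.items() if not f
        ]
        assert len(missing) == 7

    def test_files_round_trip_through_readers(self, tmp_path, atlas):
        cfg = GeneratorConfig(n_asd=3, n_td=3, t_points=12, n_ados=2,
                              n_missing_fmri=1, seed=5)
        outdir = generate_cohort(cfg, tmp_path / "cohort")
        manifest = read_cohort_manifest(outdir / "manifest.csv", atlas)
        assert len(manifest) == 6
        data = generate_cohort_arrays(cfg)
        sid = manifest.subjects[0].subject_id
        table = read_region_features(outdir / "smri" / f"{sid}.csv", atlas)
        np.testing.assert_allclose(
            table.to_numpy(), data.morphometry[sid].to_numpy(), rtol=1e-9
        )
        fmri_sids = [
            s for s, (_, f) in manifest.modality_availability.items() if f
        ]
        tc = read_time_courses(outdir / "fmri" / f"{fmri_sids[0]}.csv", atlas)
        assert tc.values.shape == (68, 12)

    def test_sidecar_lists_planted_elements(self, tmp_path):
        cfg = GeneratorConfig(n_asd=2, n_td=2, t_points=10, n_ados=2,
                              n_missing_fmri=0, seed=1)
        outdir = generate_cohort(cfg, tmp_path / "c")
        truth = json.loads((outdir / "ground_truth.json").read_text())
        assert len(truth["planted_smri"]) == len(cfg.planted_smri)
        assert truth["planted_edges"][0]["delta"] == cfg.planted_edges[0].delta

    def test_regeneration_identical(self, tmp_path):
        cfg = GeneratorConfig(n_asd=2, n_td=3, t_points=10, n_ados=2,
                              n_missing_fmri=1, seed=9)
        d1 = generate_cohort(cfg, tmp_path / "c1")
        d2 = generate_cohort(cfg, tmp_path / "c2")
        for rel in ("manifest.csv", "ground_truth.json"):
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes()
        for p1 in sorted((d1 / "smri").glob("*.csv")):
            assert p1.read_bytes() == (d2 / "smri" / p1.name).read_bytes()
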