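"""Phantom generator: age distribution, atlas, rendering, determinism."""

import numpy as np
import pytest

from brainage.synthetic import (
    ConfigurationError,
    PhantomConfig,
    SubjectRecord,
    channel_effect_params,
    make_atlas,
    make_cohort,
    render_subject,
    sample_ages,
)


class TestSampleAges:
    def test_empty(self):
        assert sample_ages(0, PhantomConfig()).size == 0

    def test_cohort_scale_moments(self):
        """At the real-cohort size the sample mean/SD land near 36.4 / 16.4 y."""
        ages = sample_ages(2483, PhantomConfig())
        assert ages.mean() == pytest.approx(36.41, abs=2.0)
        assert ages.std(ddof=1) == pytest.approx(16.37, abs=2.0)

    def test_right_skew_and_support(self):
        cfg = PhantomConfig()
        ages = sample_ages(5000, cfg)
        assert ages.min() >= cfg.age_min and ages.max() <= cfg.age_max
        # right skew: mean above median
        assert ages.mean() > np.median(ages)

    def test_seed_determinism(self):
        cfg = PhantomConfig(seed=7)
        a = sample_ages(1000, cfg)
        b = sample_ages(1000, cfg)
        assert np.array_equal(a, b)

    def test_invalid_bounds(self):
        with pytest.raises(ConfigurationError):
            PhantomConfig(age_min=90, age_max=17)


class TestMakeAtlas:
    def test_label_completeness(self):
        atlas = make_atlas((8, 8, 8), 2, seed=0)
        assert set(np.unique(atlas.labels)) == {0, 1, 2}

    def test_442_parcels_all_nonempty(self):
        atlas = make_atlas((16, 16, 16), 442, seed=1)
        counts = np.bincount(atlas.labels.ravel())
        assert atlas.n_parcels == 442
        assert np.all(counts[1:] > 0)

    def test_seed_determinism(self):
        a = make_atlas((10, 12, 10), 15, seed=3)
        b = make_atlas((10, 12, 10), 15, seed=3)
        assert np.array_equal(a.labels, b.labels)

    def test_too_many_parcels(self):
        with pytest.raises(ConfigurationError):
            make_atlas((4, 4, 4), 1000, seed=0)


class TestRenderSubject:
    def test_noise_free_linearity(self):
        """With zero noise, a -0.5/y slope moves the parcel mean by exactly -5
        over a 10-year age difference."""
        cfg = PhantomConfig(
            grid=(10, 10, 10),
            n_parcels=4,
            noise_sd=0.0,
            effect_slopes={"gmv": {1: -0.5}},
            seed=5,
        )
        atlas = make_atlas(cfg.grid, cfg.n_parcels, seed=cfg.seed)
        v30 = render_subject(SubjectRecord("s30", 30.0, 0), atlas, cfg)
        v40 = render_subject(SubjectRecord("s40", 40.0, 0), atlas, cfg)
        in1 = atlas.labels == 1
        d = v40.channels["gmv"][in1].mean() - v30.channels["gmv"][in1].mean()
        assert d == pytest.approx(-5.0, abs=1e-4)

    def test_null_effect(self):
        # zero out every auto-drawn slope
        cfg = PhantomConfig(
            grid=(8, 8, 8),
            n_parcels=3,
            noise_sd=0.0,
            effect_slopes={
                c: {p: 0.0 for p in range(1, 4)} for c in PhantomConfig().channels
            },
            seed=2,
        )
        atlas = make_atlas(cfg.grid, cfg.n_parcels, seed=cfg.seed)
        va = render_subject(SubjectRecord("s", 20.0, 0), atlas, cfg)
        vb = render_subject(SubjectRecord("s", 80.0, 0), atlas, cfg)
        for ch in cfg.channels:
            assert np.array_equal(va.channels[ch], vb.channels[ch])

    def test_background_zero(self):
        cfg = PhantomConfig(grid=(8, 8, 8), n_parcels=3, seed=4)
        atlas = make_atlas(cfg.grid, cfg.n_parcels, seed=cfg.seed)
        vol = render_subject(SubjectRecord("s", 40.0, 1), atlas, cfg)
        assert np.all(vol.channels["gmv"][atlas.labels == 0] == 0)

    def test_ols_recovers_slope(self):
        """Regression of parcel-1 mean on age recovers the planted slope."""
        slope = -0.3
        cfg = PhantomConfig(
            n_subjects=200,
            grid=(10, 10, 10),
            n_parcels=4,
            noise_sd=0.1,
            effect_slopes={"gmv": {1: slope}},
            seed=9,
        )
        atlas = make_atlas(cfg.grid, cfg.n_parcels, seed=cfg.seed)
        vols, table = make_cohort(cfg, atlas=atlas)
        in1 = atlas.labels == 1
        means = np.array([v.channels["gmv"][in1].mean() for v in vols])
        ages = table["age"].to_numpy()
        X = np.column_stack([np.ones_like(ages), ages])
        beta, res, *_ = np.linalg.lstsq(X, means, rcond=None)
        # standard error of the slope estimate
        dof = len(ages) - 2
        s2 = float(res[0]) / dof
        se = np.sqrt(s2 / np.sum((ages - ages.mean()) ** 2))
        assert abs(beta[1] - slope) < 3 * se


class TestCohort:
    def test_seed_determinism_and_order_independence(self, small_cohort):
        cfg, atlas, volumes, table = small_cohort
        vols2, table2 = make_cohort(cfg, atlas=atlas)
        assert table.equals(table2)
        for a, b in zip(volumes, vols2):
            for ch in cfg.channels:
                assert np.array_equal(a.channels[ch], b.channels[ch])
        # re-rendering one subject in isolation reproduces its cohort volume
        rec = SubjectRecord(table["subject_id"][3], float(table["age"][3]), int(table["sex"][3]))
        solo = render_subject(rec, atlas, cfg)
        assert np.array_equal(solo.channels["gmd"], volumes[3].channels["gmd"])

    def test_roundtrip_via_disk(self, tmp_path):
        from brainage.preprocess import load_subject

        cfg = PhantomConfig(n_subjects=5, grid=(8, 8, 8), n_parcels=3, seed=77)
        vols, table = make_cohort(cfg, outdir=tmp_path)
        assert (tmp_path / "cohort.csv").exists()
        for v in vols:
            back = load_subject(tmp_path / f"{v.subject_id}.nii")
            for ch in cfg.channels:
                assert np.array_equal(back.channels[ch], v.channels[ch])
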