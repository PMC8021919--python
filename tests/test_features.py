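"""Parcel-wise means, spatial ICA recovery, integrity-score regression."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from brainage.atlas import ParcelAtlas
from brainage.features import (
    CollinearComponentsError,
    ComponentBasis,
    EmptyParcelError,
    build_parcel_table,
    build_sica_table,
    cohort_mask,
    fit_spatial_ica,
    integrity_scores,
    parcel_means,
)
from brainage.synthetic import PhantomConfig, SubjectVolume, make_atlas, make_cohort


class TestParcelMeans:
    def test_constant_volume(self):
        atlas = make_atlas((8, 8, 8), 4, seed=0)
        out = parcel_means(np.full((8, 8, 8), 3.0), atlas)
        assert np.allclose(out, 3.0)

    def test_hand_computed_two_parcels(self):
        labels = np.zeros((1, 1, 5), dtype=np.int32)
        labels[0, 0, :2] = 1
        labels[0, 0, 2:] = 2
        atlas = ParcelAtlas(labels=labels)
        vol = np.array([[[1.0, 3.0, 2.0, 2.0, 2.0]]])
        assert np.allclose(parcel_means(vol, atlas), [2.0, 2.0])

    def test_linearity(self, rng):
        atlas = make_atlas((8, 8, 8), 5, seed=1)
        x = rng.normal(size=(8, 8, 8))
        y = rng.normal(size=(8, 8, 8))
        lhs = parcel_means(2.0 * x + 3.0 * y, atlas)
        rhs = 2.0 * parcel_means(x, atlas) + 3.0 * parcel_means(y, atlas)
        assert np.allclose(lhs, rhs)

    def test_884_features_from_442_parcels_two_channels(self):
        atlas = make_atlas((16, 16, 16), 442, seed=2)
        cfg = PhantomConfig(
            n_subjects=3, grid=(16, 16, 16), n_parcels=442, noise_sd=0.0, seed=2
        )
        vols, _ = make_cohort(cfg, atlas=atlas)
        table = build_parcel_table(vols, atlas, ("gmv", "gmd"))
        assert table.matrix.shape == (3, 884)

    def test_empty_parcel_guard(self):
        labels = np.zeros((2, 2, 2), dtype=np.int32)
        labels[0, 0, 0] = 1
        atlas = ParcelAtlas(labels=labels, label_ids=np.array([1, 2]))
        with pytest.raises(EmptyParcelError):
            parcel_means(np.ones((2, 2, 2)), atlas)


def _planted_sources(rng, n_subjects=60, n_voxels=300, k=3):
    """Spatially disjoint sparse sources (strongly non-Gaussian over voxels).

    Values are centered within each support block so the sources carry no
    shared indicator/mean structure (which centering would otherwise make
    inseparable).
    """
    S = np.zeros((k, n_voxels))
    block = n_voxels // k
    for i in range(k):
        vals = rng.uniform(1.0, 3.0, block)
        S[i, i * block : (i + 1) * block] = vals - vals.mean()
    A = rng.normal(size=(n_subjects, k))
    X = A @ S + rng.normal(0, 0.01, size=(n_subjects, n_voxels))
    return X, S


class TestSpatialICA:
    def test_recovers_planted_sources(self, rng):
        X, S = _planted_sources(rng)
        mask = np.ones((300, 1, 1), dtype=bool)
        basis = fit_spatial_ica(X, mask, K=3, seed=0)
        # sign/permutation-invariant matching by Hungarian assignment
        corr = np.abs(np.corrcoef(S, basis.maps)[:3, 3:])
        rows, cols = linear_sum_assignment(-corr)
        assert np.all(corr[rows, cols] > 0.95)

    def test_rank_one_data(self, rng):
        pattern = rng.normal(size=50)
        weights = rng.normal(size=20)
        X = np.outer(weights, pattern)
        mask = np.ones((50, 1, 1), dtype=bool)
        basis = fit_spatial_ica(X, mask, K=1, seed=0)
        c = np.corrcoef(basis.maps[0], pattern)[0, 1]
        assert abs(c) > 0.999

    def test_seed_determinism(self, rng):
        X, _ = _planted_sources(rng)
        mask = np.ones((300, 1, 1), dtype=bool)
        a = fit_spatial_ica(X, mask, K=3, seed=5)
        b = fit_spatial_ica(X, mask, K=3, seed=5)
        assert np.array_equal(a.maps, b.maps)

    def test_k_exceeding_subjects_rejected(self, rng):
        X = rng.normal(size=(4, 50))
        with pytest.raises(ValueError):
            fit_spatial_ica(X, np.ones((50, 1, 1), bool), K=5)


class TestIntegrityScores:
    def _orthogonal_basis(self, rng, k=4, v=200):
        q, _ = np.linalg.qr(rng.normal(size=(v, k)))
        return ComponentBasis(maps=q.T, mask=np.ones((v, 1, 1), bool))

    def test_exact_linear_model(self, rng):
        basis = self._orthogonal_basis(rng)
        subject = 2.0 * basis.maps[0]
        betas = integrity_scores(subject, basis)
        expected = np.zeros(4)
        expected[0] = 2.0
        assert np.allclose(betas, expected, atol=1e-8)

    def test_orthogonal_noise_gives_zero(self, rng):
        basis = self._orthogonal_basis(rng)
        noise = rng.normal(size=200)
        # project out the basis span and the intercept direction
        Q = np.column_stack([np.ones(200) / np.sqrt(200), basis.maps.T])
        Q, _ = np.linalg.qr(Q)
        noise = noise - Q @ (Q.T @ noise)
        betas = integrity_scores(noise, basis)
        assert np.allclose(betas, 0.0, atol=1e-8)

    def test_roundtrip_recovers_weights(self, rng):
        basis = self._orthogonal_basis(rng, k=6)
        w = rng.normal(size=6)
        subject = basis.maps.T @ w
        assert np.allclose(integrity_scores(subject, basis), w, atol=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        maps = rng.normal(size=(5, 80))
        basis = ComponentBasis(maps=maps, mask=np.ones((80, 1, 1), bool))
        y = rng.normal(size=80)
        X = np.column_stack([np.ones(80), maps.T])
        oracle = np.linalg.solve(X.T @ X, X.T @ y)[1:]
        assert np.allclose(integrity_scores(y, basis), oracle, atol=1e-8)

    def test_collinear_components_rejected(self, rng):
        m = rng.normal(size=(1, 60))
        maps = np.vstack([m, 2.0 * m, rng.normal(size=(1, 60))])
        basis = ComponentBasis(maps=maps, mask=np.ones((60, 1, 1), bool))
        with pytest.raises(CollinearComponentsError):
            integrity_scores(rng.normal(size=60), basis)


class TestSicaTable:
    def _cohort(self):
        cfg = PhantomConfig(
            n_subjects=12, grid=(10, 10, 10), n_parcels=6, noise_sd=0.05, seed=3
        )
        return cfg, *make_cohort(cfg)

    def test_column_count_contract(self):
        cfg, vols, _ = self._cohort()
        bases = {}
        for ch in ("gmv", "gmd"):
            mask = cohort_mask(vols, ch)
            data = np.stack([v.channels[ch][mask] for v in vols])
            bases[ch] = fit_spatial_ica(data, mask, K=5, seed=0, channel=ch)
        table = build_sica_table(vols, bases, K=5)
        assert table.matrix.shape == (12, 10)

    def test_full_scale_shape_arithmetic(self):
        """K=400 over 4 feature sets yields 1,600 columns (by construction)."""
        K, n_sets = 400, 4
        names = [f"set{s}_ic{k}" for s in range(n_sets) for k in range(K)]
        assert len(names) == 1600
        assert len(set(names)) == 1600

    def test_naming_bijection(self):
        cfg, vols, _ = self._cohort()
        mask = cohort_mask(vols, "gmv")
        data = np.stack([v.channels["gmv"][mask] for v in vols])
        bases = {"gmv": fit_spatial_ica(data, mask, K=3, seed=0)}
        table = build_sica_table(vols, bases)
        parsed = [tuple(n.rsplit("_ic", 1)) for n in table.feature_names]
        assert len(set(parsed)) == len(table.feature_names)
        assert all(ch == "gmv" and k.isdigit() for ch, k in parsed)
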