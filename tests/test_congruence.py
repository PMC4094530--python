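"""PCO, Procrustes, Mantel and resampling congruence machinery."""

import itertools

import numpy as np
import pytest

import panmorph as pm
from panmorph.congruence import (TaxonConstellation, _pearson, mantel, pco,
                                 procrustes_superimpose,
                                 resampling_correlation)
from panmorph.distmat import DistanceMatrix
from panmorph.gendist import GenotypeTable

from conftest import tiny_preset
from test_qst import space_from_scores


def dm(values, labels=None, kind="generic"):
    values = np.asarray(values, float)
    labels = labels or tuple("ABCDEFG"[:len(values)])
    return DistanceMatrix(tuple(labels), values, kind=kind)


class TestPCO:
    def test_3_4_5_triangle_reproduced(self):
        D = dm([[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        c = pco(D, k=2)
        got = np.linalg.norm(c.coordinates[:, None] - c.coordinates[None],
                             axis=-1)
        assert np.allclose(got, D.values, atol=1e-8)

    def test_zero_distances_zero_coordinates(self):
        c = pco(dm(np.zeros((3, 3))), k=2)
        assert np.allclose(c.coordinates, 0.0)

    def test_gower_identity_for_euclidean_input(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        D = np.linalg.norm(X[:, None] - X[None], axis=-1)
        c = pco(dm(D), k=4)
        pos = c.eigenvalues[c.eigenvalues > 1e-10]
        # Gower: sum of positive eigenvalues = sum D^2 / (2n)  (all pairs
        # counted once) -- equivalently sum of squared centered coordinates
        assert pos.sum() == pytest.approx((D ** 2).sum() / (2 * len(X)),
                                          rel=1e-8)

    def test_matches_skbio_pcoa(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 3))
        D = np.linalg.norm(X[:, None] - X[None], axis=-1)
        ours = pco(dm(D, labels=tuple("ABCDEF")), k=3)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(D, ids=list("ABCDEF")))
        got = np.sort(np.abs(ours.coordinates), axis=0)
        exp = np.sort(np.abs(ref.samples.to_numpy()[:, :3]), axis=0)
        assert np.allclose(got, exp, atol=1e-6)


class TestProcrustes:
    @staticmethod
    def _con(X, labels=None):
        X = np.asarray(X, float)
        labels = labels or tuple("ABCDEFG"[:len(X)])
        return TaxonConstellation(tuple(labels), X,
                                  np.ones(X.shape[1]))

    def test_similarity_copy_has_zero_distance(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        Y = 3.2 * X @ R.T + np.array([5.0, -2.0])
        _, _, d = procrustes_superimpose(self._con(X), self._con(Y))
        assert d == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_normalized_distance(self):
        rng = np.random.default_rng(2)
        X, Y = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
        _, _, d1 = procrustes_superimpose(self._con(X), self._con(Y))
        _, _, d2 = procrustes_superimpose(self._con(Y), self._con(X))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_matches_scipy_disparity(self):
        from scipy.spatial import procrustes as scipy_procrustes
        rng = np.random.default_rng(3)
        X, Y = rng.normal(size=(5, 2)), rng.normal(size=(5, 2))
        _, _, d = procrustes_superimpose(self._con(X, tuple("ABCDE")),
                                         self._con(Y, tuple("ABCDE")))
        _, _, disparity = scipy_procrustes(X, Y)
        assert d == pytest.approx(disparity, abs=1e-10)

    def test_matches_rotation_grid_oracle(self):
        """Analytic solution equals brute-force rotation x scale scan on
        random 4x2 constellations (within 1e-4)."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            X, Y = rng.normal(size=(4, 2)), rng.normal(size=(4, 2))
            A, B, d = procrustes_superimpose(self._con(X), self._con(Y))
            X0 = X - X.mean(0)
            X0 /= np.linalg.norm(X0)
            Y0 = Y - Y.mean(0)
            Y0 /= np.linalg.norm(Y0)
            best = np.inf
            for th in np.linspace(0, 2 * np.pi, 3000, endpoint=False):
                c, s = np.cos(th), np.sin(th)
                for refl in (1, -1):
                    R = np.array([[c, -s * refl], [s, c * refl]])
                    YR = Y0 @ R
                    scale = np.sum(X0 * YR)       # optimal scale, closed form
                    best = min(best, np.sum((X0 - scale * YR) ** 2))
            assert d == pytest.approx(best, abs=1e-4)

    def test_label_mismatch_rejected(self):
        with pytest.raises(ValueError):
            procrustes_superimpose(self._con(np.eye(3), ("a", "b", "c")),
                                   self._con(np.eye(3), ("a", "b", "x")))


class TestMantel:
    def test_self_correlation_is_one(self):
        D = dm([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]])
        res = mantel(D, D)
        assert res.r == pytest.approx(1.0)

    def test_affine_invariance(self):
        v = np.array([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6],
                      [3, 5, 6, 0]], float)
        D1 = dm(v)
        D2 = dm(2.5 * v + 1.0 * (v > 0))
        assert mantel(D1, D2).r == pytest.approx(1.0)

    def test_exhaustive_label_p_matches_itertools_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(3):
            A = rng.normal(size=(4, 2))
            B = rng.normal(size=(4, 2))
            D1 = dm(np.linalg.norm(A[:, None] - A[None], axis=-1))
            D2 = dm(np.linalg.norm(B[:, None] - B[None], axis=-1))
            res = mantel(D1, D2, scheme="labels")
            assert res.scheme == "labels_exhaustive" and res.n_perm == 24
            iu = np.triu_indices(4, 1)
            v1 = D1.values[iu]
            count = 0
            for perm in itertools.permutations(range(4)):
                p = np.asarray(perm)
                count += _pearson(v1, D2.values[np.ix_(p, p)][iu]) >= \
                    res.r - 1e-12
            assert res.p == pytest.approx(count / 24)

    def test_r_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        A = rng.normal(size=(6, 2))
        B = rng.normal(size=(6, 2))
        D1 = np.linalg.norm(A[:, None] - A[None], axis=-1)
        D2 = np.linalg.norm(B[:, None] - B[None], axis=-1)
        ours = mantel(dm(D1, tuple("ABCDEF")), dm(D2, tuple("ABCDEF")))
        r_ref, _, _ = skbio.stats.distance.mantel(
            skbio.DistanceMatrix(D1), skbio.DistanceMatrix(D2),
            permutations=0)
        assert ours.r == pytest.approx(r_ref, abs=1e-12)

    def test_entries_scheme_exhaustive_for_four_taxa(self):
        D = dm([[0, 1, 2, 3], [1, 0, 4, 5], [2, 4, 0, 6], [3, 5, 6, 0]])
        res = mantel(D, D, scheme="entries")
        assert res.scheme == "entries_exhaustive" and res.n_perm == 720
        assert res.p <= 0.01   # identity-ordered entries are extremal

    def test_constant_entries_rejected(self):
        D = dm(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(ValueError, match="constant"):
            mantel(D, D)


class TestResampling:
    @staticmethod
    def _proportional_setup():
        # 3 taxa, no within-taxon variation; genotype hamming distances
        # exactly proportional to phenotype distances {1, 4, 3}
        scores = np.array([[0.0, 0], [0, 0], [0, 0],
                           [1.0, 0], [1, 0], [1, 0],
                           [4.0, 0], [4, 0], [4, 0]])
        taxa = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        sp = space_from_scores(scores, taxa, ["s"] * 9)
        L = 16
        gA = np.zeros(L)
        gB = np.zeros(L)
        gB[:2] = 2                      # d(A,B) = 4/L/2
        gC = np.zeros(L)
        gC[:8] = 2                      # d(A,C) = 16/L/2, d(B,C) = 12/L/2
        g = np.vstack([gA] * 3 + [gB] * 3 + [gC] * 3)
        table = GenotypeTable(g, np.asarray(taxa, object))
        return sp, table

    def test_proportional_distances_give_r2_one(self):
        sp, table = self._proportional_setup()
        res = resampling_correlation(sp, "s", table, n_draws=300,
                                     n_perm=99, seed=0, n_components=2)
        assert res.R2 == pytest.approx(1.0, abs=1e-10)
        assert res.p <= 0.05

    def test_median_normalization(self):
        sp, table = self._proportional_setup()
        res = resampling_correlation(sp, "s", table, n_draws=301,
                                     n_perm=99, seed=1, n_components=2)
        assert np.median(res.pheno_distances) == pytest.approx(1.0)
        assert np.median(res.geno_distances) == pytest.approx(1.0)

    def test_scale_invariance_of_r2(self):
        sp, table = self._proportional_setup()
        r1 = resampling_correlation(sp, "s", table, n_draws=200, n_perm=49,
                                    seed=3, n_components=2)
        sp2 = space_from_scores(sp.scores * 37.0, sp.taxa, sp.stages)
        r2 = resampling_correlation(sp2, "s", table, n_draws=200, n_perm=49,
                                    seed=3, n_components=2)
        assert r1.R2 == pytest.approx(r2.R2, abs=1e-12)

    def test_null_p_values_uniform_when_no_structure(self):
        """Taxon labels carry no signal -> permutation p is ~Uniform(0,1)
        over replicates (KS sanity check)."""
        from scipy.stats import kstest
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(50):
            scores = rng.normal(size=(18, 3))
            taxa = ["A"] * 6 + ["B"] * 6 + ["C"] * 6
            sp = space_from_scores(scores, taxa, ["s"] * 18)
            g = rng.integers(0, 3, size=(18, 60)).astype(float)
            table = GenotypeTable(g, np.asarray(taxa, object))
            res = resampling_correlation(sp, "s", table, n_draws=250,
                                         n_perm=199, seed=int(rng.integers(2**31)),
                                         n_components=3)
            ps.append(res.p)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_insufficient_shared_taxa_rejected(self):
        sp, table = self._proportional_setup()
        sp2 = space_from_scores(sp.scores[:3], ["A"] * 3, ["s"] * 3)
        with pytest.raises(ValueError, match="shared"):
            resampling_correlation(sp2, "s", table, n_draws=50,
                                   n_perm=9, seed=0, n_components=2)


class TestStagewiseReport:
    def test_report_fields_complete_and_seeded(self, neutral_dataset,
                                               neutral_space, tmp_path):
        F = pm.patterson_pc_distance(neutral_dataset.genotypes)
        reports = pm.stagewise_report(F, neutral_space,
                                      neutral_dataset.genotypes,
                                      n_perm=99, n_draws=200, seed=5,
                                      plot_dir=tmp_path)
        assert [r.stage for r in reports] == ["m2", "M1", "M2", "M3"]
        for r in reports:
            assert -1 <= r.mantel_r <= 1
            assert 0 < r.mantel_p <= 1
            assert 0 <= r.resample_R2 <= 1
            assert r.procrustes_d >= 0
            assert r.seeds and r.n_perm == 99 and r.n_draws == 200
        assert (tmp_path / "overlay_m2.png").exists()
        assert (tmp_path / "scatter_M3.png").exists()
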