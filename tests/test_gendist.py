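"""Genotypic distances: hand-checked formulas, estimator oracles, IO."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

import panmorph as pm
from panmorph.gendist import AlleleFrequencies, GenotypeTable

from conftest import TAXA, tiny_preset


def freqs_2taxa(pa, pb):
    f = np.array([[pa], [pb]], float)
    return AlleleFrequencies(f, np.full((2, 1), 20.0), ("A", "B"), ("L1",))


def table_from_rows(rows_by_taxon):
    geno, taxon = [], []
    for t, rows in rows_by_taxon.items():
        for r in rows:
            geno.append(r)
            taxon.append(t)
    return GenotypeTable(np.asarray(geno, float), np.asarray(taxon, object))


class TestAlleleFrequencies:
    def test_mixed_genotypes_give_half(self):
        t = table_from_rows({"A": [[0], [1], [2]], "B": [[0], [0], [0]]})
        f = pm.allele_frequencies(t)
        assert f.freqs[0, 0] == pytest.approx(0.5)
        assert f.freqs[1, 0] == 0.0

    def test_all_alt_gives_one(self):
        t = table_from_rows({"A": [[2], [2]], "B": [[0], [1]]})
        assert pm.allele_frequencies(t).freqs[0, 0] == 1.0

    @given(st.integers(0, 2 ** 31 - 1))
    def test_matches_direct_tally(self, seed):
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 3, size=(8, 5)).astype(float)
        g[rng.random(g.shape) < 0.2] = np.nan
        taxon = np.array(["A"] * 4 + ["B"] * 4, object)
        if np.isnan(g[:4]).all(axis=0).any() or \
           np.isnan(g[4:]).all(axis=0).any():
            return
        f = pm.allele_frequencies(GenotypeTable(g, taxon))
        for k, rows in enumerate((g[:4], g[4:])):
            for j in range(5):
                col = rows[:, j]
                col = col[~np.isnan(col)]
                assert f.freqs[k, j] == pytest.approx(
                    col.sum() / (2 * len(col)))

    def test_all_missing_cell_is_reported(self):
        g = np.array([[np.nan, 1], [np.nan, 2], [0, 0], [1, 1]], float)
        t = GenotypeTable(g, np.array(["A", "A", "B", "B"], object))
        with pytest.raises(ValueError, match="A"):
            pm.allele_frequencies(t)


class TestNeiAndChord:
    def test_identical_profiles_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 10)
        f = AlleleFrequencies(np.stack([p, p]), np.full((2, 10), 20.0),
                              ("A", "B"), tuple(f"L{i}" for i in range(10)))
        assert pm.nei_standard_distance(f, "A", "B") == pytest.approx(0.0)
        assert pm.chord_distance(f, "A", "B") == pytest.approx(0.0)

    def test_nei_hand_checked_single_locus(self):
        # A fixed alt (p=1), B at p=0.5: J_A=1, J_B=0.5, J_AB=0.5
        f = freqs_2taxa(1.0, 0.5)
        assert pm.nei_standard_distance(f, "A", "B") == pytest.approx(
            0.346574, abs=1e-6)

    def test_nei_infinite_for_alternate_fixation(self):
        f = freqs_2taxa(1.0, 0.0)
        assert pm.nei_standard_distance(f, "A", "B") == np.inf

    def test_chord_hand_checked_alternate_fixation(self):
        f = freqs_2taxa(1.0, 0.0)
        assert pm.chord_distance(f, "A", "B") == pytest.approx(
            0.900316, abs=1e-6)

    def test_nei_da_variant(self):
        f = freqs_2taxa(1.0, 0.5)
        # D_A = 1 - (sqrt(1*0.5) + sqrt(0*0.5))
        assert pm.nei_standard_distance(f, "A", "B", variant="da") == \
            pytest.approx(1 - np.sqrt(0.5))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        f = AlleleFrequencies(rng.uniform(0.05, 0.95, (2, 6)),
                              np.full((2, 6), 30.0), ("A", "B"),
                              tuple(f"L{i}" for i in range(6)))
        assert pm.chord_distance(f, "A", "B") == pytest.approx(
            pm.chord_distance(f, "B", "A"))
        assert pm.nei_standard_distance(f, "A", "B") == pytest.approx(
            pm.nei_standard_distance(f, "B", "A"))


class TestFst:
    def test_identical_columns_near_zero(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 3, size=(10, 50)).astype(float)
        t = GenotypeTable(np.vstack([block, block]),
                          np.array(["A"] * 10 + ["B"] * 10, object))
        assert pm.fst_pairwise(t, "A", "B") == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_give_one(self):
        t = table_from_rows({"A": [[0, 0]] * 5, "B": [[2, 2]] * 5})
        assert pm.fst_pairwise(t, "A", "B") == pytest.approx(1.0)

    def test_exact_frequency_pseudocounts_recover_hudson_formula(self):
        """Estimator with huge samples equals the frequency-level Hudson
        ratio-of-averages."""
        rng = np.random.default_rng(3)
        p1 = rng.uniform(0.1, 0.9, 200)
        p2 = np.clip(p1 + rng.normal(0, 0.15, 200), 0.01, 0.99)
        expect = pm.hudson_fst_from_frequencies(p1, p2)
        n = 4000   # pseudo-counts: genotype columns matching p exactly-ish
        rows = []
        for p in (p1, p2):
            alt = np.round(p * n).astype(int)
            col = np.zeros((n // 2, len(p)))
            for j, a in enumerate(alt):
                col[:a // 2, j] = 2
                if a % 2:
                    col[a // 2, j] = 1
            rows.append(col)
        t = GenotypeTable(np.vstack(rows),
                          np.array(["A"] * (n // 2) + ["B"] * (n // 2),
                                   object))
        assert pm.fst_pairwise(t, "A", "B") == pytest.approx(expect,
                                                             abs=0.005)


class TestPattersonPC:
    def test_identical_rows_give_zero_distances(self):
        rng = np.random.default_rng(0)
        row = rng.integers(0, 3, 40).astype(float)
        jitter = rng.integers(0, 3, 40).astype(float)
        g = np.vstack([row] * 6 + [jitter] * 2)   # need polymorphism
        t = GenotypeTable(g, np.array(["A"] * 3 + ["B"] * 3 + ["C"] * 2,
                                      object))
        D = pm.patterson_pc_distance(t, k=2)
        assert D.pair("A", "B") == pytest.approx(0.0, abs=1e-8)

    def test_rank_order_matches_generator_targets(self):
        """Pairwise D_PPC rank order reproduces the generator's F targets
        in >= 90% of 20 replicates."""
        hits = 0
        for seed in range(20):
            scen = tiny_preset("neutral_congruent", seed=seed,
                               n_loci=1000, n_geno_per_taxon=20)
            table = pm.make_genotypes(scen)
            D = pm.patterson_pc_distance(table)
            target = scen.fst_matrix[np.triu_indices(4, 1)]
            got = D.offdiag()
            hits += np.array_equal(np.argsort(target), np.argsort(got))
        assert hits >= 18

    def test_k_too_large_rejected(self):
        scen = tiny_preset("neutral_congruent", n_geno_per_taxon=3,
                           n_loci=60)
        table = pm.make_genotypes(scen)
        with pytest.raises(ValueError, match="exceeds"):
            pm.patterson_pc_distance(table, k=50)


class TestBuildF:
    def test_all_kinds_present_and_concordant(self):
        scen = tiny_preset("neutral_congruent", n_loci=1000,
                           n_geno_per_taxon=20, seed=9)
        table = pm.make_genotypes(scen)
        mats = pm.build_F_matrices(table)
        assert set(mats) == {"F_nei", "F_chord", "F_fst", "F_ppc"}
        for m in mats.values():
            assert m.n == 4 and np.allclose(m.values, m.values.T)
        for a, b in itertools.combinations(mats.values(), 2):
            r = pm.mantel(a, b, scheme="entries").r
            assert r > 0.9

    def test_determinism(self):
        scen = tiny_preset("neutral_congruent", seed=4)
        t = pm.make_genotypes(scen)
        d1 = pm.build_F_matrices(t)["F_fst"].values
        d2 = pm.build_F_matrices(t)["F_fst"].values
        assert np.array_equal(d1, d2)


class TestIO:
    def test_csv_roundtrip(self, tmp_path):
        scen = tiny_preset("neutral_congruent", n_loci=20,
                           n_geno_per_taxon=3)
        t = pm.make_genotypes(scen)
        t.to_csv(tmp_path / "g.csv")
        back = GenotypeTable.from_csv(tmp_path / "g.csv")
        assert np.array_equal(back.genotypes, t.genotypes)
        assert list(back.taxon) == list(t.taxon)

    def test_vcf_roundtrip_with_missing(self, tmp_path):
        g = np.array([[0, 1, 2], [2, np.nan, 0], [1, 1, 1], [0, 0, 2]],
                     float)
        t = GenotypeTable(g, np.array(["A", "A", "B", "B"], object),
                          ("rs1", "rs2", "rs3"),
                          ("A_0", "A_1", "B_0", "B_1"))
        t.to_vcf(tmp_path / "g.vcf")
        back = GenotypeTable.from_vcf(tmp_path / "g.vcf")
        assert np.array_equal(np.isnan(back.genotypes),
                              np.isnan(t.genotypes))
        ok = ~np.isnan(g)
        assert np.array_equal(back.genotypes[ok], g[ok])
        assert list(back.taxon) == ["A", "A", "B", "B"]
        assert back.locus_ids == ("rs1", "rs2", "rs3")

    def test_allele_sharing_distance(self):
        assert pm.allele_sharing_distance([0, 2, 1], [2, 2, 1]) == \
            pytest.approx(1 / 3)
        assert pm.allele_sharing_distance([0, np.nan], [2, 1]) == \
            pytest.approx(1.0)
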