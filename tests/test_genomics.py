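import numpy as np
import pytest

from wssgblup.genomics import (
    MISSING_DOSAGE,
    AlleleFrequencies,
    GenotypeError,
    GenotypeMatrix,
    SnpWeights,
    allele_frequencies,
    blend_G,
    build_G,
    build_H_inverse,
    center_dosages,
    qc_filter,
    read_plink_text,
    write_plink_text,
)
from wssgblup.pedigree import (
    RelationshipMatrix,
    build_A_inverse,
    build_A_tabular,
    extract_A22,
)
import sys, pathlib

sys.path.insert(0, str(pathlib.Path(__file__).parent))
from conftest import random_pedigree


def make_genotypes(dosage, chrom=None, pos=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    n, S = dosage.shape
    return GenotypeMatrix(
        animal_ids=[f"an{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(S)],
        chrom=np.array(chrom if chrom is not None else ["1"] * S, dtype=object),
        pos_bp=np.array(pos if pos is not None else np.arange(1, S + 1) * 1000, dtype=np.int64),
        dosage=dosage,
        counted_allele=np.array(["A"] * S, dtype=object),
        other_allele=np.array(["B"] * S, dtype=object),
    )


class TestPlinkText:
    def test_basic_dosage_coding(self, tmp_path):
        (tmp_path / "g.map").write_text("1\tsnp1\t0\t100\n")
        (tmp_path / "g.ped").write_text(
            "F a1 0 0 0 -9 A A\nF a2 0 0 0 -9 A G\n"
        )
        g = read_plink_text(tmp_path / "g.ped", tmp_path / "g.map")
        np.testing.assert_array_equal(g.dosage[:, 0], [2, 1])
        assert g.counted_allele[0] == "A"

    def test_missing_genotype(self, tmp_path):
        (tmp_path / "g.map").write_text("1\tsnp1\t0\t100\n")
        (tmp_path / "g.ped").write_text("F a1 0 0 0 -9 0 0\n")
        g = read_plink_text(tmp_path / "g.ped", tmp_path / "g.map")
        assert g.dosage[0, 0] == MISSING_DOSAGE

    def test_ragged_row_raises_with_line(self, tmp_path):
        (tmp_path / "g.map").write_text("1\tsnp1\t0\t100\n")
        (tmp_path / "g.ped").write_text("F a1 0 0 0 -9 A A G\n")
        with pytest.raises(GenotypeError, match=":1"):
            read_plink_text(tmp_path / "g.ped", tmp_path / "g.map")

    def test_third_allele_raises(self, tmp_path):
        (tmp_path / "g.map").write_text("1\tsnp1\t0\t100\n")
        (tmp_path / "g.ped").write_text("F a1 0 0 0 -9 A G\nF a2 0 0 0 -9 C C\n")
        with pytest.raises(GenotypeError, match="two alleles"):
            read_plink_text(tmp_path / "g.ped", tmp_path / "g.map")

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(3, 3)).astype(np.int8)
        dosage[1, 2] = MISSING_DOSAGE
        g = make_genotypes(dosage, chrom=["1", "1", "2"], pos=[10, 500, 77])
        write_plink_text(g, tmp_path / "rt.ped", tmp_path / "rt.map")
        g2 = read_plink_text(tmp_path / "rt.ped", tmp_path / "rt.map")
        np.testing.assert_array_equal(g.dosage, g2.dosage)
        assert g2.snp_ids == g.snp_ids
        np.testing.assert_array_equal(g2.pos_bp, g.pos_bp)
        # second round trip is byte-identical
        write_plink_text(g2, tmp_path / "rt2.ped", tmp_path / "rt2.map")
        assert (tmp_path / "rt.ped").read_text() == (tmp_path / "rt2.ped").read_text()
        assert (tmp_path / "rt.map").read_text() == (tmp_path / "rt2.map").read_text()


class TestPlinkRaw:
    def test_reads_dosages_and_counted_alleles(self, tmp_path):
        from wssgblup.genomics import read_plink_raw

        (tmp_path / "g.raw").write_text(
            "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_G\n"
            "F a1 0 0 0 -9 2 0\n"
            "F a2 0 0 0 -9 1 NA\n"
        )
        g = read_plink_raw(tmp_path / "g.raw")
        assert g.animal_ids == ["a1", "a2"]
        assert g.snp_ids == ["snp1", "snp2"]
        assert list(g.counted_allele) == ["A", "G"]
        np.testing.assert_array_equal(g.dosage[:, 0], [2, 1])
        assert g.dosage[1, 1] == MISSING_DOSAGE


class TestTsvExport:
    def test_dense_and_sparse_round_trip(self, tmp_path):
        import pandas as pd
        from wssgblup.pedigree import build_A_inverse
        import sys, pathlib as pl

        sys.path.insert(0, str(pl.Path(__file__).parent))
        from conftest import random_pedigree

        ped = random_pedigree(12, seed=0)
        A = build_A_tabular(ped)
        A.to_tsv(tmp_path / "A.tsv")
        back = pd.read_csv(tmp_path / "A.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(back.to_numpy(), A.values)

        Ainv = build_A_inverse(ped)
        Ainv.to_tsv(tmp_path / "Ainv.tsv")
        trip = pd.read_csv(tmp_path / "Ainv.tsv", sep="\t")
        import scipy.sparse as sp

        rebuilt = sp.coo_matrix(
            (trip["value"], (trip["row"], trip["col"])), shape=(ped.n, ped.n)
        )
        np.testing.assert_allclose(rebuilt.toarray(), Ainv.values.toarray(), atol=1e-12)


class TestQC:
    def test_monomorphic_snp_removed(self):
        g = make_genotypes([[2, 1], [2, 1], [2, 0]])
        g2, rep = qc_filter(g)
        assert g2.snp_ids == ["s1"]
        assert rep.n_snps_low_maf == 1

    def test_low_callrate_individual_removed(self):
        dosage = np.ones((3, 4), dtype=np.int8)
        dosage[:, 0] = [0, 1, 2]  # keep SNPs polymorphic
        dosage[2, :2] = MISSING_DOSAGE  # 50% missing
        g = make_genotypes(dosage)
        g2, rep = qc_filter(g, ind_callrate_min=0.9)
        assert rep.n_animals_low_callrate == 1
        assert g2.animal_ids == ["an0", "an1"]

    def test_nonautosomal_dropped_first(self):
        g = make_genotypes([[0, 1], [1, 1], [2, 0]], chrom=["30", "1"])
        g2, rep = qc_filter(g)
        assert rep.n_snps_nonautosomal == 1
        assert g2.chrom.tolist() == ["1"]

    def test_constructed_counts_exact(self):
        """Fixture built to violate each filter by known counts."""
        rng = np.random.default_rng(5)
        n, S = 40, 10
        dosage = rng.integers(0, 3, size=(n, S)).astype(np.int8)
        # 3 SNPs made (nearly) monomorphic: maf < 0.01 given 40 animals
        for j in (2, 5, 7):
            dosage[:, j] = 2
        # one animal with 60% missing
        dosage[4, :6] = MISSING_DOSAGE
        chrom = ["1"] * 8 + ["X", "22"]  # one non-autosomal
        g = make_genotypes(dosage, chrom=chrom, pos=list(range(1, 9)) + [1, 2])
        g2, rep = qc_filter(g)
        assert rep.n_snps_nonautosomal == 1
        assert rep.n_animals_low_callrate == 1
        assert rep.n_snps_low_maf == 3
        assert rep.n_snps_out == 6
        assert rep.n_animals_out == 39

    def test_all_snps_removed_raises(self):
        g = make_genotypes([[2], [2]])
        with pytest.raises(GenotypeError, match="all SNPs"):
            qc_filter(g)

    def test_post_qc_invariants(self):
        rng = np.random.default_rng(11)
        dosage = rng.integers(0, 3, size=(30, 50)).astype(np.int8)
        g = make_genotypes(dosage, chrom=rng.choice(["1", "2", "30"], size=50).tolist(),
                           pos=rng.integers(1, 10**6, size=50).tolist())
        g2, _ = qc_filter(g.sorted_by_map())
        f = allele_frequencies(g2)
        assert np.all(f.maf >= 0.01) and np.all(f.maf <= 0.5)
        assert set(g2.chrom) <= {"1", "2"}


class TestFrequencies:
    def test_simple(self):
        f = allele_frequencies(make_genotypes([[0], [1], [2]]))
        assert f.p[0] == pytest.approx(0.5)
        assert f.two_pq_sum == pytest.approx(0.5)

    def test_missing_excluded(self):
        f = allele_frequencies(make_genotypes([[2], [2], [MISSING_DOSAGE]]))
        assert f.p[0] == pytest.approx(1.0)
        assert f.maf[0] == pytest.approx(0.0)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        dosage[rng.random(dosage.shape) < 0.1] = MISSING_DOSAGE
        g = make_genotypes(dosage)
        f = allele_frequencies(g)
        for j in range(50):
            col = [d for d in dosage[:, j] if d != MISSING_DOSAGE]
            assert f.p[j] == pytest.approx(sum(col) / (2 * len(col)))


class TestCentering:
    def test_column_values(self):
        g = make_genotypes([[0], [1], [2]])
        Z = center_dosages(g, allele_frequencies(g))
        np.testing.assert_allclose(Z[:, 0], [-1, 0, 1])

    def test_missing_imputed_to_zero(self):
        g = make_genotypes([[0], [2], [MISSING_DOSAGE]])
        Z = center_dosages(g, allele_frequencies(g))
        assert Z[2, 0] == 0.0

    def test_column_mean_zero_without_missing(self):
        rng = np.random.default_rng(8)
        g = make_genotypes(rng.integers(0, 3, size=(15, 9)).astype(np.int8))
        Z = center_dosages(g, allele_frequencies(g))
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)


class TestG:
    def test_hand_example_one_snp(self):
        # dosages [0, 2], p = 0.5: Z = [-1, 1], divisor 2*0.5*0.5 = 0.5
        g = make_genotypes([[0], [2]])
        f = allele_frequencies(g)
        G = build_G(center_dosages(g, f), f)
        np.testing.assert_allclose(G.values, [[2, -2], [-2, 2]])

    def test_unit_weights_equal_unweighted(self):
        rng = np.random.default_rng(2)
        g = make_genotypes(rng.integers(0, 3, size=(10, 30)).astype(np.int8))
        f = allele_frequencies(g)
        Z = center_dosages(g, f)
        G0 = build_G(Z, f).values
        G1 = build_G(Z, f, weights=SnpWeights.identity(30)).values
        np.testing.assert_allclose(G0, G1)

    def test_diag_mean_near_one_under_hwe(self):
        rng = np.random.default_rng(7)
        n, S = 500, 400
        p = rng.uniform(0.1, 0.9, size=S)
        dosage = (rng.random((n, S)) < p).astype(np.int8) + (rng.random((n, S)) < p).astype(np.int8)
        g = make_genotypes(dosage)
        f = AlleleFrequencies(p=p, maf=np.minimum(p, 1 - p),
                              two_pq_sum=float((2 * p * (1 - p)).sum()))
        G = build_G(center_dosages(g, f), f)
        assert abs(np.diag(G.values).mean() - 1.0) < 0.05

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        g = make_genotypes(rng.integers(0, 3, size=(8, 20)).astype(np.int8))
        f = allele_frequencies(g)
        Z = center_dosages(g, f)
        G = build_G(Z, f).values
        perm = rng.permutation(8)
        Gp = build_G(Z[perm], f).values
        np.testing.assert_allclose(Gp, G[np.ix_(perm, perm)])


class TestTuneG:
    def test_tuned_means_match_A22(self):
        from wssgblup.genomics import tune_G_to_A22

        rng = np.random.default_rng(12)
        g = make_genotypes(rng.integers(0, 3, size=(15, 80)).astype(np.int8))
        f = allele_frequencies(g)
        G = build_G(center_dosages(g, f), f)
        ped = random_pedigree(15, seed=3)
        A22 = extract_A22(ped, list(ped.ids))
        Gt = tune_G_to_A22(G, A22).dense()
        n = 15
        off = ~np.eye(n, dtype=bool)
        assert np.trace(Gt) / n == pytest.approx(np.trace(A22.dense()) / n, abs=1e-10)
        assert Gt[off].mean() == pytest.approx(A22.dense()[off].mean(), abs=1e-10)


class TestBlendAndH:
    def test_blend_extremes(self):
        G = RelationshipMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]), "G")
        A22 = RelationshipMatrix(["a", "b"], np.eye(2), "A22")
        assert blend_G(G, A22, alpha=0) is G
        np.testing.assert_allclose(blend_G(G, A22, alpha=1).values, np.eye(2))

    def test_blend_fixes_singular_G(self):
        # duplicate animals make G exactly singular
        g = make_genotypes([[0, 1, 2], [0, 1, 2], [2, 1, 0]])
        f = allele_frequencies(g)
        G = build_G(center_dosages(g, f), f)
        A22 = RelationshipMatrix(list("abc"), np.eye(3), "A22")
        assert np.linalg.eigvalsh(G.values)[0] == pytest.approx(0, abs=1e-10)
        Gb = blend_G(G, A22, alpha=0.05)
        assert np.linalg.eigvalsh(Gb.values)[0] > 0

    def test_no_genotyped_animals_returns_A_inverse(self):
        ped = random_pedigree(20, seed=1)
        A_inv = build_A_inverse(ped)
        H = build_H_inverse(A_inv, None, None, np.array([], dtype=np.int64))
        np.testing.assert_allclose(H.values.toarray(), A_inv.values.toarray())

    def test_G_equal_A22_gives_A_inverse(self):
        ped = random_pedigree(25, seed=2)
        A_inv = build_A_inverse(ped)
        ids = [ped.ids[i] for i in range(10, 20)]
        A22 = extract_A22(ped, ids)
        G = RelationshipMatrix(list(ids), A22.dense().copy(), "G")
        H = build_H_inverse(A_inv, A22, G, ped.codes(ids))
        np.testing.assert_allclose(
            H.values.toarray(), A_inv.values.toarray(), atol=1e-8
        )

    def test_all_genotyped_matches_dense_oracle(self):
        """H from the composite formula, inverted densely, matches H^-1."""
        ped = random_pedigree(20, seed=3)
        rng = np.random.default_rng(0)
        dosage = rng.integers(0, 3, size=(20, 60)).astype(np.int8)
        g = make_genotypes(dosage)
        f = allele_frequencies(g)
        G = build_G(center_dosages(g, f), f)
        G.labels = list(ped.ids)
        A22 = extract_A22(ped, list(ped.ids))
        Gb = blend_G(G, A22, alpha=0.05)
        A_inv = build_A_inverse(ped)
        H_inv = build_H_inverse(A_inv, A22, Gb, np.arange(20))
        # oracle: with everyone genotyped, H = G_blended exactly
        A = build_A_tabular(ped).values
        H_dense = A + (Gb.dense() - A22.dense())  # A22 = A here
        np.testing.assert_allclose(
            H_inv.values.toarray(), np.linalg.inv(H_dense), atol=1e-8
        )

    def test_correction_confined_to_genotyped_block(self):
        ped = random_pedigree(30, seed=5)
        rng = np.random.default_rng(1)
        ids = [ped.ids[i] for i in rng.choice(30, size=12, replace=False)]
        dosage = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        g = make_genotypes(dosage)
        f = allele_frequencies(g)
        G = build_G(center_dosages(g, f), f)
        G.labels = list(ids)
        A22 = extract_A22(ped, ids)
        Gb = blend_G(G, A22, 0.05)
        A_inv = build_A_inverse(ped)
        H_inv = build_H_inverse(A_inv, A22, Gb, ped.codes(ids))
        diff = (H_inv.values - A_inv.values).toarray()
        mask = np.zeros((30, 30), dtype=bool)
        idx = ped.codes(ids)
        mask[np.ix_(idx, idx)] = True
        assert np.abs(diff[~mask]).max() < 1e-12

    def test_singular_G_raises_pointing_to_blending(self):
        ped = random_pedigree(10, seed=6)
        ids = [ped.ids[0], ped.ids[1]]
        A22 = extract_A22(ped, ids)
        G = RelationshipMatrix(ids, np.ones((2, 2)), "G")  # singular
        with pytest.raises(GenotypeError, match="blend"):
            build_H_inverse(build_A_inverse(ped), A22, G, ped.codes(ids))
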