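import numpy as np
import pandas as pd
import pytest

import gblupgwas as g
from gblupgwas.geno_io import (GenotypeParseError, founder_allele_freqs,
                               mean_impute, qc_filter, read_genotypes,
                               read_marker_map, write_dosage_tsv,
                               write_plink_raw)


def _toy_geno(dosage, snp_ids=None, samples=None, chrom=None, pos=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    snp_ids = snp_ids or [f"s{j}" for j in range(m)]
    mm = g.MarkerMap(
        np.asarray(snp_ids, dtype=object),
        np.asarray(chrom or ["1"] * m, dtype=object),
        np.asarray(pos if pos is not None else np.arange(1, m + 1)),
    )
    samples = samples or [f"a{i}" for i in range(n)]
    return g.GenotypeMatrix(np.asarray(samples, dtype=object), mm, dosage)


def _sample_table(ids, founder):
    return g.SampleTable(pd.DataFrame(
        {"founder": founder}, index=pd.Index(ids, name="sample_id")))


class TestReaders:
    def test_dosage_tsv_with_missing(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\ts1\ts2\ts3\n"
                        "a\t0\tNA\t2\n"
                        "b\t1\t1\t0\n")
        geno = read_genotypes(path, fmt="dosage-tsv")
        assert geno.dosage.shape == (2, 3)
        assert geno.missing_mask.sum() == 1
        assert np.isnan(geno.dosage[0, 1])
        assert list(geno.samples) == ["a", "b"]
        assert list(geno.markers.snp_id) == ["s1", "s2", "s3"]

    def test_empty_file_is_an_error(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(GenotypeParseError, match="empty"):
            read_genotypes(path, fmt="dosage-tsv")

    def test_ragged_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("sample_id\ts1\ts2\na\t0\n")
        with pytest.raises(GenotypeParseError, match="line 2"):
            read_genotypes(path, fmt="dosage-tsv")

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "g.tsv"
        path.write_text("sample_id\ts1\na\t0\n")
        with pytest.raises(ValueError, match="format"):
            read_genotypes(path, fmt="vcf")

    def test_plink_raw_round_trip_of_simulated_data(self, tmp_path, sim300):
        geno = sim300.geno
        path = tmp_path / "g.raw"
        write_plink_raw(geno, path)
        back = read_genotypes(path, fmt="plink-raw",
                              marker_map=geno.markers)
        assert list(back.samples) == list(geno.samples)
        assert list(back.markers.snp_id) == list(geno.markers.snp_id)
        np.testing.assert_array_equal(back.dosage, geno.dosage)

    def test_dosage_tsv_round_trip_preserves_missing(self, tmp_path):
        geno = _toy_geno([[0, np.nan], [2, 1]])
        path = tmp_path / "g.tsv"
        write_dosage_tsv(geno, path)
        back = read_genotypes(path, fmt="dosage-tsv")
        np.testing.assert_array_equal(back.missing_mask, geno.missing_mask)
        np.testing.assert_array_equal(back.dosage[~back.missing_mask],
                                      geno.dosage[~geno.missing_mask])

    def test_plink_bed_round_trip(self, tmp_path):
        # write a tiny SNP-major .bed triplet by hand: codes 00=2, 10=1, 11=0, 01=NA
        dosage = np.array([[0, 1, 2], [2, np.nan, 1], [1, 0, 0], [0, 2, 2]],
                          dtype=float)
        n, m = dosage.shape
        code = {0.0: 0b11, 1.0: 0b10, 2.0: 0b00}
        body = bytearray()
        for j in range(m):
            for start in range(0, n, 4):
                byte = 0
                for k, i in enumerate(range(start, min(start + 4, n))):
                    v = dosage[i, j]
                    c = 0b01 if np.isnan(v) else code[v]
                    byte |= c << (2 * k)
                body.append(byte)
        (tmp_path / "toy.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]) + bytes(body))
        (tmp_path / "toy.fam").write_text(
            "".join(f"f{i} ind{i} 0 0 0 -9\n" for i in range(n)))
        (tmp_path / "toy.bim").write_text(
            "".join(f"1 snp{j} 0 {j+1} A G\n" for j in range(m)))
        geno = read_genotypes(tmp_path / "toy.bed", fmt="plink-bed")
        assert list(geno.samples) == [f"ind{i}" for i in range(n)]
        np.testing.assert_array_equal(geno.dosage, dosage)

    def test_marker_map_requires_columns(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text("snp\tchr\n")
        with pytest.raises(GenotypeParseError):
            read_marker_map(path)


class TestQcFilter:
    def test_clean_matrix_unchanged(self):
        geno = _toy_geno([[0, 1, 2], [1, 1, 0], [2, 1, 1], [1, 0, 2]])
        out, report = qc_filter(geno)
        np.testing.assert_array_equal(out.dosage, geno.dosage)
        assert (report.markers_unmapped, report.samples_missingness,
                report.markers_missingness, report.markers_maf) == (0, 0, 0, 0)

    def test_monomorphic_marker_removed_by_maf_rule(self):
        geno = _toy_geno([[0, 1], [0, 1], [0, 2], [0, 0]])
        out, report = qc_filter(geno)
        assert report.markers_maf == 1
        assert list(out.markers.snp_id) == ["s1"]

    def test_hand_enumerated_toy_counts(self):
        # 10 samples x 12 markers, enumerated by hand:
        # sample a9 misses 3/12 markers (25% > 10%) -> removed first;
        # marker s0 then misses 2/9 calls (22% > 10%) -> removed;
        # samples a0/a1 miss only 1/12 (8.3% <= 10%) -> retained.
        dosage = ((np.arange(10)[:, None] + np.arange(12)[None, :]) % 3
                  ).astype(float)
        dosage[0, 0] = np.nan
        dosage[1, 0] = np.nan
        dosage[9, 1] = np.nan
        dosage[9, 2] = np.nan
        dosage[9, 3] = np.nan
        geno = _toy_geno(dosage)
        out, report = qc_filter(geno)
        assert report.samples_missingness == 1
        assert report.markers_missingness == 1
        assert report.markers_maf == 0
        assert "a9" not in list(out.samples)
        assert "s0" not in list(out.markers.snp_id)
        assert out.dosage.shape == (9, 11)

    def test_unmapped_markers_dropped_first(self):
        geno = _toy_geno([[0, 1], [1, 2], [2, 1], [1, 0]], pos=[5, -1])
        out, report = qc_filter(geno)
        assert report.markers_unmapped == 1
        assert list(out.markers.snp_id) == ["s0"]

    def test_idempotent(self, sim300):
        rng = np.random.default_rng(0)
        dosage = sim300.geno.dosage.copy()
        mask = rng.random(dosage.shape) < 0.03
        dosage[mask] = np.nan
        geno = g.GenotypeMatrix(sim300.geno.samples, sim300.geno.markers, dosage)
        once, _ = qc_filter(geno)
        twice, rep2 = qc_filter(once)
        np.testing.assert_array_equal(once.dosage, twice.dosage)
        assert (rep2.markers_maf == 0 and rep2.markers_missingness == 0
                and rep2.samples_missingness == 0)

    def test_everything_removed_is_explicit_error(self):
        geno = _toy_geno([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="empty after QC"):
            qc_filter(geno)


class TestFounderFreqs:
    def test_forced_arithmetic(self):
        geno = _toy_geno([[0], [1], [1], [2]])
        st = _sample_table([f"a{i}" for i in range(4)], [True] * 4)
        assert founder_allele_freqs(geno, st)[0] == pytest.approx(0.5)

    def test_all_reference_homozygotes(self):
        geno = _toy_geno([[2], [2]])
        st = _sample_table(["a0", "a1"], [True, True])
        assert founder_allele_freqs(geno, st)[0] == pytest.approx(1.0)

    def test_matches_hand_tally_and_ignores_non_founders(self):
        rng = np.random.default_rng(3)
        dosage = rng.integers(0, 3, size=(9, 6)).astype(float)
        dosage[0, 2] = np.nan  # missing founder call at marker 2
        founders = [True] * 6 + [False] * 3
        ids = [f"a{i}" for i in range(9)]
        geno = _toy_geno(dosage)
        st = _sample_table(ids, founders)
        p = founder_allele_freqs(geno, st)
        for j in range(6):
            calls = [dosage[i, j] for i in range(6) if not np.isnan(dosage[i, j])]
            assert p[j] == pytest.approx(sum(calls) / (2 * len(calls)))
        # non-founder genotypes are irrelevant
        dosage2 = dosage.copy()
        dosage2[6:] = 2.0
        p2 = founder_allele_freqs(_toy_geno(dosage2), st)
        np.testing.assert_allclose(p, p2)
        # sample order is irrelevant
        order = rng.permutation(9)
        geno3 = _toy_geno(dosage[order], samples=[ids[i] for i in order])
        st3 = _sample_table(ids, founders)
        np.testing.assert_allclose(founder_allele_freqs(geno3, st3), p)

    def test_marker_with_no_founder_call_errors(self):
        dosage = np.array([[np.nan, 1.0], [1.0, 1.0]])
        st = _sample_table(["a0", "a1"], [True, False])
        with pytest.raises(ValueError, match="founder"):
            founder_allele_freqs(_toy_geno(dosage), st)


class TestMeanImpute:
    def test_missing_replaced_by_expected_dosage(self):
        geno = _toy_geno([[np.nan], [0.0]])
        out = mean_impute(geno, np.array([0.25]))
        assert out.dosage[0, 0] == pytest.approx(0.5)
        assert not out.missing_mask.any()

    def test_no_missing_is_identity(self):
        geno = _toy_geno([[0, 1], [2, 1]])
        out = mean_impute(geno, np.array([0.5, 0.5]))
        assert out is geno

    def test_misaligned_frequency_vector(self):
        geno = _toy_geno([[0, 1], [2, 1]])
        with pytest.raises(ValueError, match="length"):
            mean_impute(geno, np.array([0.5]))

    def test_imputed_cells_have_zero_standardized_deviation(self):
        p = np.array([0.3, 0.6])
        geno = _toy_geno([[np.nan, 1.0], [2.0, np.nan], [1.0, 0.0]])
        filled = mean_impute(geno, p)
        Z = g.standardize(filled, p)
        assert Z.Z[0, 0] == pytest.approx(0.0)
        assert Z.Z[1, 1] == pytest.approx(0.0)
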