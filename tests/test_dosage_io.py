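import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polygs import (
    DosageMatrix,
    PhenotypeVector,
    filter_maf,
    impute_missing,
    indicator_expand,
    pseudodiploid_recode,
    read_matrix,
    read_phenotypes,
    read_vcf_dosage,
    write_matrix,
    write_phenotypes,
)
from polygs.dosage_io import align, write_vcf

from conftest import random_panel


class TestDosageMatrix:
    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match=r"\[0, 4\]"):
            DosageMatrix(np.array([[5.0]]), 4, ["s1"])

    def test_rejects_duplicate_samples(self):
        with pytest.raises(ValueError, match="unique"):
            DosageMatrix(np.zeros((2, 1)), 4, ["s1", "s1"])

    def test_allele_freq_is_mean_over_ploidy(self):
        d = DosageMatrix(np.array([[0.0], [4.0], [2.0]]), 4, ["a", "b", "c"])
        assert d.allele_freq[0] == pytest.approx(0.5)

    def test_allele_freq_ignores_missing(self):
        d = DosageMatrix(np.array([[0.0], [4.0], [np.nan]]), 4, ["a", "b", "c"])
        assert d.allele_freq[0] == pytest.approx(0.5)


class TestVcf:
    def _write_demo_vcf(self, path):
        lines = [
            "##fileformat=VCFv4.2",
            "##contig=<ID=1>",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2",
            # biallelic SNP: dosages 3 and 0
            "1\t100\tsnp1\tA\tC\t.\tPASS\t.\tGT\t0/1/1/1\t0/0/0/0",
            # fully missing call in s2
            "1\t200\tsnp2\tG\tT\t.\tPASS\t.\tGT\t1/1/1/1\t./././.",
            # multiallelic: dropped
            "1\t300\tsnp3\tA\tC,G\t.\tPASS\t.\tGT\t0/0/1/2\t0/0/0/0",
            # indel: dropped
            "1\t400\tindel1\tAT\tA\t.\tPASS\t.\tGT\t0/0/0/1\t0/0/0/0",
        ]
        path.write_text("\n".join(lines) + "\n")

    def test_alt_allele_count_and_missing(self, tmp_path):
        vcf = tmp_path / "demo.vcf"
        self._write_demo_vcf(vcf)
        d, report = read_vcf_dosage(str(vcf), ploidy=4)
        assert d.values[0, 0] == 3  # 0/1/1/1
        assert d.values[1, 0] == 0
        assert np.isnan(d.values[1, 1])  # ./././.
        assert report == {"kept": 2, "multiallelic_dropped": 1, "indel_dropped": 1}
        assert d.marker_meta["pos"].tolist() == [100, 200]

    def test_gt_arity_mismatch_names_record(self, tmp_path):
        vcf = tmp_path / "demo.vcf"
        self._write_demo_vcf(vcf)
        with pytest.raises(ValueError, match="1:100"):
            read_vcf_dosage(str(vcf), ploidy=2)

    def test_vcf_round_trip(self, tmp_path):
        d = random_panel(8, 12, seed=3)
        write_vcf(d, str(tmp_path / "rt.vcf"))
        d2, _ = read_vcf_dosage(str(tmp_path / "rt.vcf"), ploidy=4)
        np.testing.assert_array_equal(d.values, d2.values)
        assert d2.sample_ids == d.sample_ids
        assert d2.marker_ids == d.marker_ids


class TestMatrixRoundTrip:
    def test_round_trip_preserves_values_and_metadata(self, tmp_path, toy_panel):
        path = str(tmp_path / "d.csv")
        write_matrix(toy_panel, path)
        d2 = read_matrix(path)
        np.testing.assert_array_equal(toy_panel.values, d2.values)
        assert d2.ploidy == toy_panel.ploidy
        assert d2.sample_ids == toy_panel.sample_ids
        pd.testing.assert_frame_equal(
            d2.marker_meta, toy_panel.marker_meta, check_dtype=False
        )

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000), n=st.integers(2, 8), m=st.integers(1, 10))
    def test_round_trip_random_panels(self, tmp_path_factory, seed, n, m):
        d = random_panel(n, m, seed=seed, polymorphic=False)
        path = str(tmp_path_factory.mktemp("rt") / "d.csv")
        write_matrix(d, path)
        np.testing.assert_array_equal(read_matrix(path).values, d.values)

    def test_phenotype_round_trip(self, tmp_path, toy_phenotype):
        path = str(tmp_path / "y.csv")
        write_phenotypes(toy_phenotype, path)
        y2 = read_phenotypes(path)
        np.testing.assert_allclose(y2.values, toy_phenotype.values)
        assert y2.sample_ids == toy_phenotype.sample_ids


class TestImputeMissing:
    def test_mean_imputation(self):
        d = DosageMatrix(np.array([[0.0], [4.0], [np.nan]]), 4, ["a", "b", "c"])
        out = impute_missing(d)
        assert out.values[2, 0] == pytest.approx(2.0)

    def test_identity_when_complete(self, toy_panel):
        out = impute_missing(toy_panel)
        np.testing.assert_array_equal(out.values, toy_panel.values)

    def test_mean_preservation_under_random_masking(self):
        d = random_panel(40, 30, seed=7)
        rng = np.random.default_rng(1)
        vals = d.values.copy()
        mask = rng.random(vals.shape) < 0.10
        # keep at least one observed value per marker
        mask[0, :] = False
        masked = DosageMatrix(
            np.where(mask, np.nan, vals), 4, d.sample_ids, d.marker_meta
        )
        expected = np.nanmean(masked.values, axis=0)
        out = impute_missing(masked)
        np.testing.assert_allclose(out.values.mean(axis=0), expected, atol=1e-12)
        assert not out.has_missing

    def test_fully_missing_marker_dropped(self):
        vals = np.array([[1.0, np.nan], [2.0, np.nan]])
        d = DosageMatrix(vals, 4, ["a", "b"])
        with pytest.warns(UserWarning, match="fully missing"):
            out = impute_missing(d)
        assert out.n_markers == 1


class TestFilterMaf:
    def test_monomorphic_always_removed(self):
        vals = np.array([[0.0, 1.0], [0.0, 3.0]])
        d = DosageMatrix(vals, 4, ["a", "b"])
        out = filter_maf(d, maf_min=0.0)
        assert out.n_markers == 1
        assert out.marker_ids == [d.marker_ids[1]]

    def test_threshold_retains_above(self):
        # p = 0.10 with 10 tetraploid individuals: dosage sum 4
        vals = np.zeros((10, 1))
        vals[0, 0] = 4
        d = DosageMatrix(vals, 4, [f"s{i}" for i in range(10)])
        assert filter_maf(d, maf_min=0.05).n_markers == 1

    def test_all_removed_raises(self):
        d = DosageMatrix(np.zeros((3, 2)), 4, ["a", "b", "c"])
        with pytest.raises(ValueError, match="no markers pass"):
            filter_maf(d, maf_min=0.0)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_retained_count_matches_direct_scan(self, seed):
        d = random_panel(15, 25, seed=seed, polymorphic=False)
        maf_min = 0.1
        p = d.values.mean(axis=0) / 4
        expected = sum(
            1 for pi in p if min(pi, 1 - pi) >= maf_min and min(pi, 1 - pi) > 0
        )
        if expected == 0:
            with pytest.raises(ValueError):
                filter_maf(d, maf_min)
        else:
            assert filter_maf(d, maf_min).n_markers == expected

    def test_post_filter_frequencies_are_interior(self):
        d = random_panel(20, 50, seed=11, polymorphic=False)
        out = filter_maf(impute_missing(d), 0.05)
        p = out.allele_freq
        assert np.all((p > 0) & (p < 1))
        assert np.all(np.isfinite(1.0 / (p * (1 - p))))


class TestPseudodiploidRecode:
    @pytest.mark.parametrize(
        "dosage,expected", [(0, 0), (1, 1), (2, 1), (3, 1), (4, 2)]
    )
    def test_mapping(self, dosage, expected):
        d = DosageMatrix(np.array([[float(dosage)]]), 4, ["s"])
        out = pseudodiploid_recode(d)
        assert out.values[0, 0] == expected
        assert out.ploidy == 2

    def test_rejects_diploid_input(self):
        d = DosageMatrix(np.array([[1.0]]), 2, ["s"])
        with pytest.raises(ValueError, match="ploidy 4"):
            pseudodiploid_recode(d)

    def test_double_recode_raises(self, toy_panel):
        once = pseudodiploid_recode(toy_panel)
        with pytest.raises(ValueError):
            pseudodiploid_recode(once)

    def test_missing_preserved(self):
        d = DosageMatrix(np.array([[np.nan], [3.0]]), 4, ["a", "b"])
        out = pseudodiploid_recode(d)
        assert np.isnan(out.values[0, 0])
        assert out.values[1, 0] == 1


class TestIndicatorExpand:
    def test_one_hot_for_dosage_2(self):
        d = DosageMatrix(np.array([[2.0], [0.0]]), 4, ["a", "b"])
        ind, freq = indicator_expand(d)
        np.testing.assert_array_equal(ind[0], [0, 0, 1, 0, 0])
        np.testing.assert_array_equal(ind[1], [1, 0, 0, 0, 0])

    def test_column_sums_are_class_frequencies(self):
        d = random_panel(30, 5, seed=2)
        ind, freq = indicator_expand(d)
        np.testing.assert_allclose(ind.mean(axis=0), freq)
        # exactly one class per individual per marker
        np.testing.assert_array_equal(
            ind.reshape(30, 5, 5).sum(axis=2), np.ones((30, 5))
        )

    def test_matches_hand_enumeration(self):
        dos = np.array([[0, 3], [4, 3], [2, 1], [1, 0]], dtype=float)
        d = DosageMatrix(dos, 4, list("wxyz"))
        ind, freq = indicator_expand(d)
        expected = np.zeros((4, 10))
        for i in range(4):
            for j in range(2):
                expected[i, 5 * j + int(dos[i, j])] = 1
        np.testing.assert_array_equal(ind, expected)
        assert ind.shape[1] == 5 * d.n_markers

    def test_requires_imputed(self):
        d = DosageMatrix(np.array([[np.nan], [1.0]]), 4, ["a", "b"])
        with pytest.raises(ValueError, match="missing"):
            indicator_expand(d)


class TestAlign:
    def test_intersection_in_genotype_order(self):
        d = random_panel(4, 3, seed=1)
        y = PhenotypeVector([9.0, 7.0, 8.0], ["S2", "S0", "S3"])
        d2, y2 = align(d, y)
        assert d2.sample_ids == ["S0", "S2", "S3"]
        np.testing.assert_allclose(y2.values, [7.0, 9.0, 8.0])

    def test_empty_intersection_raises(self):
        d = random_panel(3, 2, seed=1)
        y = PhenotypeVector([1.0], ["nope"])
        with pytest.raises(ValueError, match="no samples shared"):
            align(d, y)
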