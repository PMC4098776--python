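import numpy as np
import pandas as pd
import pytest

from exoqc import (
    CohortDataset,
    GenotypeCall,
    assign_batches,
    read_array_genotypes,
    read_site_set,
    read_vcf,
    write_vcf,
)
from exoqc.errors import TableParseError, ValidationError, VcfParseError
from exoqc.model import HET, HOM_ALT, HOM_REF, MISSING
from tests.conftest import VCF_HEADER, write_lines


class TestGenotypeCall:
    def test_missing_is_a_unit(self):
        call = GenotypeCall("S", MISSING)
        assert call.alleles == ("MISSING", "MISSING")
        assert call.alt_allele_count is None

    @pytest.mark.parametrize("code,alleles", [
        (HOM_REF, ("REF", "REF")), (HET, ("REF", "ALT")), (HOM_ALT, ("ALT", "ALT")),
    ])
    def test_allele_pairs(self, code, alleles):
        assert GenotypeCall("S", code, dp=3, gq=10).alleles == alleles

    def test_negative_quality_rejected(self):
        with pytest.raises(ValidationError):
            GenotypeCall("S", HET, dp=-1)
        with pytest.raises(ValidationError):
            GenotypeCall("S", HET, gq=-2)


class TestReadVcf:
    def test_selects_biallelic_snvs_and_maps_filter(self, fixture_vcf):
        dataset = read_vcf(str(fixture_vcf), split_multiallelic=True)
        assert dataset.samples == ["S1", "S2", "S3"]
        # indel skipped; triallelic split into two sites sharing chrom/pos/ref
        assert dataset.keys() == [
            ("1", 100, "A", "G"), ("1", 200, "C", "T"),
            ("1", 400, "G", "A"), ("1", 400, "G", "T"),
        ]
        # PASS and '.' both count as a passing VQSR verdict; tranche fails
        assert dataset.vqsr_pass.tolist() == [True, True, False, False]
        # genotype codes, incl. half-missing coerced to MISSING
        assert dataset.gt[0].tolist() == [HET, HOM_ALT, MISSING]
        assert dataset.gt[1].tolist() == [MISSING, HOM_REF, HET]
        # split sites: 1/2 is HET for each ALT; 0/2 is HET only for ALT=T
        assert dataset.gt[2].tolist() == [HET, HOM_REF, HOM_REF]
        assert dataset.gt[3].tolist() == [HET, HET, HOM_REF]
        # absent DP/GQ become -1; missing genotypes carry no DP/GQ
        assert dataset.dp[0].tolist() == [10, -1, -1]
        assert dataset.gq[0].tolist() == [30, 20, -1]

    def test_multiallelic_skipped_without_split(self, fixture_vcf):
        dataset = read_vcf(str(fixture_vcf), split_multiallelic=False)
        assert dataset.keys() == [("1", 100, "A", "G"), ("1", 200, "C", "T")]

    def test_non_diploid_genotype_is_an_error(self, tmp_path):
        path = tmp_path / "hap.vcf"
        write_lines(path, VCF_HEADER + [
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1",
            "1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t1",
        ])
        with pytest.raises(VcfParseError, match="ploidy"):
            read_vcf(str(path))


class TestRoundTrip:
    def test_fixture_round_trip(self, fixture_vcf, tmp_path):
        dataset = read_vcf(str(fixture_vcf))
        out = tmp_path / "out.vcf"
        write_vcf(dataset, str(out))
        assert read_vcf(str(out)).equal_genotypes(dataset)

    def test_simulated_round_trip(self, sim_small, tmp_path):
        dataset, _ = sim_small
        sub = dataset.subset_variants(np.arange(300))
        out = tmp_path / "sim.vcf"
        write_vcf(sub, str(out))
        assert read_vcf(str(out)).equal_genotypes(sub)

    def test_empty_dataset_round_trip(self, tiny_dataset, tmp_path):
        empty = tiny_dataset.subset_variants(np.zeros(3, dtype=bool))
        out = tmp_path / "empty.vcf"
        write_vcf(empty, str(out))
        back = read_vcf(str(out))
        assert back.n_variants == 0 and back.samples == empty.samples

    def test_gzip_output_and_input(self, tiny_dataset, tmp_path):
        out = tmp_path / "x.vcf.gz"
        write_vcf(tiny_dataset, str(out))
        assert read_vcf(str(out)).equal_genotypes(tiny_dataset)


def _array_tsv(tmp_path, rows):
    path = tmp_path / "array.tsv"
    header = "sample\tchrom\tpos\tref\talt\tgenotype\tgencall_score"
    write_lines(path, [header] + rows)
    return str(path)


class TestReadArrayGenotypes:
    def test_gencall_threshold(self, tmp_path):
        rows = [
            f"S1\t1\t{100 + i}\tA\tG\tHET\t{score}"
            for i, score in enumerate([0.9, 0.5, 0.31, 0.29, 0.1])
        ]
        assert len(read_array_genotypes(_array_tsv(tmp_path, rows), 0.3)) == 3
        assert len(read_array_genotypes(_array_tsv(tmp_path, rows), 0.0)) == 5

    def test_duplicate_key_is_an_error(self, tmp_path):
        rows = ["S1\t1\t100\tA\tG\tHET\t0.9", "S1\t1\t100\tA\tG\tHOM_ALT\t0.8"]
        with pytest.raises(TableParseError, match="duplicate"):
            read_array_genotypes(_array_tsv(tmp_path, rows))

    def test_unknown_genotype_token(self, tmp_path):
        with pytest.raises(TableParseError, match="genotype"):
            read_array_genotypes(_array_tsv(tmp_path, ["S1\t1\t100\tA\tG\tA/G\t0.9"]))


class TestReadSiteSet:
    def test_duplicates_collapse(self, tmp_path):
        path = tmp_path / "sites.tsv"
        write_lines(path, ["chrom\tpos\tref\talt", "1\t5\tA\tG", "1\t5\tA\tG",
                           "1\t7\tC\tT", "2\t5\tA\tC"])
        assert len(read_site_set(str(path))) == 3

    def test_empty_file(self, tmp_path):
        path = tmp_path / "sites.tsv"
        write_lines(path, ["chrom\tpos\tref\talt"])
        assert len(read_site_set(str(path))) == 0

    def test_zero_position_rejected(self, tmp_path):
        path = tmp_path / "sites.tsv"
        write_lines(path, ["chrom\tpos\tref\talt", "1\t0\tA\tG"])
        with pytest.raises(TableParseError, match="1-based"):
            read_site_set(str(path))


class TestAssignBatches:
    def test_columns_partition_the_cohort(self, tiny_dataset):
        table = {"A": "x", "B": "x", "C": "y", "D": "y"}
        batches = assign_batches(tiny_dataset, table)
        assert [b.samples for b in batches] == [["A", "B"], ["C", "D"]]
        assert all(b.keys() == tiny_dataset.keys() for b in batches)
        # multiset union of per-batch genotype columns equals the original matrix
        rebuilt = np.concatenate([b.gt for b in batches], axis=1)
        assert np.array_equal(np.sort(rebuilt, axis=1), np.sort(tiny_dataset.gt, axis=1))

    def test_single_batch_is_identity(self, tiny_dataset):
        (batch,) = assign_batches(tiny_dataset, {s: "only" for s in tiny_dataset.samples})
        assert batch.equal_genotypes(tiny_dataset)

    def test_unknown_sample_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError, match="unknown"):
            assign_batches(tiny_dataset, {"A": "x", "B": "x", "C": "y", "D": "y", "Z": "y"})

    def test_unassigned_sample_rejected(self, tiny_dataset):
        with pytest.raises(ValidationError, match="missing"):
            assign_batches(tiny_dataset, {"A": "x", "B": "x", "C": "y"})


class TestDatasetInvariants:
    def test_duplicate_variant_keys_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            CohortDataset.from_variant_records(
                ["A"],
                [{"chrom": "1", "pos": 1, "ref": "A", "alt": "G", "gt": [0]},
                 {"chrom": "1", "pos": 1, "ref": "A", "alt": "G", "gt": [1]}],
            )

    def test_non_snv_alleles_rejected(self):
        with pytest.raises(ValidationError):
            CohortDataset.from_variant_records(
                ["A"], [{"chrom": "1", "pos": 1, "ref": "AT", "alt": "G", "gt": [0]}])
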