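"""Genotype parsing, additive coding, imputation and allele frequencies."""

import numpy as np
import pytest

import binlmm as bl
from binlmm.geno_io import MISSING, AllMissingMarkerError

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestReadVcf:
    def test_alt_minor_site_codes_alt_dosage(self, tmp_path):
        vcf = VCF_HEADER + "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        G = bl.read_genotypes(_write(tmp_path / "a.vcf", vcf), "vcf")
        # ALT carries 3/6 alleles: exact tie, counted allele = min(A, G) = A (REF)
        assert list(G.calls[:, 0]) == [2, 1, 0]
        assert G.samples == ["S1", "S2", "S3"]
        assert G.chrom[0] == "1" and G.pos[0] == 100

    def test_minor_allele_counted(self, tmp_path):
        vcf = VCF_HEADER + "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/0\t0/1\n"
        G = bl.read_genotypes(_write(tmp_path / "b.vcf", vcf), "vcf")
        assert list(G.calls[:, 0]) == [0, 0, 1]  # ALT minor: dosage as-is

    def test_missing_call_is_sentinel(self, tmp_path):
        vcf = VCF_HEADER + "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t./.\t0/1\t1/1\n"
        G = bl.read_genotypes(_write(tmp_path / "c.vcf", vcf), "vcf")
        col = G.calls[:, 0]
        assert col[0] == MISSING
        assert set(col[1:]) <= {0, 1, 2}

    def test_multiallelic_skipped(self, tmp_path):
        vcf = VCF_HEADER + (
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n")
        G = bl.read_genotypes(_write(tmp_path / "d.vcf", vcf), "vcf")
        assert G.markers == ["rs2"]

    def test_all_multiallelic_raises(self, tmp_path):
        vcf = VCF_HEADER + "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
        with pytest.raises(bl.geno_io.EmptyInputError):
            bl.read_genotypes(_write(tmp_path / "e.vcf", vcf), "vcf")


class TestHapmap:
    def test_iupac_coding(self, tmp_path):
        meta = "\t".join(["alleles", "chrom", "pos", "strand", "assembly", "center",
                          "protLSID", "assayLSID", "panelLSID", "QCcode"])
        text = (f"rs#\t{meta}\tS1\tS2\tS3\tS4\n"
                "m1\tA/G\t1\t50\t+\t.\t.\t.\t.\t.\t.\tA\tR\tG\tN\n")
        G = bl.read_genotypes(_write(tmp_path / "h.hmp.txt", text), "hapmap")
        col = G.calls[:, 0]
        # allele counts tie at 3/6, so the lexicographically smaller allele A
        # is counted: A hom -> 2, het (R = A/G) -> 1, G hom -> 0, N missing
        assert list(col) == [2, 1, 0, MISSING]


class TestMatrixRoundTrip:
    def test_round_trip_identity(self, tmp_path, rng):
        calls = rng.integers(0, 3, size=(5, 8)).astype(np.int8)
        calls[0, 0] = MISSING
        G = bl.GenotypeMatrix([f"s{i}" for i in range(5)],
                              [f"m{j}" for j in range(8)],
                              ["1"] * 8, np.arange(1, 9), calls)
        path = tmp_path / "g.tsv"
        bl.write_matrix(G, str(path))
        G2 = bl.read_genotypes(str(path), "matrix")
        assert np.array_equal(G.calls, G2.calls)
        assert G2.samples == G.samples and G2.markers == G.markers
        assert np.array_equal(G2.pos, G.pos)


class TestImpute:
    @pytest.mark.parametrize("col,expected", [
        ([0, 0, 2, MISSING], [0, 0, 2, 0]),    # major allele is code 0
        ([0, 1, 2, 1], [0, 1, 2, 1]),          # nothing missing: unchanged
        ([0, 2, MISSING, MISSING], [0, 2, 0, 0]),  # exact tie -> code 0
        ([2, 2, 0, MISSING], [2, 2, 0, 2]),    # major allele is code 2
    ])
    def test_major_allele_fill(self, col, expected):
        G = bl.GenotypeMatrix([f"s{i}" for i in range(len(col))], ["m"], ["1"], [1],
                              np.array(col, dtype=np.int8)[:, None])
        out = bl.impute_major_allele(G)
        assert list(out.calls[:, 0]) == expected

    def test_idempotent(self, rng):
        calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
        calls[rng.random((10, 6)) < 0.2] = MISSING
        calls[:, 0] = [0, 1, 2, 0, 1, 2, 0, 1, 2, 0]  # keep one marker callable
        G = bl.GenotypeMatrix([f"s{i}" for i in range(10)],
                              [f"m{j}" for j in range(6)],
                              ["1"] * 6, np.arange(6) + 1, calls)
        try:
            once = bl.impute_major_allele(G)
        except AllMissingMarkerError:
            pytest.skip("draw left a marker fully missing")
        twice = bl.impute_major_allele(once)
        assert np.array_equal(once.calls, twice.calls)
        assert not once.has_missing()

    def test_all_missing_marker_raises(self):
        G = bl.GenotypeMatrix(["a", "b"], ["mBad"], ["1"], [1],
                              np.array([[MISSING], [MISSING]], dtype=np.int8))
        with pytest.raises(AllMissingMarkerError, match="mBad"):
            bl.impute_major_allele(G)


class TestAlleleFrequency:
    @pytest.mark.parametrize("col,freq,maf", [
        ([0, 1, 2], 0.5, 0.5),
        ([0, 0, 0], 0.0, 0.0),
        ([2, 2, 2, 0], 0.75, 0.25),
    ])
    def test_hand_computed(self, col, freq, maf):
        G = bl.GenotypeMatrix([f"s{i}" for i in range(len(col))], ["m"], ["1"], [1],
                              np.array(col, dtype=np.int8)[:, None])
        t = bl.allele_frequency(G)
        assert t.freq[0] == pytest.approx(freq)
        assert t.maf[0] == pytest.approx(maf)

    def test_missing_excluded_from_denominator(self):
        G = bl.GenotypeMatrix(["a", "b", "c"], ["m"], ["1"], [1],
                              np.array([[2], [0], [MISSING]], dtype=np.int8))
        assert bl.allele_frequency(G).freq[0] == pytest.approx(0.5)

    def test_full_panel_frequency_is_weighted_subpop_average(self, rng):
        calls = rng.integers(0, 3, size=(30, 20)).astype(np.int8)
        G = bl.GenotypeMatrix([f"s{i}" for i in range(30)],
                              [f"m{j}" for j in range(20)],
                              ["1"] * 20, np.arange(20) + 1, calls)
        a = np.arange(12)
        b = np.arange(12, 30)
        fa = bl.allele_frequency(G, a).freq
        fb = bl.allele_frequency(G, b).freq
        full = bl.allele_frequency(G).freq
        np.testing.assert_allclose(full, (12 * fa + 18 * fb) / 30, atol=1e-12)

    def test_empty_subset_raises(self):
        G = bl.GenotypeMatrix(["a"], ["m"], ["1"], [1],
                              np.array([[1]], dtype=np.int8))
        with pytest.raises(ValueError):
            bl.allele_frequency(G, np.array([], dtype=int))
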