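import numpy as np
import pandas as pd
import pytest

import admixkit as ak
from admixkit.genotype_io import MISSING, GenotypeError

from conftest import make_matrix

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return path


class TestReadVcf:
    def test_gt_encoding(self, tmp_path):
        """0/0, 0/1 and ./. become counts 0, 1 and MISSING."""
        p = write_vcf(
            tmp_path / "a.vcf",
            "1\t100\t.\tA\tC\t.\t.\t.\tGT\t0/0\t0/1\t./.\n",
        )
        g = ak.read_genotypes(p, "vcf")
        assert list(g.derived[:, 0]) == [0, 1, MISSING]
        assert list(g.ploidy[:, 0]) == [2, 2, 0]

    def test_biallelic_snv_rule(self, tmp_path):
        """Indels and multiallelic records are dropped; SNVs survive."""
        body = (
            "1\t100\t.\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\t.\tA\tATG\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n"
            "1\t300\t.\tG\tA,C\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n"
        )
        g = ak.read_genotypes(write_vcf(tmp_path / "b.vcf", body), "vcf")
        assert g.n_variants == 1
        assert g.variants.loc[0, "pos"] == 100

    def test_haploid_calls(self, tmp_path):
        body = "1\t100\t.\tA\tC\t.\t.\t.\tGT\t1\t0\t.\n"
        g = ak.read_genotypes(write_vcf(tmp_path / "c.vcf", body), "vcf")
        assert list(g.ploidy[:, 0]) == [1, 1, 0]
        assert list(g.derived[:, 0]) == [1, 0, MISSING]

    def test_duplicate_position_rejected(self, tmp_path):
        body = (
            "1\t100\t.\tA\tC\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n"
            "1\t100\t.\tG\tT\t.\t.\t.\tGT\t0/0\t0/0\t0/0\n"
        )
        with pytest.raises(GenotypeError, match="duplicate"):
            ak.read_genotypes(write_vcf(tmp_path / "d.vcf", body), "vcf")


class TestEigenstrat:
    def test_geno_9_is_missing(self, tmp_path):
        (tmp_path / "e.geno").write_text("092\n")
        (tmp_path / "e.snp").write_text("v1 1 0.0 100 A C\n")
        (tmp_path / "e.ind").write_text("S1 U P1\nS2 U P1\nS3 U P2\n")
        g = ak.read_genotypes(tmp_path / "e", "eigenstrat")
        # digit counts reference alleles: 0 -> 2 derived, 2 -> 0 derived
        assert list(g.derived[:, 0]) == [2, MISSING, 0]
        assert list(g.ploidy[:, 0]) == [2, 0, 2]

    def test_round_trip_preserves_cells(self, tmp_path):
        rng = np.random.default_rng(0)
        n_s, n_v = 6, 40
        ploidy = np.full((n_s, n_v), 2, dtype=np.int8)
        ploidy[4:] = 1  # two pseudo-haploid samples
        ploidy[rng.random((n_s, n_v)) < 0.1] = 0
        derived = rng.integers(0, 3, (n_s, n_v)).astype(np.int16)
        derived = np.minimum(derived, ploidy)
        derived[ploidy == 0] = MISSING
        g = make_matrix(derived, ploidy)
        haploid = [g.samples[4], g.samples[5]]
        ak.write_eigenstrat(g, tmp_path / "rt")
        g2 = ak.read_genotypes(tmp_path / "rt", "eigenstrat", haploid_samples=haploid)
        assert g2.samples == g.samples
        np.testing.assert_array_equal(g2.derived, g.derived)
        np.testing.assert_array_equal(g2.ploidy, g.ploidy)
        # second round trip is byte-stable
        ak.write_eigenstrat(g2, tmp_path / "rt2")
        assert (tmp_path / "rt.geno").read_text() == (tmp_path / "rt2.geno").read_text()


class TestPanel:
    def test_basic_read(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "sample\tpopulation\tregion\tage_class\tlatitude\tlongitude\n"
            "S1\tMbuti\tOutgroup\tcontemporary\tNA\tNA\n"
            "S2\tMixe\tCentralAmerica\tcontemporary\t17.0\t-96.0\n"
        )
        panel = ak.read_panel(p)
        assert panel.population_of("S1") == "Mbuti"
        assert panel.coordinates_of_population("Mixe") == (17.0, -96.0)

    def test_unknown_region_rejected(self, tmp_path):
        p = tmp_path / "panel.tsv"
        p.write_text(
            "sample\tpopulation\tregion\tage_class\tlatitude\tlongitude\n"
            "S1\tFoo\tAmazonia\tcontemporary\tNA\tNA\n"
        )
        with pytest.raises(GenotypeError, match="region"):
            ak.read_panel(p)

    def test_population_count(self, tmp_path):
        rows = [
            f"S{i}\tP{i % 8}\tAmazon\tcontemporary\tNA\tNA" for i in range(58)
        ]
        p = tmp_path / "panel.tsv"
        p.write_text(
            "sample\tpopulation\tregion\tage_class\tlatitude\tlongitude\n"
            + "\n".join(rows) + "\n"
        )
        assert len(ak.read_panel(p).populations()) == 8


class TestIntersect:
    def _random_matrix(self, seed, n_v, samples, start=1):
        rng = np.random.default_rng(seed)
        derived = rng.integers(0, 3, (len(samples), n_v)).astype(np.int16)
        ploidy = np.full_like(derived, 2, dtype=np.int8)
        g = make_matrix(derived, ploidy, samples=samples)
        g.variants["pos"] = np.arange(start, start + n_v)
        return ak.GenotypeMatrix(g.variants, g.samples, g.derived, g.ploidy)

    def test_identity_doubles_samples(self):
        a = self._random_matrix(1, 30, ["A1", "A2"])
        b = self._random_matrix(1, 30, ["B1", "B2"])
        out = ak.intersect_datasets(a, b)
        assert out.n_variants == 30
        assert out.samples == ["A1", "A2", "B1", "B2"]

    def test_swap_recode(self):
        a = make_matrix([[1], [2]], [[2], [2]], samples=["A1", "A2"])
        b = make_matrix([[0], [1]], [[2], [2]], samples=["B1", "B2"])
        b.variants.loc[0, ["ref", "alt"]] = ["C", "A"]  # swapped vs a
        out = ak.intersect_datasets(a, b)
        assert out.n_variants == 1
        # b counts recoded as ploidy - derived
        assert list(out.derived[:, 0]) == [1, 2, 2, 1]

    def test_incompatible_sites_dropped(self):
        a = self._random_matrix(2, 100, ["A1"])
        b = self._random_matrix(3, 150, ["B1"])
        # b shares a's 100 positions (plus 50 more); corrupt 10 allele pairs
        b.variants.loc[:9, ["ref", "alt"]] = ["G", "T"]
        out = ak.intersect_datasets(a, b)
        # brute-force expectation
        akeys = {(r.chrom, r.pos, r.ref, r.alt) for r in a.variants.itertuples()}
        bkeys = {(r.chrom, r.pos, r.ref, r.alt) for r in b.variants.itertuples()}
        bswap = {(c, p, al, r) for c, p, r, al in bkeys}
        expected = len(akeys & (bkeys | bswap))
        assert expected == 90
        assert out.n_variants == expected

    def test_site_content_symmetric(self):
        a = self._random_matrix(4, 80, ["A1", "A2"])
        b = self._random_matrix(5, 120, ["B1"], start=41)
        ab = ak.intersect_datasets(a, b)
        ba = ak.intersect_datasets(b, a)
        key = lambda g: list(zip(g.variants["chrom"], g.variants["pos"]))
        assert key(ab) == key(ba)

    def test_overlapping_samples_rejected(self):
        a = self._random_matrix(6, 10, ["S1"])
        b = self._random_matrix(7, 10, ["S1"])
        with pytest.raises(GenotypeError, match="overlap"):
            ak.intersect_datasets(a, b)

    def test_swap_flips_downstream_frequency(self):
        """After recoding, frequencies at a swapped site satisfy p' = 1-p."""
        b = make_matrix([[1], [2], [2]], [[2], [2], [2]], samples=["B1", "B2", "B3"])
        a = make_matrix([[0]], [[2]], samples=["A1"])
        a.variants.loc[0, ["ref", "alt"]] = ["C", "A"]
        panel = ak.PopulationPanel(
            pd.DataFrame(
                {
                    "population": ["PA", "PB", "PB", "PB"],
                    "region": "Other",
                    "age_class": "contemporary",
                },
                index=["A1", "B1", "B2", "B3"],
            )
        )
        merged = ak.intersect_datasets(a, b)
        freq = ak.population_counts(merged, panel)
        p_orig = (1 + 2 + 2) / 6
        assert freq.freq("PB")[0] == pytest.approx(1 - p_orig)


class TestWriteTable:
    def test_fstat_rows_and_round_trip(self, tmp_path):
        r = ak.FStatResult(
            "D", ("W", "X", "Y", "Z"), -0.1234567, -0.12, 0.0123456, -9.87654,
            50, 4999,
        )
        path = tmp_path / "out.tsv"
        ak.write_table([r], path)
        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == [
            "stat", "W", "X", "Y", "Z", "estimate", "se", "z", "n_blocks", "n_sites",
        ]
        # 6 significant digits survive the round trip
        assert back.loc[0, "estimate"] == pytest.approx(-0.123457, abs=1e-9)
        assert back.loc[0, "se"] == pytest.approx(0.0123456, rel=1e-5)

    def test_empty_frame_gives_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        ak.write_table(pd.DataFrame(columns=["a", "b"]), path)
        assert path.read_text() == "a\tb\n"
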