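"""Summary-statistics and genotype IO, harmonization, standardization."""

import numpy as np
import pandas as pd
import pytest

from smoothsum import (
    GenotypePanel,
    HarmonizationError,
    SchemaError,
    ShapeError,
    SummaryStatsTable,
    beta_to_correlation,
    harmonize,
    read_genotypes,
    read_summary_stats,
    standardize,
    apply_standardization,
    write_genotypes,
    write_summary_stats,
)


def stats_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue"],
    )


@pytest.fixture
def small_panel():
    variants = pd.DataFrame(
        {
            "chrom": ["1", "1", "2"],
            "pos": [100, 200, 300],
            "a1": ["A", "G", "C"],
            "a2": ["G", "T", "T"],
        }
    )
    dosages = np.array(
        [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]], dtype=float
    )
    return GenotypePanel(dosages=dosages, sample_ids=["s1", "s2", "s3", "s4"],
                         variants=variants)


class TestSummaryStats:
    def test_clean_read(self, tmp_path):
        df = stats_frame(
            [["1", 100, "A", "G", 0.3, 0.1, 0.01],
             ["1", 200, "G", "T", -0.2, 0.05, 0.5],
             ["2", 300, "C", "T", 0.0, 0.2, 1.0]]
        )
        path = tmp_path / "stats.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_summary_stats(path)
        assert len(table) == 3
        assert list(table.frame["pos"]) == [100, 200, 300]

    def test_column_map(self, tmp_path):
        df = stats_frame([["1", 100, "A", "G", 0.3, 0.1, 0.01]])
        df.columns = ["CHR", "BP", "A1", "A2", "Beta", "SE", "P"]
        path = tmp_path / "stats.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_summary_stats(
            path,
            column_map={"chrom": "CHR", "pos": "BP", "effect_allele": "A1",
                        "other_allele": "A2", "beta": "Beta", "se": "SE",
                        "pvalue": "P"},
        )
        assert len(table) == 1
        assert table.frame.loc[0, "beta"] == 0.3

    def test_invalid_rows_dropped_with_count(self, tmp_path):
        df = stats_frame(
            [["1", 100, "A", "G", 0.3, 0.1, 0.01],
             ["1", 200, "G", "T", -0.2, 0.0, 0.5],   # se = 0
             ["1", 300, "C", "T", 0.1, 0.1, 1.5]]    # p > 1
        )
        path = tmp_path / "stats.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="dropped 2"):
            table = read_summary_stats(path)
        assert len(table) == 1

    def test_missing_column_names_found_columns(self, tmp_path):
        df = stats_frame([["1", 100, "A", "G", 0.3, 0.1, 0.01]]).drop(columns=["se"])
        path = tmp_path / "stats.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(SchemaError, match="se"):
            read_summary_stats(path)

    def test_round_trip_identity(self, tmp_path):
        df = stats_frame(
            [["1", 100, "A", "G", 0.312345678901234, 0.1, 0.01],
             ["2", 300, "C", "T", -1e-8, 0.05, 0.999]]
        )
        table = SummaryStatsTable(frame=df)
        path = tmp_path / "rt.tsv"
        write_summary_stats(table, path)
        back = read_summary_stats(path)
        pd.testing.assert_frame_equal(
            back.frame[df.columns], df, check_dtype=False
        )


class TestGenotypeIO:
    def test_bed_fixture_byte_level(self, tmp_path):
        """A 4-sample x 3-variant bed file written byte-by-byte from the spec
        of the two-bit SNP-major encoding round-trips to the exact dosages."""
        # codes: 00 -> 2 copies of a1, 10 -> 1, 11 -> 0, 01 -> missing
        # variant 1 dosages (s1..s4): 2, 1, 0, 2 -> codes 00,10,11,00
        # packed low-to-high: 00 | 10<<2 | 11<<4 | 00<<6 = 0b00111000
        # variant 2: 0, 0, 1, 2 -> 11,11,10,00 -> 0b00101111
        # variant 3: 1, missing, 2, 0 -> 10,01,00,11 -> 0b11000110
        body = bytes([0b00111000, 0b00101111, 0b11000110])
        (tmp_path / "toy.bed").write_bytes(bytes([0x6C, 0x1B, 0x01]) + body)
        (tmp_path / "toy.fam").write_text(
            "".join(f"f{i} s{i} 0 0 0 -9\n" for i in range(1, 5))
        )
        (tmp_path / "toy.bim").write_text(
            "1\tv1\t0\t100\tA\tG\n1\tv2\t0\t200\tG\tT\n2\tv3\t0\t300\tC\tT\n"
        )
        with pytest.warns(UserWarning, match="mean-imputed 1"):
            panel = read_genotypes(tmp_path / "toy.bed")
        expected = np.array(
            [[2, 0, 1], [1, 0, 1], [0, 1, 2], [2, 2, 0]], dtype=float
        )
        expected[1, 2] = (1 + 2 + 0) / 3  # missing imputed to column mean
        np.testing.assert_allclose(panel.dosages, expected)
        assert panel.sample_ids == ["s1", "s2", "s3", "s4"]

    def test_bed_tsv_cross_format_equivalence(self, tmp_path, small_panel):
        write_genotypes(small_panel, tmp_path / "x.bed", fmt="bed")
        write_genotypes(small_panel, tmp_path / "x.tsv", fmt="tsv")
        from_bed = read_genotypes(tmp_path / "x.bed")
        from_tsv = read_genotypes(tmp_path / "x.tsv")
        np.testing.assert_allclose(from_bed.dosages, from_tsv.dosages)
        assert from_bed.sample_ids == from_tsv.sample_ids
        np.testing.assert_allclose(from_bed.dosages, small_panel.dosages)
        assert list(from_bed.variants["pos"]) == list(small_panel.variants["pos"])

    def test_bad_magic_rejected(self, tmp_path):
        (tmp_path / "bad.bed").write_bytes(b"\x00\x00\x01\x00")
        (tmp_path / "bad.fam").write_text("f1 s1 0 0 0 -9\n")
        (tmp_path / "bad.bim").write_text("1\tv1\t0\t100\tA\tG\n")
        with pytest.raises(SchemaError, match="magic"):
            read_genotypes(tmp_path / "bad.bed")

    def test_inconsistent_row_counts_rejected(self, tmp_path, small_panel):
        write_genotypes(small_panel, tmp_path / "x.bed", fmt="bed")
        bim = (tmp_path / "x.bim").read_text().splitlines()
        (tmp_path / "x.bim").write_text("\n".join(bim[:-1]) + "\n")
        with pytest.raises(SchemaError, match="inconsistent"):
            read_genotypes(tmp_path / "x.bed")


class TestHarmonize:
    def make_stats(self, rows):
        return SummaryStatsTable(frame=stats_frame(rows))

    def test_identical_coding_unchanged(self, small_panel):
        stats = self.make_stats(
            [["1", 100, "A", "G", 0.3, 0.1, 0.01],
             ["1", 200, "G", "T", -0.2, 0.1, 0.5]]
        )
        res = harmonize(stats, small_panel)
        np.testing.assert_allclose(res.beta, [0.3, -0.2])
        np.testing.assert_array_equal(res.kept_index, [0, 1])
        assert res.n_flipped == 0

    def test_swapped_alleles_flip_sign(self, small_panel):
        stats = self.make_stats([["1", 100, "G", "A", 0.3, 0.1, 0.01]])
        res = harmonize(stats, small_panel)
        np.testing.assert_allclose(res.beta, [-0.3])
        assert res.n_flipped == 1

    def test_ambiguous_and_mismatched_dropped(self, small_panel):
        panel = small_panel
        panel.variants.loc[2, ["a1", "a2"]] = ["A", "T"]  # ambiguous pair
        stats = self.make_stats(
            [["1", 100, "A", "G", 0.3, 0.1, 0.01],
             ["2", 300, "A", "T", 0.5, 0.1, 0.01],   # ambiguous
             ["1", 200, "C", "A", 0.2, 0.1, 0.01]]   # allele-set mismatch
        )
        with pytest.warns(UserWarning, match="1 strand-ambiguous and 1"):
            res = harmonize(stats, panel)
        np.testing.assert_array_equal(res.kept_index, [0])

    def test_empty_intersection_raises(self, small_panel):
        stats = self.make_stats([["9", 999, "A", "G", 0.3, 0.1, 0.01]])
        with pytest.raises(HarmonizationError):
            harmonize(stats, small_panel)

    def test_idempotent(self, small_panel):
        stats = self.make_stats(
            [["1", 100, "G", "A", 0.3, 0.1, 0.01],
             ["1", 200, "G", "T", -0.2, 0.1, 0.5]]
        )
        once = harmonize(stats, small_panel)
        again = harmonize(SummaryStatsTable(frame=once.table), small_panel)
        np.testing.assert_allclose(once.beta, again.beta)
        np.testing.assert_array_equal(once.kept_index, again.kept_index)
        assert again.n_flipped == 0


class TestStandardize:
    def test_hand_computed_column(self):
        std = standardize(np.array([[0.0], [1.0], [2.0], [1.0]]))
        np.testing.assert_allclose(std.x[:, 0], np.array([-1, 0, 1, 0]) / np.sqrt(2))
        assert np.linalg.norm(std.x[:, 0]) == pytest.approx(1.0, abs=1e-14)
        assert std.center[0] == 1.0
        assert std.scale[0] == pytest.approx(np.sqrt(2))

    def test_idempotent_and_zero_mean(self, rng):
        X = rng.standard_normal((30, 5))
        std = standardize(X)
        assert np.max(np.abs(std.x.mean(axis=0))) < 1e-12
        again = standardize(std.x)
        np.testing.assert_allclose(again.x, std.x, atol=1e-12)

    def test_constant_column_dropped(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 1] = 7.0
        with pytest.warns(UserWarning, match="zero-variance"):
            std = standardize(X)
        np.testing.assert_array_equal(std.kept, [0, 2])

    def test_all_constant_raises(self):
        with pytest.raises(ShapeError):
            standardize(np.ones((10, 2)))

    def test_apply_standardization_matches_training_transform(self, rng):
        X = rng.standard_normal((25, 4))
        std = standardize(X)
        np.testing.assert_allclose(apply_standardization(X, std), std.x, atol=1e-12)


class TestBetaToCorrelation:
    def test_zero_beta(self):
        assert beta_to_correlation(0.0, 0.1, 100) == 0.0

    def test_direct_formula(self):
        # t = 2, n = 6: r = 2 / sqrt(4 + 4) = 0.7071...
        assert beta_to_correlation(0.2, 0.1, 6) == pytest.approx(
            2 / np.sqrt(8), abs=1e-12
        )

    def test_bounded_and_odd(self, rng):
        for _ in range(200):
            b = float(rng.uniform(-100, 100))
            se = float(rng.uniform(1e-4, 10))
            n = int(rng.integers(3, 1000))
            r = beta_to_correlation(b, se, n)
            assert -1.0 < r < 1.0
            assert r == pytest.approx(-beta_to_correlation(-b, se, n), abs=1e-15)

    def test_recovers_empirical_pearson(self, rng):
        """The defining identity: converting a marginal-regression (beta, se)
        reproduces the Pearson correlation of variant and outcome."""
        from smoothsum import GenotypePanel, make_summary_stats

        n, p = 200, 12
        dos = rng.integers(0, 3, size=(n, p)).astype(float)
        variants = pd.DataFrame(
            {"chrom": "1", "pos": np.arange(1, p + 1) * 10,
             "a1": "A", "a2": "G"}
        )
        panel = GenotypePanel(dos, [f"s{i}" for i in range(n)], variants)
        y = rng.standard_normal(n)
        stats = make_summary_stats(panel, y)
        r_conv = beta_to_correlation(
            stats.frame["beta"], stats.frame["se"], stats.frame["n_gwas"]
        )
        r_emp = [float(np.corrcoef(dos[:, j], y)[0, 1]) for j in range(p)]
        np.testing.assert_allclose(r_conv, r_emp, atol=1e-6)
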