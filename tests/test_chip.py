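"""Pausing index and peak fold change against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from ms2burst.chip import (
    CoverageTrack,
    GeneRecord,
    pausing_cdf,
    pausing_index,
    peak_fold_change,
    read_bed6,
    read_chrom_sizes,
)


def brute_force_pausing(cov, gene):
    """Per-base-sum oracle, looping over every base explicitly."""
    v = cov[gene.chrom]
    n = v.size
    tss = gene.start if gene.strand == "+" else gene.end
    promoter = sum(v[i] for i in range(max(0, tss - 250), min(n, tss + 250)))
    body = sum(v[i] for i in range(max(0, gene.start + 500), min(n, gene.end - 500)))
    return promoter, body


class TestPausingIndex:
    def test_uniform_coverage_analytic_case(self):
        # 3000 bp gene, uniform depth d: promoter 500*d, body 2000*d -> 0.25
        cov = CoverageTrack({"chr1": np.full(10_000, 3.0)})
        gene = GeneRecord("chr1", 4000, 7000, "+", "g")
        df = pausing_index(cov, [gene])
        assert df["pausing_index"].iloc[0] == pytest.approx(0.25)

    def test_short_genes_removed(self):
        cov = CoverageTrack({"chr1": np.ones(5000)})
        genes = [
            GeneRecord("chr1", 100, 1500, "+", "short"),  # 1400 bp
            GeneRecord("chr1", 100, 1600, "+", "kept"),  # 1500 bp
        ]
        df = pausing_index(cov, genes)
        assert list(df["gene_id"]) == ["kept"]

    def test_minus_strand_upstream_spike_in_promoter(self):
        # spike 100 bp upstream of a minus-strand TSS (above `end`)
        v = np.ones(10_000)
        v[7100] = 500.0
        cov = CoverageTrack({"chr1": v})
        gene = GeneRecord("chr1", 4000, 7000, "-", "g")
        df = pausing_index(cov, [gene])
        promoter, body = brute_force_pausing(cov, gene)
        assert df["promoter_signal"].iloc[0] == pytest.approx(promoter)
        assert promoter > 600  # includes the spike

    def test_matches_brute_force_on_random_toy_genome(self):
        rng = np.random.default_rng(0)
        cov = CoverageTrack({"chrA": rng.gamma(2, 1, 50_000), "chrB": rng.gamma(2, 1, 30_000)})
        genes = []
        for k in range(30):
            chrom = "chrA" if k % 2 else "chrB"
            n = cov.chrom_length(chrom)
            start = int(rng.integers(0, n - 5000))
            length = int(rng.integers(1500, 5000))
            genes.append(
                GeneRecord(chrom, start, min(start + length, n), "+-"[k % 2], f"g{k}")
            )
        df = pausing_index(cov, genes).set_index("gene_id")
        for g in genes:
            if g.length < 1500:
                continue
            promoter, body = brute_force_pausing(cov, g)
            assert df.loc[g.gene_id, "promoter_signal"] == pytest.approx(promoter)
            assert df.loc[g.gene_id, "body_signal"] == pytest.approx(body)

    def test_strand_flip_invariance(self):
        # mirroring the genome and flipping strand preserves the index
        rng = np.random.default_rng(1)
        v = rng.gamma(2, 1, 20_000)
        gene = GeneRecord("c", 5000, 9000, "+", "g")
        mirrored = GeneRecord("c", v.size - 9000, v.size - 5000, "-", "g")
        df1 = pausing_index(CoverageTrack({"c": v}), [gene])
        df2 = pausing_index(CoverageTrack({"c": v[::-1].copy()}), [mirrored])
        assert df1["pausing_index"].iloc[0] == pytest.approx(df2["pausing_index"].iloc[0])

    def test_zero_body_reported_missing(self):
        v = np.zeros(10_000)
        v[4000:4100] = 5.0  # promoter-only signal
        df = pausing_index(CoverageTrack({"c": v}), [GeneRecord("c", 4000, 7000, "+", "g")])
        assert np.isnan(df["pausing_index"].iloc[0])

    def test_gene_beyond_chromosome_rejected(self):
        cov = CoverageTrack({"c": np.ones(1000)})
        with pytest.raises(ValueError, match="g1"):
            pausing_index(cov, [GeneRecord("c", 0, 2000, "+", "g1")], min_gene_length=100)


class TestPausingCdf:
    def _records(self, values):
        return pd.DataFrame({"gene_id": range(len(values)), "pausing_index": values})

    def test_identical_sets(self):
        rng = np.random.default_rng(2)
        v = rng.lognormal(0, 1, 200)
        cdf, p = pausing_cdf(self._records(v), self._records(v.copy()))
        np.testing.assert_allclose(cdf["cdf_a"], cdf["cdf_b"])
        assert p == 1.0

    def test_scaled_set_shifts_cdf(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(0, 0.5, 500)
        cdf, _ = pausing_cdf(self._records(v), self._records(2 * v))
        # B stochastically larger: its CDF lies at or below A's everywhere
        assert np.all(cdf["cdf_b"] <= cdf["cdf_a"] + 1e-12)

    def test_paused_subset_detected(self):
        rng = np.random.default_rng(4)
        base = rng.lognormal(0, 0.5, 500)
        subset = base[:100] * 5  # "paused" promoters
        _, p = pausing_cdf(self._records(base), self._records(subset))
        assert p < 0.01


class TestPeakFoldChange:
    def _tracks(self, control_max, treatment_max, n=1000):
        ca = np.zeros(n)
        cb = np.zeros(n)
        peaks = []
        pos = 10
        for k, (a, b) in enumerate(zip(control_max, treatment_max)):
            ca[pos] = a
            cb[pos] = b
            peaks.append(GeneRecord("c", pos - 5, pos + 5, "+", f"p{k}"))
            pos += 50
        return CoverageTrack({"c": ca}), CoverageTrack({"c": cb}), peaks

    def test_printed_toy_cases(self):
        ca, cb, peaks = self._tracks([10.0, 4.9, 8.0], [10.0, 4.9, 6.0])
        df = peak_fold_change(ca, cb, peaks)
        assert list(df["class"]) == ["associated", "filtered", "diminished"]
        assert df["log2_fc"].iloc[0] == 0.0
        assert df["log2_fc"].iloc[2] == pytest.approx(np.log2(0.75))

    def test_classification_is_partition(self):
        rng = np.random.default_rng(5)
        a = rng.gamma(3, 4, 50)
        b = a * rng.uniform(0.5, 1.5, 50)
        ca, cb, peaks = self._tracks(a, b, n=3000)
        df = peak_fold_change(ca, cb, peaks)
        unfiltered = df[~df["filtered"]]
        assert set(unfiltered["class"]) <= {"diminished", "associated"}
        assert ((unfiltered["log2_fc"] < -0.1) == (unfiltered["class"] == "diminished")).all()

    def test_diminished_recall_as_noise_vanishes(self):
        # a fraction of peaks scaled 0.7 in treatment: all called diminished
        rng = np.random.default_rng(6)
        a = rng.uniform(6, 50, 40)
        scaled = np.zeros(40, dtype=bool)
        scaled[::4] = True
        b = np.where(scaled, 0.7 * a, a)
        ca, cb, peaks = self._tracks(a, b, n=3000)
        df = peak_fold_change(ca, cb, peaks)
        called = set(df.loc[df["class"] == "diminished", "peak_id"])
        expected = {f"p{k}" for k in np.flatnonzero(scaled)}
        assert called == expected

    def test_empty_peak_set(self):
        ca, cb, _ = self._tracks([], [])
        assert len(peak_fold_change(ca, cb, [])) == 0


class TestIo:
    def test_bed_and_sizes_round_trip(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t100\t2000\tgeneA\t0\t+\nchr1\t3000\t5000\tgeneB\t0\t-\n")
        genes = read_bed6(bed)
        assert genes[0].gene_id == "geneA" and genes[1].strand == "-"
        sizes = tmp_path / "sizes.tsv"
        sizes.write_text("chr1\t10000\n")
        assert read_chrom_sizes(sizes) == {"chr1": 10000}

    def test_bedgraph_round_trip_preserves_nonzero_intervals(self, tmp_path):
        rng = np.random.default_rng(7)
        v = np.zeros(500)
        v[50:80] = 2.5
        v[200:210] = 7.0
        track = CoverageTrack({"chr1": v})
        path = tmp_path / "cov.bedgraph"
        track.to_bedgraph(path)
        back = CoverageTrack.from_bedgraph(path, {"chr1": 500})
        np.testing.assert_allclose(back["chr1"], v)

    def test_bad_bedgraph_interval_rejected(self, tmp_path):
        path = tmp_path / "cov.bedgraph"
        path.write_text("chr1\t400\t600\t1.0\n")
        with pytest.raises(ValueError, match="chr1"):
            CoverageTrack.from_bedgraph(path, {"chr1": 500})

    def test_rpm_conversion(self):
        t = CoverageTrack({"c": np.array([2.0, 4.0])}).to_rpm(2_000_000)
        np.testing.assert_allclose(t["c"], [1.0, 2.0])
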