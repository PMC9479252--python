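"""Gene-table loading, symbol quality, peak merging/capping, TSS QC profile."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tfregulon import (cap_peaks, load_gene_table, load_peaks,
                       merge_close_peaks, symbol_quality, tss_peak_profile)
from tfregulon.annotation_io import GeneModel

from conftest import make_genes


def peaks_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "score"])


class TestSymbolQuality:
    @pytest.mark.parametrize("symbol,expected", [
        ("SOX2", 3), ("POU5F1", 3), ("NANOG", 3), ("KLF4", 3),
        ("FAM83A", 1), ("MIR21", 1), ("MRPL3", 1),
        ("C9orf72", 1), ("C9ORF72", 1),          # orf matches any case
        ("LOC100128881", 1), ("AB1234CD", 1),    # 4 consecutive digits
        ("A1B2C3D4", 3),                          # digits not consecutive
        ("famously", 3),                          # FAM is case-sensitive
    ])
    def test_weak_symbol_rules(self, symbol, expected):
        assert symbol_quality(symbol) == expected

    def test_empty_symbol_rejected(self):
        with pytest.raises(ValueError):
            symbol_quality("")

    @given(st.text(alphabet=st.characters(codec="ascii"), min_size=1,
                   max_size=12))
    def test_returns_only_one_or_three(self, symbol):
        assert symbol_quality(symbol) in (1, 3)


class TestLoadGeneTable:
    def write(self, tmp_path, rows, header=True):
        path = tmp_path / "genes.tsv"
        lines = (["symbol\tchrom\tstrand\ttxStart\ttxEnd"] if header else [])
        lines += ["\t".join(map(str, r)) for r in rows]
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_close_alternative_tss_collapsed(self, tmp_path):
        # two transcripts 200 bp apart -> one TSS kept
        path = self.write(tmp_path, [("NANOG", "chr1", "+", 1000, 5000),
                                     ("NANOG", "chr1", "+", 1200, 5200)])
        gm = load_gene_table(path)
        assert list(gm.genes["tss"]) == [1000]

    def test_distant_alternative_tss_kept(self, tmp_path):
        path = self.write(tmp_path, [("NANOG", "chr1", "+", 1000, 5000),
                                     ("NANOG", "chr1", "+", 6000, 9000)])
        gm = load_gene_table(path)
        assert sorted(gm.genes["tss"]) == [1000, 6000]

    def test_minus_strand_tss_is_txend(self, tmp_path):
        path = self.write(tmp_path, [("SOX2", "chr3", "-", 1000, 5000)])
        gm = load_gene_table(path)
        assert list(gm.genes["tss"]) == [5000]

    def test_empty_file_gives_empty_model(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("")
        assert len(load_gene_table(path)) == 0

    def test_unknown_strand_rejected_with_row(self, tmp_path):
        path = self.write(tmp_path, [("SOX2", "chr3", ".", 1000, 5000)])
        with pytest.raises(ValueError, match="row 1"):
            load_gene_table(path)

    def test_malformed_coordinate_rejected(self, tmp_path):
        path = self.write(tmp_path, [("SOX2", "chr3", "+", "xx", 5000)])
        with pytest.raises(ValueError, match="row 1"):
            load_gene_table(path)

    def test_quality_assigned_from_symbol(self, tmp_path):
        path = self.write(tmp_path, [("SOX2", "chr3", "+", 1000, 5000),
                                     ("FAM83A", "chr3", "+", 9000, 9500)])
        gm = load_gene_table(path)
        q = dict(zip(gm.genes["symbol"], gm.genes["quality"]))
        assert q == {"SOX2": 3, "FAM83A": 1}


class TestMergeClosePeaks:
    def test_gap_below_500_merges_and_sums_scores(self):
        p = peaks_df([("chr1", 100, 200, 2.0), ("chr1", 500, 600, 3.0)])
        m = merge_close_peaks(p)
        assert m.to_numpy().tolist() == [["chr1", 100, 600, 5.0]]

    def test_gap_of_600_unchanged(self):
        p = peaks_df([("chr1", 100, 200, 2.0), ("chr1", 800, 900, 3.0)])
        assert len(merge_close_peaks(p)) == 2

    def test_chain_collapses_left_to_right(self):
        p = peaks_df([("chr1", 0, 100, 1.0), ("chr1", 400, 500, 1.0),
                      ("chr1", 800, 900, 1.0)])
        m = merge_close_peaks(p)
        assert m[["start", "end"]].to_numpy().tolist() == [[0, 900]]

    def test_different_chromosomes_never_merge(self):
        p = peaks_df([("chr1", 0, 100, 1.0), ("chr2", 100, 200, 1.0)])
        assert len(merge_close_peaks(p)) == 2

    @given(st.lists(st.tuples(st.integers(0, 10_000), st.integers(1, 800)),
                    min_size=1, max_size=30))
    def test_idempotent_and_min_gap(self, items):
        p = peaks_df([("chr1", s, s + w, 1.0) for s, w in items])
        once = merge_close_peaks(p)
        twice = merge_close_peaks(once)
        pd.testing.assert_frame_equal(once, twice)
        gaps = once["start"].to_numpy()[1:] - once["end"].to_numpy()[:-1]
        assert (gaps >= 500).all()
        assert once["score"].sum() == pytest.approx(p["score"].sum())


class TestCapPeaks:
    def test_under_cap_unchanged(self):
        p = peaks_df([("chr1", i * 1000, i * 1000 + 100, i) for i in range(10)])
        assert len(cap_peaks(p, max_n=25_000)) == 10

    def test_keeps_top_scoring(self):
        p = peaks_df([("chr1", i * 1000, i * 1000 + 100, float(i))
                      for i in range(100)])
        kept = cap_peaks(p, max_n=30)
        assert sorted(kept["score"]) == list(map(float, range(70, 100)))

    def test_ties_resolved_by_genome_order(self):
        # all scores equal: full sort oracle keeps the genomically first
        p = peaks_df([("chr1", s, s + 100, 1.0)
                      for s in [5000, 1000, 3000, 2000, 4000]])
        kept = cap_peaks(p, max_n=3)
        assert list(kept["start"]) == [1000, 2000, 3000]


class TestLoadPeaks:
    def test_bed3_scores_default_to_one(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t100\t200\nchr1\t900\t1000\n")
        ps = load_peaks(path, format="bed")
        assert list(ps.peaks["score"]) == [1.0, 1.0]

    def test_bed5_reads_score_column(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t100\t200\tp1\t7\nchr1\t900\t1000\tp2\t3\n")
        ps = load_peaks(path, format="bed")
        assert list(ps.peaks["score"]) == [7.0, 3.0]

    def test_narrowpeak_uses_signal_column(self, tmp_path):
        row = "chr1\t100\t200\tp1\t950\t.\t12.5\t30.1\t28.2\t50\n"
        path = tmp_path / "p.narrowPeak"
        path.write_text(row)
        ps = load_peaks(path, format="narrowPeak")
        assert list(ps.peaks["score"]) == [12.5]
        ps5 = load_peaks(path, format="narrowPeak", score_column=5)
        assert list(ps5.peaks["score"]) == [950.0]

    def test_invalid_interval_rows_dropped(self, tmp_path):
        path = tmp_path / "p.bed"
        path.write_text("chr1\t200\t100\nchr1\t900\t1000\n")
        ps = load_peaks(path, format="bed")
        assert len(ps) == 1

    def test_merge_and_cap_applied(self, tmp_path):
        # 40 adjacent intervals < 500 bp apart collapse; far ones capped
        lines = [f"chr1\t{i * 600}\t{i * 600 + 200}\tp\t1" for i in range(40)]
        lines += [f"chr1\t{10 ** 6 + i * 10 ** 4}\t{10 ** 6 + i * 10 ** 4 + 100}\tp\t5"
                  for i in range(30)]
        path = tmp_path / "p.bed"
        path.write_text("\n".join(lines) + "\n")
        ps = load_peaks(path, format="bed")
        gaps = (ps.peaks["start"].to_numpy()[1:]
                - ps.peaks["end"].to_numpy()[:-1])
        assert (gaps >= 500).all()
        capped = cap_peaks(ps.peaks, max_n=10)
        assert len(capped) == 10


class TestTssPeakProfile:
    def test_centers_at_tss_single_spike(self):
        genes = make_genes([100_000, 300_000, 500_000])
        p = peaks_df([("chr1", t - 50, t + 50, 1.0)
                      for t in (100_000, 300_000)])
        from tfregulon.annotation_io import PeakSet
        prof = tss_peak_profile(PeakSet("TF", "e1", p), genes)
        assert prof.qc_pass
        assert prof.counts.sum() == 2
        assert abs(prof.mode_offset) <= 1000

    def test_uniform_peaks_fail_qc(self, rng):
        genes = make_genes(np.arange(50) * 400_000 + 200_000)
        starts = np.sort(rng.integers(0, 2 * 10 ** 7, size=400))
        p = peaks_df([("chr1", int(s), int(s) + 100, 1.0) for s in starts])
        from tfregulon.annotation_io import PeakSet
        prof = tss_peak_profile(PeakSet("TF", "e1", p), genes)
        assert not prof.qc_pass

    def test_promoter_biased_peaks_pass_qc(self, rng):
        genes = make_genes(np.arange(50) * 400_000 + 200_000)
        offs = rng.normal(0, 2_000, size=300).astype(int)
        tss = rng.choice(genes.genes["tss"].to_numpy(), size=300)
        p = peaks_df([("chr1", int(t + o) - 50, int(t + o) + 50, 1.0)
                      for t, o in zip(tss, offs)])
        from tfregulon.annotation_io import PeakSet
        prof = tss_peak_profile(PeakSet("TF", "e1", p), genes)
        assert prof.qc_pass
        assert abs(prof.mode_offset) <= 5_000

    def test_counts_sum_to_peaks_within_window(self):
        genes = make_genes([1_000_000])
        p = peaks_df([("chr1", 1_000_000, 1_000_100, 1.0),   # near
                      ("chr1", 5_000_000, 5_000_100, 1.0)])  # > 100 kb away
        from tfregulon.annotation_io import PeakSet
        prof = tss_peak_profile(PeakSet("TF", "e1", p), genes)
        assert prof.counts.sum() == 1

    def test_strand_aware_sign(self):
        genes = GeneModel(pd.DataFrame({
            "symbol": ["A", "B"], "chrom": "chr1", "strand": ["+", "-"],
            "tss": [100_000, 900_000], "quality": 3}))
        # both peaks 10 kb to the genomic right of the TSS
        p = peaks_df([("chr1", 109_950, 110_050, 1.0),
                      ("chr1", 909_950, 910_050, 1.0)])
        from tfregulon.annotation_io import PeakSet
        prof = tss_peak_profile(PeakSet("TF", "e1", p), genes)
        mid = (prof.bin_edges[:-1] + prof.bin_edges[1:]) / 2
        hit = mid[prof.counts > 0]
        # + strand: downstream (+10 kb); - strand: upstream (-10 kb)
        assert set(np.sign(hit)) == {1.0, -1.0}
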