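"""Window tiling, coverage counting, masking rules, spike normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polkin.windows import (
    Coverage,
    TranscriptionUnit,
    WindowVector,
    count_coverage,
    flag_termination_missing,
    make_windows,
    spike_size_factors,
)


class TestMakeWindows:
    def test_80kb_tu_gives_80_body_windows(self, plus_tu):
        wins = make_windows(plus_tu, "body_1kb")
        assert len(wins) == 80
        assert wins[0] == (100_000, 101_000)

    def test_pas_grid_has_20_upstream_and_100_downstream(self, plus_tu):
        wins = make_windows(plus_tu, "pas_250nt")
        assert len(wins) == 120
        assert wins[0] == (175_000, 175_250)  # PAS-5kb
        assert wins[20] == (180_000, 180_250)  # first downstream

    def test_minus_strand_window1_is_genomically_rightmost(self, minus_tu):
        wins = make_windows(minus_tu, "body_1kb")
        assert wins[0] == (499_000, 500_000)
        assert wins[0][0] > wins[-1][0]

    def test_partial_terminal_window_dropped(self):
        tu = TranscriptionUnit("t", "chr1", "+", 0, 2500)
        assert len(make_windows(tu, "body_1kb")) == 2

    def test_short_tu_warns_and_returns_empty(self):
        tu = TranscriptionUnit("t", "chr1", "+", 0, 500)
        with pytest.warns(UserWarning):
            assert make_windows(tu, "body_1kb") == []

    @given(length=st.integers(1000, 300_000), width=st.sampled_from([250, 500, 1000]))
    @settings(max_examples=30, deadline=None)
    def test_tiling_is_a_partition(self, length, width):
        tu = TranscriptionUnit("t", "chr1", "+", 10_000, 10_000 + length)
        wins = make_windows(tu, "custom", width)
        assert len(wins) == length // width
        for (s1, e1), (s2, e2) in zip(wins[:-1], wins[1:]):
            assert e1 == s2 and e1 - s1 == width


class TestCountCoverage:
    def test_uniform_coverage_counts_window_width(self, plus_tu, uniform_coverage):
        wins = make_windows(plus_tu, "body_1kb")
        wv = count_coverage(uniform_coverage, plus_tu, wins, flag_exons=False)
        assert np.allclose(wv.counts, 1000.0)

    def test_exon_overlap_flags_missing(self, plus_tu, uniform_coverage):
        wins = make_windows(plus_tu, "body_1kb")
        wv = count_coverage(uniform_coverage, plus_tu, wins)
        # exon spans 110,200-111,700 -> windows 11 and 12 (0-based 10, 11)
        assert wv.missing[10] and wv.missing[11]
        assert not wv.missing[9] and not wv.missing[12]

    def test_input_subtraction_retains_negative_values(self, plus_tu, uniform_coverage):
        big_input = Coverage.from_intervals(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [1_000_000], "value": [3.0]})
        )
        wins = make_windows(plus_tu, "body_1kb")
        wv = count_coverage(uniform_coverage, plus_tu, wins, input_coverage=big_input, flag_exons=False)
        assert np.allclose(wv.counts, -2000.0)

    def test_absent_chromosome_gives_all_missing(self, plus_tu):
        cov = Coverage.from_intervals(
            pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [100], "value": [1.0]})
        )
        wins = make_windows(plus_tu, "body_1kb")
        with pytest.warns(UserWarning):
            wv = count_coverage(cov, plus_tu, wins)
        assert wv.missing.all()

    def test_counting_is_additive(self, plus_tu, rng):
        """Counting the sum of two tracks equals the sum of counts."""
        edges = np.arange(90_000, 200_000, 777)
        frames = []
        for seed in (1, 2):
            vals = np.random.default_rng(seed).uniform(0, 2, len(edges) - 1)
            frames.append(
                pd.DataFrame({"chrom": "chr1", "start": edges[:-1], "end": edges[1:], "value": vals})
            )
        summed = frames[0].assign(value=frames[0]["value"] + frames[1]["value"])
        wins = make_windows(plus_tu, "body_1kb")
        c1 = count_coverage(Coverage.from_intervals(frames[0]), plus_tu, wins, flag_exons=False)
        c2 = count_coverage(Coverage.from_intervals(frames[1]), plus_tu, wins, flag_exons=False)
        cs = count_coverage(Coverage.from_intervals(summed), plus_tu, wins, flag_exons=False)
        assert np.allclose(c1.counts + c2.counts, cs.counts)

    def test_strand_symmetry(self, uniform_coverage):
        """Mirroring coordinates and strand leaves the WindowVector unchanged."""
        N = 1_000_000
        edges = np.arange(100_000, 200_000, 1234)
        vals = np.random.default_rng(7).uniform(0, 3, len(edges) - 1)
        fwd = pd.DataFrame({"chrom": "chr1", "start": edges[:-1], "end": edges[1:], "value": vals})
        mirr = pd.DataFrame(
            {"chrom": "chr1", "start": N - edges[1:], "end": N - edges[:-1], "value": vals}
        ).iloc[::-1]
        tu_f = TranscriptionUnit("t", "chr1", "+", 100_000, 180_000)
        tu_r = TranscriptionUnit("t", "chr1", "-", N - 100_000, N - 180_000)
        cf = count_coverage(Coverage.from_intervals(fwd), tu_f, make_windows(tu_f, "body_1kb"))
        cr = count_coverage(Coverage.from_intervals(mirr), tu_r, make_windows(tu_r, "body_1kb"))
        assert np.allclose(cf.counts, cr.counts)


class TestTerminationMask:
    def _grid(self, tu):
        return WindowVector(tu.id, "pas_250nt", 250, np.ones(120))

    def test_short_tu_flags_all_upstream(self):
        tu = TranscriptionUnit("t", "chr1", "+", 0, 4000)
        wv = flag_termination_missing(tu, self._grid(tu))
        assert wv.missing[:20].all() and not wv.missing[20:].any()

    def test_downstream_neighbor_tss_truncates(self):
        tu = TranscriptionUnit("t", "chr1", "+", 0, 100_000)
        nb = TranscriptionUnit("n", "chr1", "+", 110_000, 130_000)  # TSS at PAS+10kb
        wv = flag_termination_missing(tu, self._grid(tu), [nb])
        first = 20 + 10_000 // 250
        assert not wv.missing[first - 1] and wv.missing[first:].all()

    def test_opposite_strand_neighbor_ignored(self):
        tu = TranscriptionUnit("t", "chr1", "+", 0, 100_000)
        nb = TranscriptionUnit("n", "chr1", "-", 130_000, 110_000)
        wv = flag_termination_missing(tu, self._grid(tu), [nb])
        assert not wv.missing.any()


class TestSpikeFactors:
    def test_median_normalization(self):
        f = spike_size_factors({"a": 10e6, "b": 20e6, "c": 40e6})
        assert np.allclose(f[["a", "b", "c"]], [0.5, 1.0, 2.0])

    def test_equal_totals_give_unity(self):
        assert np.allclose(spike_size_factors({"a": 5, "b": 5}), 1.0)

    def test_single_sample_factor_is_one(self):
        assert spike_size_factors({"only": 123.0})["only"] == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            spike_size_factors({"a": 0.0, "b": 10.0})
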