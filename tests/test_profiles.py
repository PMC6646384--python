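"""IS-anchored profiling: G4 status, mirror convention, nulls, heatmap."""

import numpy as np
import pandas as pd
import pytest

from g4ori import (
    G4Region,
    GenomeModel,
    GenomicInterval,
    OriginRecord,
    ValidationError,
    assign_g4_status,
    count_reads_in_intervals,
    peak_offset,
    positional_profile,
    shuffle_null_band,
    signal_heatmap,
)
from conftest import make_origins


def g4(chrom, start, end, strand="+", score=3.0, method="window_scorer"):
    return G4Region(GenomicInterval(chrom, start, end, strand), method, score)


def origin(chrom="chr1", is_pos=10_000, halfwidth=150, oid="origin_1"):
    return OriginRecord(
        GenomicInterval(chrom, is_pos - halfwidth, is_pos + halfwidth),
        is_pos,
        frozenset(),
        oid,
    )


class TestAssignStatus:
    def test_g4_within_halfwidth_positive(self):
        o = origin(is_pos=10_000)
        st = assign_g4_status([o], [g4("chr1", 9_580, 9_600)])
        assert st.loc["origin_1", "g4_positive"]

    def test_g4_beyond_halfwidth_negative(self):
        o = origin(is_pos=10_000)
        st = assign_g4_status([o], [g4("chr1", 9_380, 9_400)])
        assert not st.loc["origin_1", "g4_positive"]
        assert st.loc["origin_1", "nearest_bp"] == -601

    def test_edge_exactly_at_bound_inclusive(self):
        o = origin(is_pos=10_000)
        # G4 whose last base sits exactly at IS-500
        st = assign_g4_status([o], [g4("chr1", 9_480, 9_501)])
        assert st.loc["origin_1", "g4_positive"]
        st2 = assign_g4_status([o], [g4("chr1", 10_500, 10_520)])
        assert st2.loc["origin_1", "g4_positive"]

    def test_score_filter(self):
        o = origin(is_pos=10_000)
        st = assign_g4_status([o], [g4("chr1", 9_900, 9_920, score=1.5)])
        assert not st.loc["origin_1", "g4_positive"]

    def test_interval_midpoint_center_option(self):
        # asymmetric span: IS at 10_000 but interval midpoint at 10_100
        o = OriginRecord(
            GenomicInterval("chr1", 9_900, 10_300), 10_000, frozenset(), "origin_1"
        )
        region = [g4("chr1", 10_550, 10_570)]  # within 500 of midpoint only
        assert not assign_g4_status([o], region).loc["origin_1", "g4_positive"]
        assert assign_g4_status([o], region, center="midpoint").loc[
            "origin_1", "g4_positive"
        ]


class TestProfile:
    def test_plus_strand_direct_mapping(self):
        o = origin(is_pos=10_000)
        regions = [g4("chr1", 10_000 - 260, 10_000 - 240)]  # offsets -260..-241
        prof = positional_profile([o], regions, flank=1000)
        hot = prof.offsets[prof.fraction == 1.0]
        assert hot.tolist() == list(range(-260, -240))
        assert prof.fraction.sum() == 20

    def test_minus_strand_mirror_convention(self):
        o = origin(is_pos=10_000)
        # minus-strand G4 at genomic offsets +241..+260 maps to -260..-241
        regions = [g4("chr1", 10_241, 10_261, strand="-")]
        prof = positional_profile([o], regions, flank=1000)
        hot = prof.offsets[prof.fraction == 1.0]
        assert hot.tolist() == list(range(-260, -240))

    def test_coverage_conservation(self):
        rng = np.random.default_rng(8)
        origins = make_origins(20, spacing=5000)
        regions = []
        for o in origins:
            for _ in range(rng.integers(0, 4)):
                s = o.is_pos + int(rng.integers(-900, 900))
                regions.append(g4("chr1", s, s + 25, strand="+"))
        prof = positional_profile(origins, regions, flank=1000)
        total_cov = 0
        for o in origins:
            mask = np.zeros(2001, bool)
            for r in regions:
                lo = max(r.interval.start, o.is_pos - 1000) - o.is_pos
                hi = min(r.interval.end, o.is_pos + 1001) - o.is_pos
                if lo < hi:
                    mask[lo + 1000 : hi + 1000] = True
            total_cov += mask.sum()
        assert prof.fraction.sum() * len(origins) == pytest.approx(total_cov)

    def test_wilson_band_contains_fraction(self):
        origins = make_origins(50, spacing=4000)
        regions = [g4("chr1", o.is_pos - 255, o.is_pos - 230) for o in origins[:25]]
        prof = positional_profile(origins, regions, flank=500)
        assert (prof.ci_low <= prof.fraction + 1e-12).all()
        assert (prof.fraction <= prof.ci_high + 1e-12).all()

    def test_midpoint_mode_counts_single_base(self):
        o = origin(is_pos=10_000)
        regions = [g4("chr1", 10_000 - 260, 10_000 - 240)]  # midpoint at -250
        prof = positional_profile([o], regions, flank=1000, mode="midpoint")
        hot = prof.offsets[prof.fraction == 1.0]
        assert hot.tolist() == [-250]
        assert prof.fraction.sum() == 1

    def test_empty_origin_set_errors(self):
        with pytest.raises(ValidationError):
            positional_profile([], [], flank=100)


class TestPeakOffset:
    def _profile(self, frac, flank):
        from g4ori.profiles import PositionalProfile

        return PositionalProfile(
            offsets=np.arange(-flank, flank + 1),
            fraction=np.asarray(frac, float),
            ci_low=np.zeros(2 * flank + 1),
            ci_high=np.ones(2 * flank + 1),
            n_origins=10,
        )

    def test_unique_max(self):
        frac = np.zeros(2001)
        frac[1000 - 250] = 0.5
        assert peak_offset(self._profile(frac, 1000)) == -250

    def test_symmetric_tie_prefers_negative(self):
        frac = np.zeros(201)
        frac[100 - 100] = 0.5  # offset -100
        frac[100 + 100] = 0.5  # offset +100
        assert peak_offset(self._profile(frac, 100)) == -100

    def test_flat_profile_warns_zero(self):
        with pytest.warns(UserWarning, match="flat"):
            assert peak_offset(self._profile(np.full(201, 0.2), 100)) == 0


class TestNullBand:
    def test_zero_g4_band_identically_zero(self):
        genome = GenomeModel({"chr1": 100_000})
        origins = make_origins(10, spacing=5000)
        prof = shuffle_null_band(origins, [], genome, flank=200, n_shuffles=5, seed=1)
        assert not prof.null_mean.any()
        assert not prof.null_high.any()

    def test_single_shuffle_degenerate_band(self):
        genome = GenomeModel({"chr1": 100_000})
        origins = make_origins(10, spacing=5000)
        rng = np.random.default_rng(0)
        regions = [
            g4("chr1", int(s), int(s) + 20)
            for s in rng.integers(0, 99_000, size=100)
        ]
        prof = shuffle_null_band(
            origins, regions, genome, flank=200, n_shuffles=1, seed=1
        )
        assert np.allclose(prof.null_low, prof.null_mean)
        assert np.allclose(prof.null_high, prof.null_mean)

    def test_seed_reproducibility_and_divergence(self):
        genome = GenomeModel({"chr1": 100_000})
        origins = make_origins(10, spacing=5000)
        rng = np.random.default_rng(1)
        regions = [
            g4("chr1", int(s), int(s) + 20)
            for s in rng.integers(0, 99_000, size=200)
        ]
        a = shuffle_null_band(origins, regions, genome, flank=100, n_shuffles=20, seed=4)
        b = shuffle_null_band(origins, regions, genome, flank=100, n_shuffles=20, seed=4)
        c = shuffle_null_band(origins, regions, genome, flank=100, n_shuffles=20, seed=5)
        assert np.array_equal(a.null_mean, b.null_mean)
        assert not np.array_equal(a.null_mean, c.null_mean)


class TestHeatmap:
    def test_default_geometry_140_columns(self):
        origins = make_origins(3, spacing=20_000, first_is=10_000)
        df = signal_heatmap(origins, [])
        assert df.shape == (3, 140)

    def test_reads_at_is_hot_center(self):
        origins = make_origins(1, first_is=10_000)
        reads = [GenomicInterval("chr1", 9_990, 10_010)] * 7
        df = signal_heatmap(origins, reads)
        center = df.columns[70]  # bin starting at offset 0
        assert df.iloc[0][center] == 7
        assert df.iloc[0].sum() == 7

    def test_row_sums_match_window_counts(self):
        rng = np.random.default_rng(12)
        origins = make_origins(5, spacing=20_000, first_is=10_000)
        reads = [
            GenomicInterval("chr1", int(s), int(s) + 30)
            for s in rng.integers(0, 90_000, size=400)
        ]
        df = signal_heatmap(origins, reads)
        windows = [
            GenomicInterval("chr1", o.is_pos - 7000, o.is_pos + 7000) for o in origins
        ]
        expected = count_reads_in_intervals(reads, windows)
        got = df.loc[[o.origin_id for o in origins]].sum(axis=1).to_numpy()
        assert np.array_equal(got, expected)

    def test_rows_sorted_by_fold_change(self):
        origins = make_origins(4, spacing=20_000, first_is=10_000)
        diff = pd.DataFrame(
            {"log2FC": [0.5, -1.0, 3.0, 1.5]},
            index=[o.origin_id for o in origins],
        )
        df = signal_heatmap(origins, [], diff=diff)
        assert df.index.tolist() == ["origin_3", "origin_4", "origin_1", "origin_2"]

    def test_bin_must_divide_span(self):
        with pytest.raises(ValidationError):
            signal_heatmap(make_origins(1, first_is=10_000), [], flank=7000, bin_size=300)
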