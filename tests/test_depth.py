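"""Read-depth / span-depth profiles, scaling, segmentation, disomy calls."""

import numpy as np
import pytest

from gcrscope.depth import (
    build_depth_profiles,
    call_disomies,
    scale_profile,
    segment_profile,
)
from gcrscope.errors import ConfigurationError
from gcrscope.pairs import EndAlignment, ReadPairAlignment


def test_single_pair_depth_definitions(ref):
    """One concordant pair, 100-bp reads, 600-bp insert: read depth covers
    200 bases, span depth covers the full 600-base fragment."""
    p = ReadPairAlignment(
        "p",
        EndAlignment("chrV", 1_000, 1_100, "+", "unique", 0, "A"),
        EndAlignment("chrV", 1_500, 1_600, "-", "unique", 0, "A"),
    )
    rd, sd = build_depth_profiles([p], ref)
    assert rd.counts["chrV"].sum() == 200
    assert sd.counts["chrV"].sum() == 600
    assert sd.counts["chrV"][1_000:1_600].min() == 1


def test_span_dominates_read_depth(clean_pairs, ref):
    pairs, _, _ = clean_pairs
    rd, sd = build_depth_profiles(pairs, ref)
    for chrom in ref.chrom_names:
        assert np.all(sd.counts[chrom] >= rd.counts[chrom])


def test_mean_depth_tracks_coverage(clean_pairs, ref):
    pairs, _, _ = clean_pairs
    rd, _ = build_depth_profiles(pairs, ref)
    allv = np.concatenate([rd.counts[c][2000:-2000] for c in ref.chrom_names])
    assert abs(allv.mean() - 50) / 50 < 0.08


@pytest.fixture(scope="module")
def scaled(clean_pairs, ref, ctx):
    pairs, _, _ = clean_pairs
    rd, _ = build_depth_profiles(pairs, ref)
    cd, _ = build_depth_profiles([p for p in pairs if p.concordant], ref)
    return scale_profile(rd, cd, ctx.mask)


def test_scaling_normalizes_median(scaled):
    med = np.median(scaled.unmasked_values())
    assert abs(med - 1.0) <= 0.02


def test_most_bases_near_1n(scaled):
    """Per-base scaled depth concentrates around 1n.

    At 50x a Poisson marginal puts ~97% of bases within +-0.3n; requiring
    both ends of a pair to map uniquely depresses coverage within an
    insert length of multi-mapping islands, so the realised fraction runs
    a few points lower, with the wide band essentially complete.
    """
    vals = np.concatenate(
        [scaled.values[c][2000:-2000][scaled.mask[c][2000:-2000]] for c in scaled.values]
    )
    assert np.mean((vals >= 0.7) & (vals <= 1.3)) >= 0.90
    assert np.mean((vals >= 0.5) & (vals <= 1.5)) >= 0.98


def test_flat_profile_single_segment(scaled):
    segs = [s for s in segment_profile(scaled) if s.chrom == "chrIII"]
    assert len(segs) == 1
    assert segs[0].copy_state == 1


def test_min_seg_must_cover_window(scaled):
    with pytest.raises(ConfigurationError):
        segment_profile(scaled, window=500, min_seg=200)


def test_deleted_interval_near_zero(analyzed):
    truth, res = analyzed["interstitial_deletion"]
    chrom, d, a = truth.deleted[0]
    vals = res.copy_number.values[chrom][d + 200 : a - 200]
    good = vals[~np.isnan(vals)]
    assert np.nanmean(good) < 0.05


def test_duplicated_interval_near_two(analyzed):
    truth, res = analyzed["hairpin_repeat_HR"]
    chrom, s, e = truth.duplicated[0]
    vals = res.copy_number.values[chrom][s + 300 : e - 300]
    good = vals[~np.isnan(vals)]
    assert abs(np.mean(good) - 2.0) <= 0.15


def test_terminal_zero_segment_at_break(analyzed):
    truth, res = analyzed["telomere_addition"]
    a = truth.junctions[0].breakend_b.pos
    segs = sorted((s for s in res.segments if s.chrom == "chrV"), key=lambda s: s.start)
    assert segs[0].copy_state == 0
    assert abs(segs[0].end - a) <= 500  # window resolution


def test_duplication_segments_at_state_two(analyzed):
    """The inverted duplication segments at state 2 and begins at the
    inversion point; pair coverage sags within an insert length of
    multi-mapping islands, so a margin of the interval may segment low."""
    truth, res = analyzed["hairpin_repeat_HR"]
    chrom, s, e = truth.duplicated[0]
    seg2 = [g for g in res.segments if g.chrom == chrom and g.copy_state == 2]
    assert seg2
    assert abs(min(g.start for g in seg2) - truth.pivot) <= 500  # window resolution
    covered = sum(max(0, min(g.end, e) - max(g.start, s)) for g in seg2)
    assert covered / (e - s) >= 0.6


def test_disomy_called_only_on_disomic_chromosome(analyzed):
    truth, res = analyzed["disomy"]
    calls = {d.chrom: d.disomic for d in call_disomies(res.copy_number)}
    assert calls["chrIII"] is True
    assert not calls.get("chrII", False)


def test_all_1n_genome_has_no_disomy(unrearranged_result):
    assert unrearranged_result.disomies == []


def test_gcr_duplicated_chromosome_not_disomic(analyzed):
    """A chromosome partially duplicated by a GCR is bimodal, not 2n."""
    _, res = analyzed["hairpin_repeat_HR"]
    calls = {d.chrom: d.disomic for d in call_disomies(res.copy_number)}
    assert not any(calls.values())
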