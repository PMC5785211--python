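import numpy as np
import pandas as pd
import pytest

from clocklight import chip as ch
from clocklight import synth


# ---------------------------------------------------------------------------
# smoothing


def test_smooth_constant_track_unchanged():
    track = ch.SignalTrack(np.full(5000, 7.0))
    out = ch.smooth_track(track)
    np.testing.assert_allclose(out.values, 7.0)


def test_smooth_impulse_gives_truncated_gaussian_of_unit_mass():
    n = 5000
    track = ch.SignalTrack(np.zeros(n))
    track.values[2500] = 1.0
    out = ch.smooth_track(track, window_bp=400, sd_bp=50)
    x = np.arange(-200, 201)
    kernel = np.exp(-0.5 * (x / 50.0) ** 2)
    kernel /= kernel.sum()
    np.testing.assert_allclose(out.values[2300:2701], kernel, atol=1e-12)
    assert out.values.sum() == pytest.approx(1.0)


def test_smooth_conserves_total_signal_on_circular_genome():
    rng = np.random.default_rng(0)
    track = ch.SignalTrack(rng.uniform(0, 10, 3000), circular=True)
    out = ch.smooth_track(track)
    assert out.values.sum() == pytest.approx(track.values.sum())


def test_smooth_is_linear():
    rng = np.random.default_rng(1)
    a = ch.SignalTrack(rng.uniform(0, 5, 2000))
    b = ch.SignalTrack(rng.uniform(0, 5, 2000))
    combo = ch.SignalTrack(2.0 * a.values + 3.0 * b.values)
    np.testing.assert_allclose(
        ch.smooth_track(combo).values,
        2.0 * ch.smooth_track(a).values + 3.0 * ch.smooth_track(b).values,
        atol=1e-9,
    )


def test_smooth_rejects_nonpositive_sd():
    with pytest.raises(ValueError):
        ch.smooth_track(ch.SignalTrack(np.ones(100)), sd_bp=0)


# ---------------------------------------------------------------------------
# peak calling


def test_no_peaks_when_ip_equals_mock():
    values = np.full(2000, 5.0)
    peaks = ch.call_peaks(ch.SignalTrack(values), ch.SignalTrack(values.copy()))
    assert peaks == []


def test_planted_fold5_peak_found_with_summit_within_1bp(chip_fixture):
    ip, mock = chip_fixture["smoothed"][0]
    peaks = ch.call_peaks(ip, mock, 3.5, min_width_bp=100)
    summits = {p.summit for p in peaks}
    for planted_summit, fold, _ in chip_fixture["planted"]:
        if fold >= 4.0:
            assert any(abs(s - planted_summit) <= 1 for s in summits), (planted_summit, fold)


def test_fold_3p4_bump_is_rejected(chip_fixture):
    ip, mock = chip_fixture["smoothed"][0]
    peaks = ch.call_peaks(ip, mock, 3.5)
    rejected = [s for s, fold, _ in chip_fixture["planted"] if fold < 3.5]
    for summit in rejected:
        assert all(abs(p.summit - summit) > 2000 for p in peaks)


def test_call_peaks_invariant_to_common_scaling(chip_fixture):
    ip, mock = chip_fixture["smoothed"][0]
    peaks1 = ch.call_peaks(ip, mock)
    peaks2 = ch.call_peaks(
        ch.SignalTrack(ip.values * 7.5), ch.SignalTrack(mock.values * 7.5)
    )
    assert [(p.start, p.end, p.summit) for p in peaks1] == [
        (p.start, p.end, p.summit) for p in peaks2
    ]


def test_call_peaks_rejects_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        ch.call_peaks(ch.SignalTrack(np.ones(10)), ch.SignalTrack(np.ones(20)))


def test_peak_wrapping_circular_origin():
    n = 10_000
    mock = np.full(n, 10.0)
    ip = np.full(n, 10.0)
    span = np.arange(-150, 151)
    ip[span % n] += 10.0 * 40.0 * np.exp(-0.5 * (span / 60.0) ** 2)
    peaks = ch.call_peaks(
        ch.smooth_track(ch.SignalTrack(ip)), ch.smooth_track(ch.SignalTrack(mock))
    )
    assert len(peaks) == 1
    assert min(peaks[0].summit, n - peaks[0].summit) <= 2


# ---------------------------------------------------------------------------
# replicate consistency


def _peak(start, end, summit=None):
    return ch.Peak(start, end, summit if summit is not None else start, 5.0)


def test_identical_replicate_peaks_all_kept():
    peaks = [_peak(100, 400), _peak(1000, 1200)]
    assert len(ch.replicate_consistent_peaks(peaks, list(peaks), 5000)) == 2


def test_disjoint_replicate_peaks_dropped():
    assert ch.replicate_consistent_peaks([_peak(100, 400)], [_peak(500, 700)], 5000) == []


def test_one_bp_overlap_suffices():
    kept = ch.replicate_consistent_peaks([_peak(100, 400)], [_peak(399, 600)], 5000)
    assert [(p.start, p.end) for p in kept] == [(100, 400)]


def test_replicate_consistent_round_trip(chip_fixture):
    peak_sets = [
        ch.call_peaks(ip, mock, 3.5) for ip, mock in chip_fixture["smoothed"]
    ]
    kept = ch.replicate_consistent_peaks(peak_sets[0], peak_sets[1], chip_fixture["genome"])
    expected = sorted(s for s, fold, _ in chip_fixture["planted"] if fold >= 4.0)
    assert sorted(p.summit for p in kept) == pytest.approx(expected, abs=1)


# ---------------------------------------------------------------------------
# peak-to-gene assignment (with a brute-force validator)


def _brute_force_links(peaks, annotation, max_distance=500):
    """Independent re-test of the three printed rules on every pair."""
    links = set()
    n = annotation.genome_length
    for pi, peak in enumerate(peaks):
        for gene in annotation.genes:
            sc = gene.start_codon0
            d = min(abs(peak.summit - sc), n - abs(peak.summit - sc))
            if d > max_distance:
                continue
            if gene.strand == "+":
                upstream = (sc - peak.summit) % n == d
            else:
                upstream = (peak.summit - sc) % n == d
            if not upstream:
                continue
            same_strand = [g for g in annotation.genes if g.strand == gene.strand]
            dists = {
                g.gene_id: min(abs(peak.summit - g.start_codon0), n - abs(peak.summit - g.start_codon0))
                for g in same_strand
            }
            if gene.gene_id == min(dists, key=lambda gid: (dists[gid], gid)):
                links.add((pi, gene.gene_id))
    return links


def _toy_annotation(genome=100_000):
    genes = [
        ch.Gene("plus_near", 1301, 2300, "+"),      # summit 1000 -> 300 bp upstream
        ch.Gene("plus_far", 3600, 4000, "+"),       # > 500 bp from any summit
        ch.Gene("plus_pair_a", 11201, 11800, "+"),  # 200 bp from summit 11000
        ch.Gene("plus_pair_b", 11401, 12000, "+"),  # farther; must lose the tie
        ch.Gene("minus_near", 20, 901, "-"),        # start codon at base 900 (0-based), upstream of summit 1000
        ch.Gene("minus_far", 30_000, 30_400, "-"),
        ch.Gene("downstream_only", 21_000, 21_900, "+"),  # summit sits inside gene body
        ch.Gene("wrap_plus", 201, 700, "+"),        # tests circular wrap from ~genome end
        ch.Gene("minus_left", 40_000, 40_900, "-"), # summit left of start codon: downstream
        ch.Gene("plus_600", 51_601, 52_400, "+"),   # exactly 600 bp: outside the cutoff
    ]
    return ch.GeneAnnotation(genes, genome, circular=True)


def _peaks_at(summits):
    return [ch.Peak(s - 50, s + 50, s, 5.0) for s in summits]


def test_assignment_examples_on_toy_annotation():
    ann = _toy_annotation()
    peaks = _peaks_at([1000, 11_000, 21_400, 51_000, 99_900, 40_500])
    links = ch.assign_peak_targets(peaks, ann)
    by_gene = {l.gene_id: l for l in links}
    assert by_gene["plus_near"].distance == 300
    assert by_gene["minus_near"].distance == 100  # divergent promoter, same peak
    assert by_gene["plus_pair_a"].distance == 200
    assert "plus_pair_b" not in by_gene          # closest-gene rule
    assert "plus_600" not in by_gene             # 600 bp > 500 bp cutoff
    assert "downstream_only" not in by_gene      # summit not upstream
    assert "minus_left" not in by_gene           # wrong side for a minus gene
    assert by_gene["wrap_plus"].distance == 300  # wraps the circular origin


def test_assignment_matches_brute_force_validator():
    ann = _toy_annotation()
    rng = np.random.default_rng(0)
    summits = [1000, 11_000, 21_400, 51_000, 99_900, 40_500] + list(
        rng.integers(0, 100_000, 25)
    )
    peaks = _peaks_at(summits)
    links = ch.assign_peak_targets(peaks, ann)
    got = {(peaks.index(l.peak), l.gene_id) for l in links}
    assert got == _brute_force_links(peaks, ann)


def test_assignment_at_most_one_gene_per_strand_per_peak():
    ann = _toy_annotation()
    peaks = _peaks_at(list(range(0, 100_000, 997)))
    links = ch.assign_peak_targets(peaks, ann)
    seen = {}
    for l in links:
        key = (id(l.peak), l.strand)
        assert key not in seen
        seen[key] = l.gene_id


def test_assignment_rejects_strandless_gene():
    ann = ch.GeneAnnotation([ch.Gene("g", 100, 200, ".")], 1000)
    with pytest.raises(ValueError, match="strand"):
        ch.assign_peak_targets(_peaks_at([150]), ann)


def test_full_planted_truth_recovery():
    """Generator round trip: summits within 1 bp, planted promoter genes linked."""
    genome = 150_000
    planted = [(30_000, 5.0, 200.0), (90_000, 4.5, 200.0)]
    reps = synth.make_chip_tracks(genome, planted, seed=9)
    sets_ = []
    for ip, mock in reps:
        sets_.append(ch.call_peaks(ch.smooth_track(ip), ch.smooth_track(mock), 3.5))
    peaks = ch.replicate_consistent_peaks(sets_[0], sets_[1], genome)
    assert sorted(p.summit for p in peaks) == pytest.approx([30_000, 90_000], abs=1)
    ann = ch.GeneAnnotation(
        [ch.Gene("promA", 30_201, 31_000, "+"), ch.Gene("promB", 89_000, 89_900, "-")],
        genome,
    )
    links = ch.assign_peak_targets(peaks, ann)
    assert sorted(l.gene_id for l in links) == ["promA", "promB"]


# ---------------------------------------------------------------------------
# enrichment change table and correlations


def _links_with_series(enrichments):
    peak = ch.Peak(900, 1100, 1000, 5.0, dict(enrichments))
    return [ch.PeakGeneLink(peak, "g0", 300, "+")]


def _log2_expr(values):
    cols = pd.MultiIndex.from_tuples(list(values), names=["condition", "time_h"])
    return pd.DataFrame([list(values.values())], index=["g0"], columns=cols)


def test_change_table_self_comparison_is_zero():
    links = _links_with_series({("HighLight", 8.0): 4.0})
    expr = _log2_expr({("HighLight", 8.0): 1.5})
    table = ch.enrichment_change_table(links, expr, [(8.0, 8.0, "HighLight")])
    assert table["delta_log2_enrichment"].iloc[0] == 0.0
    assert table["delta_log2_expression"].iloc[0] == 0.0


def test_change_table_powers_of_two():
    links = _links_with_series({("HighLight", 8.0): 4.0, ("HighLight", 9.0): 8.0})
    expr = _log2_expr({("HighLight", 8.0): 1.0, ("HighLight", 9.0): 3.0})
    table = ch.enrichment_change_table(links, expr, [(9.0, 8.0, "HighLight")])
    assert table["delta_log2_enrichment"].iloc[0] == pytest.approx(1.0)
    assert table["delta_log2_expression"].iloc[0] == pytest.approx(2.0)


def test_change_table_missing_timepoint_raises():
    links = _links_with_series({("HighLight", 8.0): 4.0})
    expr = _log2_expr({("HighLight", 8.0): 1.0})
    with pytest.raises(ValueError, match="9.0"):
        ch.enrichment_change_table(links, expr, [(9.0, 8.0, "HighLight")])


def test_delta_correlation_identity_and_anti_identity():
    table = pd.DataFrame(
        {
            "condition": ["HL"] * 3 + ["Shade"] * 3,
            "delta_log2_enrichment": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            "delta_log2_expression": [1.0, 2.0, 3.0, -1.0, -2.0, -3.0],
        }
    )
    r = ch.delta_correlation(table)
    assert r["HL"] == pytest.approx(1.0)
    assert r["Shade"] == pytest.approx(-1.0)


def test_delta_correlation_matches_closed_form():
    x = np.array([1.0, 2.0, 3.0])
    y = np.array([2.0, 4.0, 5.0])
    table = pd.DataFrame(
        {"condition": ["HL"] * 3, "delta_log2_enrichment": x, "delta_log2_expression": y}
    )
    expected = ((x - x.mean()) @ (y - y.mean())) / np.sqrt(
        ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
    )
    assert ch.delta_correlation(table)["HL"] == pytest.approx(expected)


def test_delta_correlation_zero_variance_is_nan():
    table = pd.DataFrame(
        {
            "condition": ["HL"] * 3,
            "delta_log2_enrichment": [1.0, 1.0, 1.0],
            "delta_log2_expression": [1.0, 2.0, 3.0],
        }
    )
    assert np.isnan(ch.delta_correlation(table)["HL"])


def test_delta_correlation_requires_three_pairs():
    table = pd.DataFrame(
        {"condition": ["HL"] * 2, "delta_log2_enrichment": [1.0, 2.0], "delta_log2_expression": [1.0, 2.0]}
    )
    with pytest.raises(ValueError):
        ch.delta_correlation(table)
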