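"""ChIP signal smoothing, fold-enrichment peak calling, and rule-based
assignment of peaks to promoter-proximal target genes.

Per-base ChIP and mock-IP coverage is smoothed with a truncated
Gaussian kernel (window 400 bp, sd 50 bp). Peaks are maximal runs of
positions where smoothed ChIP / smoothed mock reaches the fold
threshold (default 3.5), kept only if detected in both replicates
(>= 1 bp interval overlap). The enrichment of a peak at any time point
is the smoothed ChIP over smoothed mock ratio at the peak summit.

A gene is a target of a peak iff (i) its start codon lies within 500 bp
of the summit, (ii) the summit is upstream (5') of the start codon on
the gene's strand, and (iii) the gene is the closest gene to the peak
among genes on that strand. A peak may thus target one gene per strand
(divergent promoters). Coordinates are 0-based internally; distances
wrap on circular genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "SignalTrack",
    "Peak",
    "PeakGeneLink",
    "Gene",
    "GeneAnnotation",
    "smooth_track",
    "floor_mock",
    "call_peaks",
    "replicate_consistent_peaks",
    "quantify_peaks",
    "assign_peak_targets",
    "enrichment_change_table",
    "delta_correlation",
]

logger = logging.getLogger(__name__)

FOLD_THRESHOLD = 3.5
LINK_MAX_DISTANCE_BP = 500
SMOOTH_WINDOW_BP = 400
SMOOTH_SD_BP = 50
MIN_PEAK_WIDTH_BP = 50
MOCK_FLOOR_QUANTILE = 0.05


@dataclass
class SignalTrack:
    """Per-base nonnegative genomic signal."""

    values: np.ndarray
    circular: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal values must be finite")
        if np.any(self.values < 0):
            raise ValueError("signal values must be nonnegative")

    @property
    def genome_length(self) -> int:
        return self.values.size


@dataclass
class Peak:
    """An enrichment peak: half-open interval with summit and enrichment.

    For peaks wrapping the origin of a circular genome ``end`` may
    exceed the genome length (interval taken modulo L); ``summit`` is
    always in [0, L).
    """

    start: int
    end: int
    summit: int
    enrichment: float
    enrichment_by_timepoint: dict = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    strand: str

    @property
    def start_codon0(self) -> int:
        """0-based position of the start codon's first base."""
        return self.start - 1 if self.strand == "+" else self.end - 1


@dataclass
class GeneAnnotation:
    genes: list[Gene]
    genome_length: int
    circular: bool = True

    def by_strand(self, strand: str) -> list[Gene]:
        return [g for g in self.genes if g.strand == strand]


@dataclass(frozen=True)
class PeakGeneLink:
    peak: Peak
    gene_id: str
    distance: int
    strand: str


# ---------------------------------------------------------------------------
# Signal processing


def _gaussian_kernel(window_bp: int, sd_bp: float) -> np.ndarray:
    if sd_bp <= 0:
        raise ValueError("sd_bp must be positive")
    radius = window_bp // 2
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sd_bp) ** 2)
    return k / k.sum()


def smooth_track(track: SignalTrack, window_bp: int = SMOOTH_WINDOW_BP, sd_bp: float = SMOOTH_SD_BP) -> SignalTrack:
    """Convolve with a unit-mass truncated Gaussian kernel.

    Wraps around the origin on circular genomes, reflects at the edges
    otherwise. Total signal is conserved on circular genomes.
    """
    kernel = _gaussian_kernel(window_bp, sd_bp)
    mode = "wrap" if track.circular else "reflect"
    smoothed = ndimage.convolve1d(track.values, kernel, mode=mode)
    return SignalTrack(np.maximum(smoothed, 0.0), track.circular)


def floor_mock(mock: SignalTrack, quantile: float = MOCK_FLOOR_QUANTILE) -> SignalTrack:
    """Raise mock values below the q-th percentile of nonzero mock signal.

    Ratios against near-zero mock are unstable; the floor regularizes
    them without touching well-covered positions.
    """
    nonzero = mock.values[mock.values > 0]
    if nonzero.size == 0:
        raise ValueError("mock track is identically zero; enrichment undefined")
    floor = float(np.quantile(nonzero, quantile))
    return SignalTrack(np.maximum(mock.values, floor), mock.circular)


def _threshold_runs(above: np.ndarray, circular: bool) -> list[tuple[int, int]]:
    """Maximal runs of True, merging a wrap-around run on circular genomes."""
    n = above.size
    if above.all():
        return [(0, n)]
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs = list(zip(starts.tolist(), ends.tolist()))
    if circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == n:
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], n + first[1])]
    return runs


def call_peaks(
    ip: SignalTrack,
    mock: SignalTrack,
    fold_threshold: float = FOLD_THRESHOLD,
    min_width_bp: int = MIN_PEAK_WIDTH_BP,
    normalize_totals: bool = True,
    floor_quantile: float = MOCK_FLOOR_QUANTILE,
) -> list[Peak]:
    """Call peaks as runs of >= fold_threshold smoothed IP/mock ratio.

    Both tracks are expected smoothed. IP is library-size scaled to the
    mock total (``normalize_totals``), the mock is floored at its 5th
    percentile of nonzero signal, and maximal runs of ratio >=
    ``fold_threshold`` that are at least ``min_width_bp`` wide become
    peaks. The summit is the leftmost argmax of the IP signal within the
    run; peak enrichment is the IP/mock ratio at the summit.
    """
    if ip.genome_length != mock.genome_length:
        raise ValueError(
            f"genome length mismatch: ip {ip.genome_length} vs mock {mock.genome_length}"
        )
    ip_vals = ip.values
    if normalize_totals and ip_vals.sum() > 0:
        ip_vals = ip_vals * (mock.values.sum() / ip_vals.sum())
    mock_vals = floor_mock(mock, floor_quantile).values
    ratio = ip_vals / mock_vals
    n = ip.genome_length
    peaks: list[Peak] = []
    for start, end in _threshold_runs(ratio >= fold_threshold, ip.circular):
        if end - start < min_width_bp:
            continue
        idx = np.arange(start, end) % n
        summit = int(idx[np.argmax(ip_vals[idx])])
        peaks.append(Peak(start, end, summit, float(ratio[summit])))
    return peaks


def _interval_positions(peak: Peak, n: int) -> np.ndarray:
    return np.arange(peak.start, peak.end) % n


def replicate_consistent_peaks(
    peaks_rep1: Sequence[Peak], peaks_rep2: Sequence[Peak], genome_length: int | None = None
) -> list[Peak]:
    """Keep replicate-1 peaks whose interval overlaps a replicate-2 peak.

    One base pair of overlap suffices; reported coordinates are the
    replicate-1 intervals. ``genome_length`` enables wrap-aware overlap
    for origin-spanning peaks (inferred from intervals if omitted).
    """
    if genome_length is None:
        upper = [p.end for p in list(peaks_rep1) + list(peaks_rep2)]
        genome_length = max(upper, default=1)
    kept = []
    sets2 = [set(_interval_positions(p, genome_length).tolist()) for p in peaks_rep2]
    for p1 in peaks_rep1:
        pos1 = set(_interval_positions(p1, genome_length).tolist())
        if any(pos1 & s2 for s2 in sets2):
            kept.append(p1)
    return kept


def quantify_peaks(
    peaks: Sequence[Peak],
    ip_by_timepoint: Mapping,
    mock_by_timepoint: Mapping,
    normalize_totals: bool = True,
    floor_quantile: float = MOCK_FLOOR_QUANTILE,
) -> list[Peak]:
    """Fill ``enrichment_by_timepoint`` as summit IP/mock per time point.

    Both mappings go time point key -> *smoothed* SignalTrack.
    """
    for key in ip_by_timepoint:
        if key not in mock_by_timepoint:
            raise ValueError(f"mock track missing for time point {key!r}")
        ip = ip_by_timepoint[key]
        ip_vals = ip.values
        if normalize_totals and ip_vals.sum() > 0:
            ip_vals = ip_vals * (mock_by_timepoint[key].values.sum() / ip_vals.sum())
        mock_vals = floor_mock(mock_by_timepoint[key], floor_quantile).values
        for p in peaks:
            p.enrichment_by_timepoint[key] = float(ip_vals[p.summit] / mock_vals[p.summit])
    return list(peaks)


# ---------------------------------------------------------------------------
# Peak-to-gene assignment


def _circular_distance(a: int, b: int, n: int, circular: bool) -> int:
    d = abs(a - b)
    return min(d, n - d) if circular else d


def _upstream_offset(summit: int, gene: Gene, n: int, circular: bool) -> int | None:
    """bp from the summit to the start codon going 5'->3'; None if downstream."""
    sc = gene.start_codon0
    if gene.strand == "+":
        off = (sc - summit) % n if circular else sc - summit
    else:
        off = (summit - sc) % n if circular else summit - sc
    if off < 0 or (circular and off > n // 2):
        return None
    return int(off)


def assign_peak_targets(
    peaks: Sequence[Peak],
    annotation: GeneAnnotation,
    max_distance_bp: int = LINK_MAX_DISTANCE_BP,
) -> list[PeakGeneLink]:
    """Assign each peak its promoter target gene(s) by the three rules.

    For each strand independently: the candidate is the gene whose
    start codon is closest to the summit among all genes on that
    strand; it is linked iff that distance is at most
    ``max_distance_bp`` and the summit lies upstream of the start
    codon. At most one gene per strand per peak.
    """
    n = annotation.genome_length
    links: list[PeakGeneLink] = []
    for g in annotation.genes:
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene {g.gene_id!r} lacks a strand")
    for peak in peaks:
        for strand in ("+", "-"):
            genes = annotation.by_strand(strand)
            if not genes:
                continue
            nearest = min(
                genes,
                key=lambda g: (
                    _circular_distance(peak.summit, g.start_codon0, n, annotation.circular),
                    g.start,
                ),
            )
            d = _circular_distance(peak.summit, nearest.start_codon0, n, annotation.circular)
            if d > max_distance_bp:
                continue
            off = _upstream_offset(peak.summit, nearest, n, annotation.circular)
            if off is None or off > max_distance_bp:
                continue
            links.append(PeakGeneLink(peak, nearest.gene_id, int(off), strand))
    return links


# ---------------------------------------------------------------------------
# Enrichment-change vs expression-change analysis


def enrichment_change_table(
    links: Sequence[PeakGeneLink],
    log2_expression: pd.DataFrame,
    comparisons: Sequence[tuple[float, float, str]],
) -> pd.DataFrame:
    """Per peak-gene pair, paired log2 changes of enrichment and expression.

    ``log2_expression`` is a genes x (condition, time_h) frame on the
    log2 scale. ``comparisons`` lists (t, t0, condition); the peak's
    enrichment_by_timepoint must hold values keyed by (condition, t).
    """
    rows = []
    for t, t0, condition in comparisons:
        for link in links:
            e = link.peak.enrichment_by_timepoint
            for key in ((condition, t), (condition, t0)):
                if key not in e:
                    raise ValueError(f"enrichment missing for time point {key!r}")
            for key in ((condition, t), (condition, t0)):
                if key not in log2_expression.columns:
                    raise ValueError(f"expression missing for time point {key!r}")
            d_enrich = float(np.log2(e[(condition, t)] / e[(condition, t0)]))
            d_expr = float(
                log2_expression.loc[link.gene_id, (condition, t)]
                - log2_expression.loc[link.gene_id, (condition, t0)]
            )
            rows.append(
                {
                    "gene_id": link.gene_id,
                    "condition": condition,
                    "t": t,
                    "t0": t0,
                    "delta_log2_enrichment": d_enrich,
                    "delta_log2_expression": d_expr,
                }
            )
    return pd.DataFrame(rows)


def delta_correlation(table: pd.DataFrame) -> dict[str, float]:
    """Pearson r of enrichment change vs expression change, per condition.

    Returns NaN (with a warning) for a condition where either column has
    zero variance; requires at least 3 pairs per condition.
    """
    out: dict[str, float] = {}
    for condition, sub in table.groupby("condition"):
        x = sub["delta_log2_enrichment"].to_numpy()
        y = sub["delta_log2_expression"].to_numpy()
        if x.size < 3:
            raise ValueError(f"need >= 3 pairs for condition {condition!r}, got {x.size}")
        if np.std(x) == 0 or np.std(y) == 0:
            logger.warning("correlation undefined (zero variance) for condition %r", condition)
            out[str(condition)] = float("nan")
            continue
        out[str(condition)] = float(stats.pearsonr(x, y).statistic)
    return out
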