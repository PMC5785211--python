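"""Expression normalization, cosinor rhythm fitting, circadian
classification, and correlation-distance clustering of dusk genes.

The workflow mirrors a circadian RNA-seq analysis in *S. elongatus*:

1. :func:`normalize_counts` — per-sample median normalization followed
   by division by ORF length (reads per nucleotide).
2. :func:`log2_relative_expression` — log2 fold change of each gene
   against its mean expression in a reference condition.
3. :func:`cosinor_fit` — classical single-component cosinor (linear
   least squares on a 24-h sin/cos basis) giving mesor, amplitude and
   acrophase.
4. :func:`classify_circadian` — dawn/dusk/non-circadian labels from an
   amplitude threshold, acrophase windows (dawn 40-189 degrees, dusk
   190-360 and 0-39 degrees) and a one-read-per-nucleotide expression
   filter.
5. :func:`zscore_block_normalize` + :func:`kmeans_correlation` —
   k-means with Pearson correlation distance on block-z-scored
   profiles; :func:`name_clusters_by_activation` names the three
   largest clusters Early/Middle/Late by activation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CosinorResult",
    "normalize_counts",
    "log2_relative_expression",
    "cosinor_fit",
    "cosinor_fit_frame",
    "classify_circadian",
    "zscore_block_normalize",
    "kmeans_correlation",
    "KMeansResult",
    "name_clusters_by_activation",
    "scale_unit_interval",
    "cluster_means",
]

logger = logging.getLogger(__name__)

DAWN_WINDOW_DEG = (40.0, 189.0)
DUSK_WINDOW_DEG = ((190.0, 360.0), (0.0, 39.0))
AMPLITUDE_THRESHOLD = 0.15
EXPRESSION_FILTER_READS_PER_NT = 1.0


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with (condition, time) sample metadata.

    ``values``: DataFrame indexed by gene_id with a two-level column
    MultiIndex (condition, time_h); entries are nonnegative (raw counts
    or normalized units). ``gene_lengths``: ORF length in nucleotides.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values.columns, pd.MultiIndex) or self.values.columns.nlevels != 2:
            raise ValueError("columns must be a (condition, time_h) MultiIndex")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.gene_lengths is not None:
            missing = self.values.index.difference(self.gene_lengths.index)
            if len(missing):
                raise ValueError(f"gene_lengths missing for {len(missing)} genes")
            if (self.gene_lengths.loc[self.values.index] <= 0).any():
                raise ValueError("gene_lengths must be positive")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    def condition_frame(self, condition: str) -> pd.DataFrame:
        """Genes x time_h sub-frame for one condition."""
        if condition not in self.conditions:
            raise ValueError(f"condition {condition!r} not present; have {self.conditions}")
        return self.values[condition]


def normalize_counts(raw: ExpressionMatrix) -> ExpressionMatrix:
    """Median-normalize samples, then divide by ORF length.

    Each sample is rescaled so that its median count — over the genes
    with nonzero counts in *every* sample — equals the grand median
    (the median of the per-sample medians). The rescaled counts are then
    divided by each gene's ORF length, giving normalized reads per
    nucleotide.
    """
    if raw.gene_lengths is None:
        raise ValueError("normalize_counts requires gene_lengths")
    counts = raw.values
    zero_samples = counts.columns[(counts == 0).all(axis=0)]
    if len(zero_samples):
        raise ValueError(f"sample(s) with all-zero counts: {list(zero_samples)}")
    everywhere_nonzero = (counts > 0).all(axis=1)
    if not everywhere_nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples; median scale undefined")
    medians = counts.loc[everywhere_nonzero].median(axis=0)
    grand = float(np.median(medians.to_numpy()))
    scaled = counts * (grand / medians)
    per_nt = scaled.div(raw.gene_lengths.loc[counts.index], axis=0)
    return ExpressionMatrix(per_nt, raw.gene_lengths)


def log2_relative_expression(
    expr: ExpressionMatrix | pd.DataFrame,
    reference_condition: str,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """log2 of expression over the gene's mean in the reference condition.

    The pseudocount defaults to half the smallest nonzero value in the
    matrix and is applied symmetrically to numerator and denominator.
    """
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    conditions = values.columns.get_level_values(0)
    if reference_condition not in set(conditions):
        raise ValueError(f"reference condition {reference_condition!r} not present")
    if pseudocount is None:
        arr = values.to_numpy()
        nonzero = arr[arr > 0]
        pseudocount = float(nonzero.min()) / 2.0 if nonzero.size else 0.0
    ref_mean = values.loc[:, values.columns.get_level_values(0) == reference_condition].mean(axis=1)
    return np.log2(values.add(pseudocount)).sub(np.log2(ref_mean + pseudocount), axis=0)


@dataclass(frozen=True)
class CosinorResult:
    """Single-component cosinor fit of a 24-h rhythm.

    ``amplitude`` is half the fitted peak-to-trough range (input units);
    ``acrophase_deg`` maps the fitted peak time to degrees, 0 at dawn
    (360 * t_peak / period), in [0, 360).
    """

    mesor: float
    amplitude: float
    acrophase_deg: float


def cosinor_fit(times: Sequence[float], values: Sequence[float], period_h: float = 24.0) -> CosinorResult:
    """Least-squares fit of ``mesor + a*cos(wt) + b*sin(wt)``."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and values must match in length")
    if np.unique(t).size < 3:
        raise ValueError("cosinor fit requires at least 3 distinct time points")
    w = 2.0 * np.pi / period_h
    basis = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
    mesor, a, b = coef
    amplitude = float(np.hypot(a, b))
    acrophase = float(np.degrees(np.arctan2(b, a)) % 360.0)
    return CosinorResult(float(mesor), amplitude, acrophase)


def cosinor_fit_frame(frame: pd.DataFrame, period_h: float = 24.0) -> pd.DataFrame:
    """Row-wise cosinor fits of a genes x time_h frame.

    Returns a DataFrame with columns mesor, amplitude, acrophase_deg.
    """
    t = np.asarray(frame.columns, dtype=float)
    if np.unique(t).size < 3:
        raise ValueError("cosinor fit requires at least 3 distinct time points")
    w = 2.0 * np.pi / period_h
    basis = np.column_stack([np.ones_like(t), np.cos(w * t), np.sin(w * t)])
    coef, *_ = np.linalg.lstsq(basis, frame.to_numpy().T, rcond=None)
    mesor, a, b = coef
    return pd.DataFrame(
        {
            "mesor": mesor,
            "amplitude": np.hypot(a, b),
            "acrophase_deg": np.degrees(np.arctan2(b, a)) % 360.0,
        },
        index=frame.index,
    )


def _in_window(phase: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (phase >= lo) & (phase <= hi)


def classify_circadian(
    fits: pd.DataFrame,
    expr: ExpressionMatrix,
    amplitude_threshold: float = AMPLITUDE_THRESHOLD,
) -> pd.DataFrame:
    """Label genes dawn / dusk / non_circadian.

    ``fits`` must carry ``amplitude`` and ``acrophase_deg`` per gene
    (cosinor fits of log2-scale constant-light or Low Light series);
    ``expr`` must be in normalized reads per nucleotide. A gene passes
    the expression filter iff it reaches at least one read per
    nucleotide in at least one sample. Dawn requires amplitude above
    threshold plus acrophase in [40, 189] degrees; dusk the complementary
    printed window [190, 360) and [0, 39].
    """
    missing = fits.index.difference(expr.values.index)
    if len(missing):
        raise ValueError(f"genes present in fits but absent from expression: {list(missing)[:5]}")
    sub = expr.values.loc[fits.index]
    passed = (sub >= EXPRESSION_FILTER_READS_PER_NT).any(axis=1)
    amp = fits["amplitude"].to_numpy()
    phase = fits["acrophase_deg"].to_numpy() % 360.0
    rhythmic = amp > amplitude_threshold
    dawn = rhythmic & _in_window(phase, *DAWN_WINDOW_DEG)
    dusk = rhythmic & (
        ((phase >= DUSK_WINDOW_DEG[0][0]) & (phase < DUSK_WINDOW_DEG[0][1]))
        | _in_window(phase, *DUSK_WINDOW_DEG[1])
    )
    label = np.where(passed & dawn, "dawn", np.where(passed & dusk, "dusk", "non_circadian"))
    return pd.DataFrame(
        {
            "amplitude": amp,
            "acrophase_deg": phase,
            "passed_expression_filter": passed.to_numpy(),
            "label": label,
        },
        index=fits.index,
    )


def zscore_block_normalize(
    matrix: pd.DataFrame,
    blocks: Mapping[str, Sequence] ,
) -> tuple[pd.DataFrame, list]:
    """Z-score each gene row within each sample block, then concatenate.

    ``blocks`` maps block name -> list of columns. Uses the sample
    standard deviation (ddof=1). Genes with zero variance inside any
    block are dropped from the output and returned as the second element
    (they carry no shape information for correlation clustering).
    """
    pieces = []
    degenerate: set = set()
    for name, cols in blocks.items():
        cols = list(cols)
        if len(cols) < 2:
            raise ValueError(f"block {name!r} needs at least 2 samples")
        sub = matrix[cols]
        sd = sub.std(axis=1, ddof=1)
        zero = sd[sd == 0].index
        degenerate.update(zero)
        pieces.append(sub.sub(sub.mean(axis=1), axis=0).div(sd.replace(0, np.nan), axis=0))
    out = pd.concat(pieces, axis=1)
    keep = out.index.difference(degenerate)
    if degenerate:
        logger.warning(
            "excluding %d gene(s) with zero variance within a block: %s",
            len(degenerate),
            sorted(degenerate)[:10],
        )
    return out.loc[keep], sorted(degenerate)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm (correlation geometry)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("row with zero variance cannot be clustered with correlation distance")
    return Xc / norms


@dataclass
class KMeansResult:
    """Correlation-distance k-means labels (1-based) plus diagnostics."""

    assignments: pd.Series
    inertia: float
    k: int
    seed: int
    n_restarts: int

    def sizes(self) -> pd.Series:
        return self.assignments.value_counts().sort_values(ascending=False)


def _kmeans_once(Xh: np.ndarray, k: int, rng: np.random.Generator, max_iter: int) -> tuple[np.ndarray, float]:
    n = Xh.shape[0]
    centroids = Xh[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        sim = Xh @ centroids.T  # correlation; distance = 1 - sim
        new_labels = np.argmax(sim, axis=1)
        d_min = 1.0 - sim[np.arange(n), new_labels]
        for j in range(k):
            members = new_labels == j
            if not members.any():
                # re-seed an empty centroid from the farthest point
                far = int(np.argmax(d_min))
                centroids[j] = Xh[far]
                new_labels[far] = j
                members = new_labels == j
            c = Xh[members].mean(axis=0)
            c = c - c.mean()
            norm = np.linalg.norm(c)
            centroids[j] = Xh[members][0] if norm == 0 else c / norm
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    sim = Xh @ centroids.T
    labels = np.argmax(sim, axis=1)
    inertia = float(np.sum(1.0 - sim[np.arange(n), labels]))
    return labels, inertia


def kmeans_correlation(
    matrix: pd.DataFrame,
    k: int = 8,
    n_restarts: int = 50,
    seed: int = 0,
    max_iter: int = 100,
) -> KMeansResult:
    """K-means with Pearson correlation distance d(x, c) = 1 - r(x, c).

    Centroids are the member mean re-standardized to zero mean and unit
    norm (the correlation-distance convention). The best of
    ``n_restarts`` seeded restarts (lowest total within-cluster
    distance) is returned; labels are 1-based.
    """
    if k > matrix.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({matrix.shape[0]})")
    Xh = _standardize_rows(matrix.to_numpy(dtype=float))
    rng = np.random.default_rng(seed)
    best_labels, best_inertia = None, np.inf
    for _ in range(n_restarts):
        labels, inertia = _kmeans_once(Xh, k, rng, max_iter)
        if inertia < best_inertia:
            best_labels, best_inertia = labels, inertia
    assignments = pd.Series(best_labels + 1, index=matrix.index, name="cluster_index")
    return KMeansResult(assignments, best_inertia, k, seed, n_restarts)


def _first_crossing_time(times: np.ndarray, values: np.ndarray, level: float = 0.5) -> float:
    """First time a 0-1 series crosses ``level``, linearly interpolated."""
    above = values >= level
    if above[0]:
        return float(times[0])
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return float(times[-1]) + 1.0  # never activates within the window
    i = idx[0]
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    return float(t0 + (level - v0) / (v1 - v0) * (t1 - t0))


def name_clusters_by_activation(
    assignments: pd.Series,
    low_light_cluster_means: Mapping[int, tuple[np.ndarray, np.ndarray]],
    names: Sequence[str] = ("Early", "Middle", "Late"),
) -> pd.Series:
    """Name the three largest clusters by activation order under Low Light.

    ``low_light_cluster_means`` maps cluster index -> (times, 0-1 scaled
    mean trajectory). The largest three clusters are named in increasing
    order of the first time their scaled Low Light mean crosses 0.5;
    remaining clusters are named "other". Size ties for third place are
    broken toward earlier activation (with a warning).
    """
    sizes = assignments.value_counts()
    crossing = {
        int(c): _first_crossing_time(np.asarray(t, dtype=float), np.asarray(v, dtype=float))
        for c, (t, v) in low_light_cluster_means.items()
    }
    order = sorted(sizes.index, key=lambda c: (-sizes[c], crossing.get(int(c), np.inf)))
    n_major = min(len(names), len(order))
    if len(order) > n_major and sizes[order[n_major - 1]] == sizes[order[n_major]]:
        logger.warning("cluster size tie at rank %d broken by earlier activation time", n_major)
    major = sorted(order[:n_major], key=lambda c: crossing.get(int(c), np.inf))
    mapping = {int(c): names[i] for i, c in enumerate(major)}
    return pd.Series(
        {int(c): mapping.get(int(c), "other") for c in sizes.index}, name="cluster_name"
    )


def scale_unit_interval(series: Mapping[str, np.ndarray] | np.ndarray):
    """Scale to [0, 1] with min/max pooled over all conditions.

    Accepts either a plain array or a mapping condition -> array (the
    joint-scaling case used for cluster means and regulator levels).
    Raises on a constant series (zero range).
    """
    if isinstance(series, Mapping):
        pooled = np.concatenate([np.asarray(v, dtype=float).ravel() for v in series.values()])
        lo, hi = float(pooled.min()), float(pooled.max())
        if hi == lo:
            raise ValueError("cannot scale a constant series to the unit interval")
        return {k: (np.asarray(v, dtype=float) - lo) / (hi - lo) for k, v in series.items()}
    arr = np.asarray(series, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise ValueError("cannot scale a constant series to the unit interval")
    return (arr - lo) / (hi - lo)


def cluster_means(matrix: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Mean row per cluster (clusters x samples), preserving column structure."""
    common = matrix.index.intersection(assignments.index)
    return matrix.loc[common].groupby(assignments.loc[common]).mean()
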