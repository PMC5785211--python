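"""Synthetic-data generators for every pipeline input.

Generates, under a seeded RNG, the statistical structure the analysis
assumes: diel light profiles, regulator phosphorylation series, dusk
cluster trajectories forward-simulated from the reference Hill AND-gate
parameter sets, gene-level count matrices with planted cosinor rhythms,
and per-base ChIP / mock tracks with planted enrichment summits. Every
generator is a pure function of (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import model as mdl
from .chip import SignalTrack
from .expression import scale_unit_interval
from .light import CONDITIONS, LightProfile, make_light_profile
from .params import BEST_FEEDBACK_VARIANT
from .regulators import RegulatorTrajectory, make_regulator_trajectories

__all__ = [
    "SyntheticScenario",
    "SyntheticStudy",
    "make_cluster_expression",
    "make_dusk_dataset",
    "make_gene_counts",
    "make_cluster_profiles",
    "make_chip_tracks",
]

#: Genome used for fixture annotations: order of the S. elongatus
#: chromosome; coordinates wrap.
GENOME_LENGTH_BP = 2_700_000

#: Default measurement times (hours after dawn): a 2-h grid over the
#: light period plus the 15-min and 60-min marks after the hour-8 pulse
#: onset, matching how the pulse responses are sampled.
DEFAULT_SAMPLING_TIMES = (0.0, 2.0, 4.0, 6.0, 8.0, 8.25, 9.0, 10.0, 11.0, 12.0)


@dataclass(frozen=True)
class SyntheticScenario:
    """Study-level knobs shared by the generators."""

    seed: int = 0
    noise_sd: float = 0.05  # additive Gaussian sd on 0-1 normalized expression
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        st = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(st) <= 0):
            raise ValueError("sampling_times must be strictly increasing")
        if st[0] < 0 or st[-1] > 12:
            raise ValueError("sampling_times must lie within [0, 12] hours")


def make_cluster_expression(
    scenario: SyntheticScenario,
    spec: mdl.ClusterModelSpec,
    params: mdl.ClusterModelParams,
    regulators: Mapping[str, Mapping[str, RegulatorTrajectory]],
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Noisy observed trajectory of one cluster per condition.

    The clean trajectory is the Hill AND-gate ODE forward simulation at
    ``scenario.sampling_times`` (each condition started from its own
    production/decay quasi-steady state); i.i.d. Gaussian noise of sd
    ``scenario.noise_sd`` is added and the result clipped at zero.
    """
    params.validate(spec)
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    times = np.asarray(scenario.sampling_times)
    out = {}
    for cond, regs in regulators.items():
        clean = _simulate_condition(spec, params, regs, times)
        noisy = clean + rng.normal(0.0, scenario.noise_sd, clean.shape)
        out[cond] = np.maximum(noisy, 0.0)
    return out


def _quasi_steady_x0(spec, params, regs, t0: float) -> float:
    inputs = {name: np.asarray(regs[name].at(t0)) for name in spec.input_names}
    production = float(mdl._production(params, spec, inputs))
    return production / params.alpha if params.alpha > 0 else 0.0


def _simulate_condition(spec, params, regs, times) -> np.ndarray:
    x0 = _quasi_steady_x0(spec, params, regs, float(times[0]))
    return mdl.simulate_cluster(params, spec, regs, times, X0=x0)


@dataclass
class SyntheticStudy:
    """A full synthetic dusk-cluster study.

    ``regulators_norm``: condition -> {"RpaA", "RpaB"} 0-1 trajectories
    at the sampling times. ``cluster_obs``: cluster -> condition ->
    noisy 0-1 observations. ``feedback_inputs``: cluster -> condition
    -> the 0-1 source-cluster trajectory used as its measured feedback
    input Y. ``truth`` records the generating variant and parameters.
    """

    scenario: SyntheticScenario
    lights: dict[str, LightProfile]
    regulators_norm: dict[str, dict[str, RegulatorTrajectory]]
    cluster_obs: dict[str, dict[str, np.ndarray]]
    cluster_clean: dict[str, dict[str, np.ndarray]]
    feedback_inputs: dict[str, dict[str, RegulatorTrajectory]]
    truth: dict[str, dict]

    @property
    def sampling_times(self) -> np.ndarray:
        return np.asarray(self.scenario.sampling_times)

    def fit_inputs(self, cluster: str) -> dict[str, dict[str, RegulatorTrajectory]]:
        """Per-condition driver dict (RpaA, RpaB, feedback source) for refitting."""
        out: dict[str, dict[str, RegulatorTrajectory]] = {}
        for cond, regs in self.regulators_norm.items():
            d = dict(regs)
            if cluster in self.feedback_inputs:
                y = self.feedback_inputs[cluster][cond]
                d[y.name] = y
            out[cond] = d
        return out

    def fit_data(self, cluster: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        t = self.sampling_times
        return {cond: (t, obs) for cond, obs in self.cluster_obs[cluster].items()}


def _normalized_regulators(scenario: SyntheticScenario) -> tuple[dict, dict]:
    """Raw regulator series sampled at scenario times, 0-1 scaled jointly."""
    lights = {c: make_light_profile(c) for c in CONDITIONS}
    times = np.asarray(scenario.sampling_times)
    raw_a, raw_b = {}, {}
    for cond, light in lights.items():
        a, b = make_regulator_trajectories(light)
        raw_a[cond] = np.asarray(a.at(times))
        raw_b[cond] = np.asarray(b.at(times))
    norm_a = scale_unit_interval(raw_a)
    norm_b = scale_unit_interval(raw_b)
    regulators = {
        cond: {
            "RpaA": RegulatorTrajectory("RpaA", times, norm_a[cond]),
            "RpaB": RegulatorTrajectory("RpaB", times, norm_b[cond]),
        }
        for cond in lights
    }
    return lights, regulators


def make_dusk_dataset(scenario: SyntheticScenario | None = None) -> SyntheticStudy:
    """Generate the three dusk-cluster time courses across all conditions.

    Drivers are the normalized RpaA~P / RpaB~P series. Clusters are
    forward-simulated from the reference best-fit parameter sets with
    the measured-feedback scheme: the Late cluster is first simulated
    with its joint (no-feedback) parameters to provide a measured Y
    series; Early (repressed by Late) and Middle (activated by Late)
    are simulated against it; Late is then regenerated from its
    feedback variant with the Middle series as Y. Each cluster's clean
    trajectories are 0-1 scaled jointly across the four conditions;
    seeded Gaussian noise (sd ``scenario.noise_sd``) gives the
    observations.
    """
    scenario = scenario or SyntheticScenario()
    lights, regulators = _normalized_regulators(scenario)
    times = np.asarray(scenario.sampling_times)
    rng = np.random.default_rng(scenario.seed)

    def simulate_scaled(variant: str, cluster: str, y_traj: Mapping[str, RegulatorTrajectory] | None):
        spec = mdl.spec_from_variant(variant, cluster)
        _, params = mdl.params_from_reference(variant, cluster)
        clean = {}
        for cond, regs in regulators.items():
            drivers = dict(regs)
            if y_traj is not None:
                drivers[spec.feedback[0]] = y_traj[cond]
            clean[cond] = _simulate_condition(spec, params, drivers, times)
        return spec, params, scale_unit_interval(clean)

    def as_traj(name: str, scaled: Mapping[str, np.ndarray]) -> dict[str, RegulatorTrajectory]:
        return {cond: RegulatorTrajectory(name, times, v) for cond, v in scaled.items()}

    # Stage 1: a measured Late series from the joint model.
    _, _, late_seed_scaled = simulate_scaled("joint", "Late", None)
    y_late = as_traj("Late", late_seed_scaled)

    truth: dict[str, dict] = {}
    clean: dict[str, dict[str, np.ndarray]] = {}
    feedback_inputs: dict[str, dict[str, RegulatorTrajectory]] = {}

    for cluster in ("Early", "Middle"):
        variant = BEST_FEEDBACK_VARIANT[cluster]
        spec, params, scaled = simulate_scaled(variant, cluster, y_late)
        clean[cluster] = scaled
        feedback_inputs[cluster] = y_late
        truth[cluster] = {"variant": variant, "spec": spec, "params": params}

    y_middle = as_traj("Middle", clean["Middle"])
    variant = BEST_FEEDBACK_VARIANT["Late"]
    spec, params, scaled = simulate_scaled(variant, "Late", y_middle)
    clean["Late"] = scaled
    feedback_inputs["Late"] = y_middle
    truth["Late"] = {"variant": variant, "spec": spec, "params": params}

    obs = {
        cluster: {
            cond: np.maximum(v + rng.normal(0.0, scenario.noise_sd, v.shape), 0.0)
            for cond, v in scaled.items()
        }
        for cluster, scaled in clean.items()
    }
    return SyntheticStudy(
        scenario=scenario,
        lights=lights,
        regulators_norm=regulators,
        cluster_obs=obs,
        cluster_clean=clean,
        feedback_inputs=feedback_inputs,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Gene-level counts with planted cosinor rhythms


def _planted_acrophase(rng: np.random.Generator, label: str) -> float:
    # Margins keep planted phases away from the 39/40 and 189/190
    # class boundaries so truth is unambiguous under count noise.
    if label == "dawn":
        return float(rng.uniform(50.0, 180.0))
    hi = rng.random() < (150.0 / 180.0)  # dusk window split 200-350 vs 0-30
    return float(rng.uniform(200.0, 350.0)) if hi else float(rng.uniform(0.0, 30.0))


def make_gene_counts(
    n_genes: int = 200,
    seed: int = 0,
    times_h: Sequence[float] = tuple(np.arange(0.0, 24.0, 2.0)),
    condition: str = "ConstantLight",
    class_fractions: Mapping[str, float] = None,
    low_expressed_fraction: float = 0.05,
    noise_sd: float = 0.05,
    gene_lengths: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.Series, "GeneAnnotation", pd.DataFrame, pd.Series]:
    """Integer count matrix with planted circadian structure.

    Per gene, log2 expression (reads per nucleotide) follows a planted
    cosinor curve ``mesor + A*cos(2*pi*(t - t_peak)/24)`` plus Gaussian
    noise; counts are Poisson draws around the per-nucleotide mean
    times ORF length times a per-sample scale factor (which exercises
    median normalization). A ``low_expressed_fraction`` of genes is
    planted below the one-read-per-nucleotide filter and is therefore
    non-circadian by definition.

    Returns ``(counts, gene_lengths, annotation, truth, scale_factors)``
    where truth records the planted class, amplitude and acrophase, and
    annotation places the genes on a circular chromosome (1-based
    inclusive GFF-style coordinates).
    """
    from .chip import Gene, GeneAnnotation

    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    # Rhythmic genes are a small minority of a real transcriptome (high
    # amplitude circadian genes are ~17% of S. elongatus ORFs, dusk
    # outnumbering dawn). Keeping them so here also prevents the
    # per-sample gene median itself from oscillating, which would leak a
    # common-mode rhythm into every median-normalized gene.
    fractions = dict(class_fractions or {"dawn": 0.07, "dusk": 0.13, "non_circadian": 0.8})
    times = np.asarray(times_h, dtype=float)

    if gene_lengths is None:
        lengths = rng.integers(300, 3001, size=n_genes)
    else:
        lengths = np.asarray(gene_lengths, dtype=int)
        if lengths.size != n_genes or np.any(lengths <= 0):
            raise ValueError("gene_lengths must be positive and match n_genes")

    labels = rng.choice(
        list(fractions), size=n_genes, p=np.array(list(fractions.values())) / sum(fractions.values())
    )
    low = rng.random(n_genes) < low_expressed_fraction

    gene_ids = [f"gene_{i:04d}" for i in range(n_genes)]
    amplitude = np.where(
        labels == "non_circadian", rng.uniform(0.0, 0.05, n_genes), rng.uniform(0.3, 1.2, n_genes)
    )
    acrophase = np.array(
        [
            _planted_acrophase(rng, lab) if lab != "non_circadian" else float(rng.uniform(0, 360))
            for lab in labels
        ]
    )
    mesor = np.where(low, rng.uniform(-4.0, -2.5, n_genes), rng.uniform(0.5, 4.0, n_genes))

    scale = pd.Series(rng.uniform(0.5, 2.0, times.size), index=times, name="scale_factor")
    phase_rad = np.deg2rad(acrophase)
    log2_expr = (
        mesor[:, None]
        + amplitude[:, None] * np.cos(2 * np.pi * times[None, :] / 24.0 - phase_rad[:, None])
        + rng.normal(0.0, noise_sd, (n_genes, times.size))
    )
    mean_counts = (2.0**log2_expr) * lengths[:, None] * scale.to_numpy()[None, :]
    counts = rng.poisson(mean_counts).astype(int)

    columns = pd.MultiIndex.from_tuples([(condition, t) for t in times], names=["condition", "time_h"])
    counts_df = pd.DataFrame(counts, index=gene_ids, columns=columns)
    lengths_s = pd.Series(lengths, index=gene_ids, name="orf_length_nt")

    # Lay genes head-to-tail with 100 bp gaps on a circular chromosome.
    genes = []
    pos = 1000
    for gid, L, strand in zip(gene_ids, lengths, rng.choice(["+", "-"], n_genes)):
        genes.append(Gene(gid, pos, pos + int(L) - 1, str(strand)))
        pos += int(L) + 100
    if pos >= GENOME_LENGTH_BP:
        raise ValueError("too many genes for the fixture chromosome")
    annotation = GeneAnnotation(genes, GENOME_LENGTH_BP, circular=True)

    truth_label = np.where(low, "non_circadian", labels)
    truth = pd.DataFrame(
        {
            "label": truth_label,
            "amplitude": amplitude,
            "acrophase_deg": acrophase,
            "mesor_log2": mesor,
            "low_expressed": low,
        },
        index=gene_ids,
    )
    return counts_df, lengths_s, annotation, truth, scale


def make_cluster_profiles(
    n_genes: int = 60,
    n_clusters: int = 3,
    noise_sd: float = 0.1,
    seed: int = 0,
    times_h: Sequence[float] = tuple(np.arange(0.0, 12.5, 1.0)),
) -> tuple[pd.DataFrame, pd.Series]:
    """Correlation-distinct planted profile groups for clustering tests.

    Each gene is a per-gene affine transform (positive gain, arbitrary
    offset) of its group's base profile plus Gaussian noise — exactly
    the structure Pearson-distance k-means is invariant to.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(times_h, dtype=float)
    peaks = np.linspace(2.0, 12.0, n_clusters)
    base = np.stack([np.cos(2 * np.pi * (times - p) / 24.0) for p in peaks])
    labels = rng.integers(0, n_clusters, size=n_genes)
    gains = rng.uniform(0.5, 2.0, n_genes)
    offsets = rng.uniform(-1.0, 1.0, n_genes)
    data = gains[:, None] * base[labels] + offsets[:, None]
    data = data + rng.normal(0.0, noise_sd, data.shape)
    idx = [f"gene_{i:04d}" for i in range(n_genes)]
    frame = pd.DataFrame(data, index=idx, columns=pd.Index(times, name="time_h"))
    return frame, pd.Series(labels + 1, index=idx, name="planted_cluster")


# ---------------------------------------------------------------------------
# ChIP tracks with planted summits


def make_chip_tracks(
    genome_length: int,
    planted_peaks: Sequence[tuple[int, float, float]],
    background: float = 10.0,
    noise_sd: float = 0.2,
    seed: int = 0,
    n_replicates: int = 2,
    circular: bool = True,
) -> list[tuple[SignalTrack, SignalTrack]]:
    """Per replicate (IP, mock) tracks with Gaussian-shaped enrichment bumps.

    ``planted_peaks`` lists (summit, fold, width_sd_bp): the clean IP
    equals the flat background times ``1 + (fold-1)*exp(-(x-s)^2/(2 w^2))``;
    the mock is the background alone. Independent Gaussian noise is added
    per replicate; replicates share the planted summits. Overlapping
    planted bumps (within 4 summed widths) are rejected to keep fixtures
    unambiguous.
    """
    rng = np.random.default_rng(seed)
    for s, fold, w in planted_peaks:
        if not (0 <= s < genome_length):
            raise ValueError(f"summit {s} outside the genome")
        if fold <= 0:
            raise ValueError("planted fold must be positive")
        if w <= 0:
            raise ValueError("planted width must be positive")
    ordered = sorted(planted_peaks)
    for (s1, _, w1), (s2, _, w2) in zip(ordered, ordered[1:]):
        if s2 - s1 < 4 * (w1 + w2):
            raise ValueError(f"planted peaks at {s1} and {s2} overlap; keep fixtures unambiguous")

    x = np.arange(genome_length, dtype=float)
    enrichment = np.ones(genome_length)
    for s, fold, w in planted_peaks:
        d = np.abs(x - s)
        if circular:
            d = np.minimum(d, genome_length - d)
        enrichment += (fold - 1.0) * np.exp(-0.5 * (d / w) ** 2)
    out = []
    for _ in range(n_replicates):
        mock = background + rng.normal(0.0, noise_sd, genome_length)
        ip = background * enrichment + rng.normal(0.0, noise_sd, genome_length)
        out.append(
            (SignalTrack(np.maximum(ip, 0.0), circular), SignalTrack(np.maximum(mock, 0.0), circular))
        )
    return out
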