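"""End-to-end orchestration: simulate -> classify -> cluster -> chip ->
fit -> compare, with YAML configuration and a reproducibility manifest.

Stage parameters default to the analysis constants used throughout the
package (amplitude threshold 0.15, dawn window 40-189 degrees, fold
threshold 3.5, 500 bp link distance, the fitting bounds box). Every run
writes a resolved copy of its configuration plus a manifest whose
deterministic section (seeds, parameters, output checksums) reproduces
bit-wise on a re-run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip as chip_mod
from . import expression as expr_mod
from . import io as io_mod
from . import model as mdl
from . import synth
from .params import BEST_FEEDBACK_VARIANT, BOUNDS

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for one pipeline run.

    Defaults equal the printed analysis constants; any subset may be
    overridden from YAML. ``stages`` toggles individual stages.
    """

    seed: int = 0
    noise_sd: float = 0.05
    n_genes: int = 200
    amplitude_threshold: float = 0.15
    k_clusters: int = 8
    kmeans_restarts: int = 20
    fold_threshold: float = 3.5
    link_max_distance_bp: int = 500
    n_starts: int = 64
    fit_clusters: tuple[str, ...] = ("Early", "Middle", "Late")
    fit_variants: tuple[str, ...] = ("rpaA_only", "rpaB_only", "joint", "feedback")
    chip_genome_length: int = 60_000
    stages: dict = field(
        default_factory=lambda: {
            "simulate": True,
            "classify": True,
            "cluster": True,
            "chip": True,
            "fit": True,
            "compare": True,
        }
    )

    _KNOWN = None  # populated below

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


PipelineConfig._KNOWN = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config; unknown keys are an error."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = sorted(set(raw) - PipelineConfig._KNOWN)
    if unknown:
        raise ValueError(f"unknown config key(s): {', '.join(unknown)}")
    if "fit_clusters" in raw:
        raw["fit_clusters"] = tuple(raw["fit_clusters"])
    if "fit_variants" in raw:
        raw["fit_variants"] = tuple(raw["fit_variants"])
    if "stages" in raw:
        base = PipelineConfig().stages
        bad = sorted(set(raw["stages"]) - set(base))
        if bad:
            raise ValueError(f"unknown stage(s): {', '.join(bad)}")
        raw["stages"] = base | raw["stages"]
    return PipelineConfig(**raw)


@dataclass
class RunManifest:
    """Provenance record: config hash, seeds, and output checksums."""

    config_hash: str
    seed: int
    stages_run: list[str]
    checksums: dict[str, str]
    created: str

    def deterministic_view(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages_run": self.stages_run,
            "checksums": self.checksums,
        }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> RunManifest:
    """Run the enabled stages in dependency order and write flat files.

    Later stages consume the in-memory results of earlier ones; if an
    upstream stage is toggled off, its dependents that cannot run
    without it raise a ``ValueError`` naming the missing stage (the fit
    and compare stages need only the simulate stage, not chip).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    header = f"config_hash={cfg_hash}"
    stages = config.stages
    written: list[Path] = []
    stages_run: list[str] = []

    (outdir / "resolved_config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )
    written.append(outdir / "resolved_config.yaml")

    scenario = synth.SyntheticScenario(seed=config.seed, noise_sd=config.noise_sd)
    study = counts = lengths = annotation = truth = None

    if stages.get("simulate"):
        stages_run.append("simulate")
        study = synth.make_dusk_dataset(scenario)
        counts, lengths, annotation, truth, _ = synth.make_gene_counts(
            n_genes=config.n_genes, seed=config.seed, noise_sd=config.noise_sd
        )
        counts_em = expr_mod.ExpressionMatrix(counts.astype(float), lengths)
        io_mod.write_expression_tsv(counts_em, outdir / "counts.tsv", header)
        io_mod.write_gff3(annotation, outdir / "genes.gff3", header)
        truth.to_csv(outdir / "truth.tsv", sep="\t")
        cluster_rows = []
        for cluster, per_cond in study.cluster_obs.items():
            for cond, values in per_cond.items():
                for t, v in zip(study.sampling_times, values):
                    cluster_rows.append((cluster, cond, t, v))
        pd.DataFrame(
            cluster_rows, columns=["cluster", "condition", "time_h", "value"]
        ).to_csv(outdir / "cluster_obs.tsv", sep="\t", index=False)
        written += [outdir / "counts.tsv", outdir / "genes.gff3", outdir / "truth.tsv", outdir / "cluster_obs.tsv"]
        logger.info("simulate: %d genes, %d clusters", config.n_genes, len(study.cluster_obs))

    classification = None
    if stages.get("classify"):
        if counts is None:
            raise ValueError("classify stage requires the simulate stage output")
        stages_run.append("classify")
        em = expr_mod.normalize_counts(expr_mod.ExpressionMatrix(counts.astype(float), lengths))
        condition = em.conditions[0]
        log2rel = expr_mod.log2_relative_expression(em, condition)
        fits = expr_mod.cosinor_fit_frame(log2rel[condition])
        classification = expr_mod.classify_circadian(fits, em, config.amplitude_threshold)
        classification.to_csv(outdir / "classification.tsv", sep="\t")
        written.append(outdir / "classification.tsv")
        logger.info(
            "classify: %s", classification["label"].value_counts().to_dict()
        )

    if stages.get("cluster"):
        if classification is None:
            raise ValueError("cluster stage requires the classify stage output")
        stages_run.append("cluster")
        profiles, planted = synth.make_cluster_profiles(
            n_genes=max(3 * config.k_clusters, 60), noise_sd=config.noise_sd, seed=config.seed
        )
        zs, dropped = expr_mod.zscore_block_normalize(
            profiles, {"light_conditions": list(profiles.columns)}
        )
        km = expr_mod.kmeans_correlation(
            zs, k=min(config.k_clusters, zs.shape[0]), n_restarts=config.kmeans_restarts, seed=config.seed
        )
        means = expr_mod.cluster_means(profiles, km.assignments)
        t = np.asarray(means.columns, dtype=float)
        scaled_means = {
            int(c): (t, expr_mod.scale_unit_interval(means.loc[c].to_numpy()))
            for c in means.index
        }
        names = expr_mod.name_clusters_by_activation(km.assignments, scaled_means)
        out = km.assignments.to_frame()
        out["cluster_name"] = out["cluster_index"].map(names)
        out["planted_cluster"] = planted
        out.to_csv(outdir / "clusters.tsv", sep="\t")
        written.append(outdir / "clusters.tsv")
        logger.info("cluster: %d genes into %d clusters (%d dropped)", len(out), km.k, len(dropped))

    if stages.get("chip"):
        stages_run.append("chip")
        genome = config.chip_genome_length
        planted = [(10_000, 5.0, 200.0), (30_000, 4.0, 200.0), (50_000, 6.0, 150.0)]
        reps = synth.make_chip_tracks(genome, planted, seed=config.seed)
        smoothed = [
            (chip_mod.smooth_track(ip), chip_mod.smooth_track(mock)) for ip, mock in reps
        ]
        peak_sets = [
            chip_mod.call_peaks(ip, mock, config.fold_threshold) for ip, mock in smoothed
        ]
        peaks = chip_mod.replicate_consistent_peaks(peak_sets[0], peak_sets[1], genome)
        chip_annotation = chip_mod.GeneAnnotation(
            [
                chip_mod.Gene("target_0001", 10_301, 11_300, "+"),
                chip_mod.Gene("target_0002", 29_000, 29_800, "-"),
                chip_mod.Gene("target_0003", 50_401, 51_200, "+"),
            ],
            genome,
        )
        links = chip_mod.assign_peak_targets(peaks, chip_annotation, config.link_max_distance_bp)
        io_mod.write_peaks_bed(peaks, outdir / "peaks.bed", header=header)
        io_mod.write_links_tsv(links, outdir / "peak_gene_links.tsv", header=header)
        io_mod.write_bedgraph(smoothed[0][0], outdir / "ip_rep1_smoothed.bedgraph", header=header)
        written += [outdir / "peaks.bed", outdir / "peak_gene_links.tsv", outdir / "ip_rep1_smoothed.bedgraph"]
        logger.info("chip: %d consistent peaks, %d gene links", len(peaks), len(links))

    fits_by_cluster: dict[str, list[mdl.FitResult]] = {}
    if stages.get("fit"):
        if study is None:
            raise ValueError("fit stage requires the simulate stage output")
        stages_run.append("fit")
        for cluster in config.fit_clusters:
            data = study.fit_data(cluster)
            inputs = study.fit_inputs(cluster)
            fits = []
            for variant in config.fit_variants:
                label = BEST_FEEDBACK_VARIANT[cluster] if variant == "feedback" else variant
                spec = mdl.spec_from_variant(label, cluster)
                fit = mdl.fit_model(
                    spec, data, inputs, BOUNDS, n_starts=config.n_starts, seed=config.seed
                )
                fits.append(fit)
                io_mod.write_fit_json(
                    fit,
                    outdir / f"fit_{cluster}_{label.replace(':', '-')}.json",
                    extra={"variant": label, "config_hash": cfg_hash},
                )
                written.append(outdir / f"fit_{cluster}_{label.replace(':', '-')}.json")
            fits_by_cluster[cluster] = fits
            logger.info(
                "fit %s: errors %s", cluster, [round(f.error, 3) for f in fits]
            )

    if stages.get("compare"):
        if not fits_by_cluster:
            raise ValueError("compare stage requires the fit stage output")
        stages_run.append("compare")
        ranking = {}
        for cluster, fits in fits_by_cluster.items():
            comparison = mdl.compare_models_aic(fits)
            ranking[cluster] = [
                {
                    "variant": config.fit_variants[i],
                    "error": fits[i].error,
                    "aic": comparison.aic[i],
                }
                for i in comparison.ranking
            ]
        (outdir / "model_comparison.json").write_text(json.dumps(ranking, indent=2) + "\n")
        written.append(outdir / "model_comparison.json")

    checksums = {p.name: _sha256(p) for p in sorted(set(written))}
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.seed,
        stages_run=stages_run,
        checksums=checksums,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    (outdir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2) + "\n"
    )
    return manifest
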