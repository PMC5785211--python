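"""Readers and writers for the flat-file formats the pipeline exchanges.

Expression travels as long-format TSV (gene_id, condition, time_h,
value); annotations as GFF3 (1-based inclusive, parsed with gffutils);
genomic signal as bedGraph (0-based half-open, run-length compressed);
peaks as BED6 plus a TSV of per-timepoint enrichments. Writers accept
an optional header comment (used by the pipeline to stamp the config
hash); readers skip ``#`` lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chip import Gene, GeneAnnotation, Peak, PeakGeneLink, SignalTrack
from .expression import ExpressionMatrix

__all__ = [
    "write_expression_tsv",
    "read_expression_tsv",
    "write_gff3",
    "read_gff3",
    "write_bedgraph",
    "read_bedgraph",
    "write_peaks_bed",
    "write_peak_enrichment_tsv",
    "write_links_tsv",
    "write_fit_json",
]


def _write_with_header(path: Path, text: str, header: str | None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write(text)


def write_expression_tsv(expr: ExpressionMatrix | pd.DataFrame, path, header: str | None = None) -> None:
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    long = values.stack(["condition", "time_h"], future_stack=True).rename("value").reset_index()
    long.columns = ["gene_id", "condition", "time_h", "value"]
    _write_with_header(Path(path), long.to_csv(sep="\t", index=False), header)


def read_expression_tsv(path, gene_lengths: pd.Series | None = None) -> ExpressionMatrix:
    long = pd.read_csv(path, sep="\t", comment="#")
    wide = long.pivot_table(index="gene_id", columns=["condition", "time_h"], values="value")
    wide.columns.names = ["condition", "time_h"]
    return ExpressionMatrix(wide, gene_lengths)


def write_gff3(annotation: GeneAnnotation, path, header: str | None = None) -> None:
    lines = ["##gff-version 3", f"##sequence-region chromosome 1 {annotation.genome_length}"]
    for g in annotation.genes:
        lines.append(
            "\t".join(
                [
                    "chromosome",
                    "clocklight",
                    "gene",
                    str(g.start),
                    str(g.end),
                    ".",
                    g.strand,
                    ".",
                    f"ID={g.gene_id}",
                ]
            )
        )
    _write_with_header(Path(path), "\n".join(lines) + "\n", header)


def read_gff3(path, circular: bool = True) -> GeneAnnotation:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = [
        Gene(f.id, f.start, f.end, f.strand)
        for f in db.all_features()
        if f.featuretype == "gene"
    ]
    genome_length = max((g.end for g in genes), default=1)
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            genome_length = int(line.split()[-1])
            break
    return GeneAnnotation(genes, genome_length, circular)


def write_bedgraph(track: SignalTrack, path, chrom: str = "chromosome", header: str | None = None) -> None:
    """Run-length compressed bedGraph (0-based half-open intervals)."""
    v = track.values
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [v.size]))
    rows = (f"{chrom}\t{s}\t{e}\t{v[s]:g}" for s, e in zip(starts, ends))
    _write_with_header(Path(path), "\n".join(rows) + "\n", header)


def read_bedgraph(path, genome_length: int | None = None, circular: bool = True) -> SignalTrack:
    df = pd.read_csv(path, sep="\t", comment="#", names=["chrom", "start", "end", "value"])
    n = genome_length if genome_length is not None else int(df["end"].max())
    values = np.zeros(n)
    for start, end, value in zip(df["start"], df["end"], df["value"]):
        values[start:end] = value
    return SignalTrack(values, circular)


def write_peaks_bed(peaks: Sequence[Peak], path, chrom: str = "chromosome", header: str | None = None) -> None:
    """BED6; score = 10 x enrichment at the calling time point, capped at 1000."""
    rows = []
    for i, p in enumerate(peaks):
        score = min(int(round(10 * p.enrichment)), 1000)
        rows.append(f"{chrom}\t{p.start}\t{p.end}\tpeak_{i:04d}\t{score}\t.")
    _write_with_header(Path(path), "\n".join(rows) + "\n", header)


def write_peak_enrichment_tsv(peaks: Sequence[Peak], path, header: str | None = None) -> None:
    rows = []
    for i, p in enumerate(peaks):
        for key, value in sorted(p.enrichment_by_timepoint.items(), key=str):
            condition, t = key if isinstance(key, tuple) else (key, "")
            rows.append(
                {
                    "peak_id": f"peak_{i:04d}",
                    "summit": p.summit,
                    "condition": condition,
                    "time_h": t,
                    "enrichment": value,
                }
            )
    _write_with_header(Path(path), pd.DataFrame(rows).to_csv(sep="\t", index=False), header)


def write_links_tsv(links: Iterable[PeakGeneLink], path, header: str | None = None) -> None:
    rows = [
        {
            "summit": link.peak.summit,
            "gene_id": link.gene_id,
            "distance_bp": link.distance,
            "strand": link.strand,
        }
        for link in links
    ]
    _write_with_header(Path(path), pd.DataFrame(rows).to_csv(sep="\t", index=False), header)


def write_fit_json(fit, path, extra: dict | None = None) -> None:
    """Serialize a FitResult (parameters, error, provenance) to JSON."""
    spec = fit.spec
    payload = {
        "target": spec.target,
        "regulators": list(spec.regulators),
        "feedback": list(spec.feedback) if spec.feedback else None,
        "params": {
            "B": fit.params.B,
            "beta": fit.params.beta,
            "alpha": fit.params.alpha,
            **{
                f"{label}_{field}": getattr(term, field)
                for label, term in (
                    ("hill_A", fit.params.hill_A),
                    ("hill_B", fit.params.hill_B),
                    ("hill_Y", fit.params.hill_Y),
                )
                if term is not None
                for field in ("K", "H")
            },
        },
        "error": fit.error,
        "n_starts": fit.n_starts,
        "seed": fit.seed,
        "n_data": fit.n_data,
        "k_params": fit.k_params,
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
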