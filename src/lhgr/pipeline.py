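"""End-to-end orchestration: io -> curve -> segment -> classify -> stats -> density.

Runs are deterministic given (inputs, config): the only randomness in
the whole pipeline lives in the simulator, which takes an explicit
seed.  Each run writes a manifest recording the configuration and
per-stage record counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from lhgr import io
from lhgr.classification import DEFAULT_H_CUT, classify_segments
from lhgr.errors import ConfigError, DataError
from lhgr.feature_density import (
    correlation_gc3_host,
    filter_lines,
    gene_density_profile,
    line_density_profile,
)
from lhgr.pattern_stats import delta_gc_summary, family_summary
from lhgr.segmentation import RecursiveSegmenter
from lhgr import __version__

log = logging.getLogger("lhgr")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    fasta: str
    outdir: str
    genes: str | None = None
    repeats: str | None = None
    t0: float = 100.0
    l_min: int = 300_000
    w: float = 1.0
    stride: int = 1
    gap_fraction: float = 0.01
    h_cut: float = DEFAULT_H_CUT
    gc_bin_width: float = 0.5
    density_bin_width: float = 1.0
    overwrite: bool = False
    extra: dict = field(default_factory=dict)


def _check_inputs(config: RunConfig, need_density: bool) -> None:
    for label, path in (("fasta", config.fasta), ("genes", config.genes), ("repeats", config.repeats)):
        if path is not None and not Path(path).exists():
            raise ConfigError(f"{label} input does not exist: {path}")
    if need_density and config.genes is None and config.repeats is None:
        raise ConfigError("density stage requested but no gene or repeat input given")


def _output_path(config: RunConfig, name: str) -> Path:
    out = Path(config.outdir) / name
    if out.exists() and not config.overwrite:
        raise ConfigError(f"refusing to overwrite {out} (pass overwrite)")
    return out


def run_pipeline(config: RunConfig, density: bool | None = None) -> dict:
    """Execute all stages and return the run manifest.

    ``density`` defaults to running the density stage exactly when a
    gene or repeat input is configured.
    """
    if density is None:
        density = config.genes is not None or config.repeats is not None
    _check_inputs(config, density)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "config": asdict(config), "stages": {}}

    log.info("[io] reading %s", config.fasta)
    seqs = io.read_fasta(config.fasta)
    manifest["stages"]["io"] = {"chromosomes": len(seqs)}

    all_segments = []
    chrom_lengths: dict[str, int] = {}
    seg_counts = {}
    for seq in seqs:
        chrom_lengths[seq.chrom_id] = seq.length
        log.info("[segment] %s (%d bp)", seq.chrom_id, seq.length)
        est = RecursiveSegmenter(
            t0=config.t0,
            l_min=config.l_min,
            w=config.w,
            stride=config.stride,
            gap_fraction=config.gap_fraction,
        ).fit(seq)
        log.info(
            "[classify] %s: %d segments in %d contigs",
            seq.chrom_id,
            len(est.segments_),
            len(est.contigs_),
        )
        table = classify_segments(est.curve_, est.segments_by_contig_, h_cut=config.h_cut)
        seg_counts[seq.chrom_id] = len(table)
        all_segments.append(table)
    segments = pd.concat(all_segments, ignore_index=True)
    n_iso = int((segments["klass"] == "isochore").sum())
    n_gc = int((segments["gc_type"] == "GC-LHGR").sum())
    log.info(
        "[classify] %d segments total: %d isochores / %d isochore-like, %d GC- / %d AT-LHGRs",
        len(segments),
        n_iso,
        len(segments) - n_iso,
        n_gc,
        len(segments) - n_gc,
    )
    io.write_segments_tsv(segments, _output_path(config, "segments.tsv"))
    io.write_segments_bed(segments, _output_path(config, "segments.bed"))
    manifest["stages"]["segment"] = {"per_chromosome": seg_counts}
    manifest["stages"]["classify"] = {
        "segments": len(segments),
        "isochores": n_iso,
        "isochore_like": len(segments) - n_iso,
        "gc_lhgrs": n_gc,
        "at_lhgrs": len(segments) - n_gc,
    }

    log.info("[stats] family summary")
    summary = family_summary(segments, gc_bin_width=config.gc_bin_width)
    summary.table.to_csv(_output_path(config, "family_summary.tsv"), sep="\t", float_format="%.4g")
    summary.count_histogram.to_csv(_output_path(config, "gc_histogram.tsv"), sep="\t")
    summary.size_histogram.to_csv(_output_path(config, "size_histogram.tsv"), sep="\t")
    delta_gc_summary(segments).to_csv(
        _output_path(config, "delta_gc_summary.tsv"), sep="\t", index=False, float_format="%.4g"
    )
    manifest["stages"]["stats"] = {
        "families": {k: int(v) for k, v in summary.table["count"].items()}
    }

    if density:
        dens_manifest: dict = {}
        if config.genes is not None:
            genes = io.read_gene_table(config.genes)
            for mode, fname in (
                ("gc3", "gene_density_gc3.tsv"),
                ("host_gc", "gene_density_hostgc.tsv"),
            ):
                try:
                    res = gene_density_profile(
                        genes, segments, chrom_lengths, mode=mode,
                        bin_width=config.density_bin_width,
                    )
                except DataError as exc:
                    raise DataError(f"gene density ({mode}): {exc}") from exc
                res.table.to_csv(_output_path(config, fname), sep="\t", index=False, float_format="%.6g")
                dens_manifest[f"gene_density_{mode}"] = {
                    "bins": len(res.table),
                    "excluded": res.excluded,
                }
            if (genes["cds"].astype(str).str.len() > 0).all():
                r2, p = correlation_gc3_host(genes, segments)
                dens_manifest["gc3_host_r2"] = r2
                log.info("[density] GC3 vs host GC: r^2=%.3f (p=%.2g)", r2, p)
        if config.repeats is not None:
            repeats = filter_lines(io.read_repeatmasker_out(config.repeats))
            if repeats.empty:
                raise DataError(f"{config.repeats}: no LINE records after filtering")
            res, reg = line_density_profile(repeats, segments, chrom_lengths)
            res.table.to_csv(_output_path(config, "line_density.tsv"), sep="\t", index=False, float_format="%.6g")
            dens_manifest["line_density"] = {
                "bins": len(res.table),
                "slope": None if reg is None else reg.slope,
                "r_squared": None if reg is None else reg.r_squared,
            }
            if reg is not None:
                log.info(
                    "[density] LINE density vs GC: slope=%.3f per GC%%, r^2=%.3f",
                    reg.slope,
                    reg.r_squared,
                )
        manifest["stages"]["density"] = dens_manifest

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
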