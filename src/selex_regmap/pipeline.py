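"""End-to-end orchestration: probe table + annotation -> tables and reports.

``run_all`` chains normalization, peak calling, site location, target
counting, category/regulon coverage and TF-network export, writing every
result as a diffable plain-text table plus a JSON run log that records all
parameters affecting any output.  Re-running with the same config and seed
produces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd

from . import __version__
from . import annotation as ann_mod
from . import chip_signal as sig
from . import target_prediction as tp
from .errors import PipelineError, ValidationError

log = logging.getLogger("selex_regmap")


@dataclass
class RunConfig:
    """Inputs and parameters for one full analysis run."""

    probe_table: Union[str, Path]
    gff3: Union[str, Path]
    outdir: Union[str, Path]
    category_map: Union[str, Path, None] = None
    reference_lists: Mapping[str, Union[str, Path]] = field(default_factory=dict)
    whole_set_sizes: Mapping[str, int] | None = None  # None: from annotation
    cutoff: float = sig.DEFAULT_CUTOFF
    alt_cutoff: float | None = None
    max_gap: int = 0
    regulator: str = "lrp"
    circular: bool = False
    genome_length: int | None = None

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValidationError(f"cutoff must be positive, got {self.cutoff}")
        if self.alt_cutoff is not None and self.alt_cutoff <= 0:
            raise ValidationError("alt_cutoff must be positive")


@dataclass
class ReportBundle:
    """All result tables of one run, plus the paths they were written to."""

    config: RunConfig
    annotation: ann_mod.GenomeAnnotation
    probes: pd.DataFrame
    peaks: list
    sites: list
    counts: tp.TargetCount
    category_rows: list
    overlaps: list
    network_edges: list
    reference_fluctuation: float
    alt_sites: list | None = None
    paths: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ValidationError:
                raise
            except Exception as e:  # attach stage context to unexpected failures
                raise PipelineError(name, e) from e

        return wrapped

    return deco


def run_all(config: RunConfig) -> ReportBundle:
    """Execute the full chain and write all output tables under ``outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    warnings: list[str] = []

    annotation = _load(config)
    probes = _normalize(config)
    fluct = sig.check_reference_fluctuation(probes)
    if fluct >= 2:
        msg = f"reference-channel fluctuation {fluct:.3g} exceeds the two-fold design bound"
        warnings.append(msg)
        log.warning(msg)

    peaks = _peaks(probes, config.cutoff, config.max_gap)
    sites = _locate(peaks, annotation)
    counts = tp.count_targets(sites)

    whole = (
        dict(config.whole_set_sizes)
        if config.whole_set_sizes is not None
        else tp.whole_set_sizes_from_annotation(annotation)
    )
    category_rows = tp.summarize_categories(sites, annotation, whole) if whole else []

    predicted = tp.predicted_target_genes(sites, annotation)
    overlaps = []
    for name, path in config.reference_lists.items():
        ref = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip()
        ]
        overlaps.append(tp.regulon_overlap(predicted, ref, name))

    edges = tp.build_tf_network(sites, annotation, config.regulator)

    alt_sites = None
    if config.alt_cutoff is not None:
        alt_peaks = _peaks(probes, config.alt_cutoff, config.max_gap)
        alt_sites = _locate(alt_peaks, annotation)

    # --- write everything ---------------------------------------------------
    paths["probes_normalized"] = outdir / "probes_normalized.tsv"
    sig.write_probe_table(probes, paths["probes_normalized"])
    paths["track"] = outdir / "ratio_track.tsv"
    _write_track(probes, paths["track"])
    paths["peaks_bed"] = outdir / "peaks.bed"
    sig.write_peaks_bed(peaks, paths["peaks_bed"])
    paths["peaks_tsv"] = outdir / "peaks.tsv"
    sig.write_peaks_tsv(peaks, paths["peaks_tsv"])
    paths["sites"] = outdir / "sites.tsv"
    tp.sites_table(sites).to_csv(paths["sites"], sep="\t", index=False)
    paths["counts"] = outdir / "target_counts.tsv"
    tp.counts_table(counts).to_csv(paths["counts"], sep="\t", index=False)
    paths["units"] = outdir / "units.tsv"
    ann_mod.write_unit_table(annotation.units, paths["units"])
    paths["spacers"] = outdir / "spacers.tsv"
    ann_mod.write_spacer_table(annotation.spacers, paths["spacers"])
    if category_rows:
        paths["categories"] = outdir / "category_coverage.tsv"
        tp.categories_table(category_rows).to_csv(paths["categories"], sep="\t", index=False)
    if overlaps:
        paths["overlaps"] = outdir / "regulon_overlap.tsv"
        tp.overlaps_table(overlaps).to_csv(paths["overlaps"], sep="\t", index=False)
    paths["network_tsv"] = outdir / "tf_network.tsv"
    tp.write_network_tsv(edges, paths["network_tsv"])
    paths["network_dot"] = outdir / "tf_network.dot"
    tp.write_network_dot(edges, paths["network_dot"])
    if alt_sites is not None:
        paths["sites_alt"] = outdir / "sites_alt_cutoff.tsv"
        tp.sites_table(alt_sites).to_csv(paths["sites_alt"], sep="\t", index=False)

    bundle = ReportBundle(
        config=config,
        annotation=annotation,
        probes=probes,
        peaks=peaks,
        sites=sites,
        counts=counts,
        category_rows=category_rows,
        overlaps=overlaps,
        network_edges=edges,
        reference_fluctuation=fluct,
        alt_sites=alt_sites,
        paths=paths,
        warnings=warnings,
    )

    paths["report"] = outdir / "report.md"
    paths["report"].write_text(render_report(bundle))
    paths["run_log"] = outdir / "run_log.json"
    paths["run_log"].write_text(_run_log(bundle))
    return bundle


@_stage("load_annotation")
def _load(config: RunConfig):
    return ann_mod.load_annotation(
        config.gff3,
        category_map=config.category_map,
        circular=config.circular,
        genome_length=config.genome_length,
    )


@_stage("normalize")
def _normalize(config: RunConfig):
    return sig.normalize(sig.read_probe_table(config.probe_table))


@_stage("call_peaks")
def _peaks(probes, cutoff, max_gap):
    return sig.call_peaks(probes, cutoff=cutoff, max_gap=max_gap)


@_stage("locate_sites")
def _locate(peaks, annotation):
    return tp.locate_sites(peaks, annotation)


def _write_track(probes: pd.DataFrame, path: Path) -> None:
    """Ratio-vs-genome-position track (plotting export)."""
    track = probes.loc[probes["usable"], ["start", "end", "ratio"]].copy()
    track["position"] = (track["start"] + track["end"]) // 2
    track[["position", "ratio"]].to_csv(path, sep="\t", index=False)


def _run_log(bundle: ReportBundle) -> str:
    c = bundle.config
    payload = {
        "package_version": __version__,
        "parameters": {
            "probe_table": str(c.probe_table),
            "gff3": str(c.gff3),
            "category_map": str(c.category_map) if c.category_map else None,
            "reference_lists": {k: str(v) for k, v in c.reference_lists.items()},
            "cutoff": c.cutoff,
            "alt_cutoff": c.alt_cutoff,
            "max_gap": c.max_gap,
            "regulator": c.regulator,
            "circular": c.circular,
            "genome_length": c.genome_length,
            "whole_set_sizes": dict(c.whole_set_sizes) if c.whole_set_sizes else None,
        },
        "reference_fluctuation": bundle.reference_fluctuation,
        "n_probes": int(len(bundle.probes)),
        "n_peaks": len(bundle.peaks),
        "warnings": bundle.warnings,
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def render_report(bundle: ReportBundle) -> str:
    """Human-readable markdown summary: site counts, coverage, network."""
    tc = bundle.counts
    lines = [
        "# Binding-site screen summary",
        "",
        f"- probes: {len(bundle.probes)}; reference fluctuation "
        f"{bundle.reference_fluctuation:.3f} (design bound: < 2)",
        f"- cutoff: {bundle.config.cutoff}; peaks called: {len(bundle.peaks)}",
        "",
        "## Binding sites by location",
        "",
        "| Location | No. sites | No. targets |",
        "|---|---|---|",
        f"| Within type A spacers | {tc.n_A} | {tc.n_A}-{2 * tc.n_A} |",
        f"| Within type B spacers | {tc.n_B} | {tc.n_B} |",
        f"| Within type C spacers | {tc.n_C} | 0 |",
        f"| Inside ORFs | {tc.n_ORF} | - |",
        f"| **Total** | {tc.total_sites} | {tc.min_targets}-{tc.max_targets} |",
        "",
    ]
    if bundle.category_rows:
        lines += [
            "## Functional-category coverage",
            "",
            "| Category | Whole set | Identified (%) |",
            "|---|---|---|",
        ]
        for r in bundle.category_rows:
            lines.append(f"| {r.category} | {r.whole_set} | {r.identified} ({r.percent}) |")
        lines.append("")
    if bundle.overlaps:
        lines += ["## Reference-regulon coverage", ""]
        for s in bundle.overlaps:
            lines.append(
                f"- {s.name}: {s.overlap} of {s.reference_size} covered ({s.percent}%)"
            )
        lines.append("")
    lines += [
        "## Transcription-factor network",
        "",
        f"- {len(bundle.network_edges)} TF genes under direct control of "
        f"{bundle.config.regulator}",
        "",
    ]
    if bundle.alt_sites is not None:
        lines += [
            f"- relaxed cutoff {bundle.config.alt_cutoff}: "
            f"{len(bundle.alt_sites)} sites "
            f"(strict cutoff {bundle.config.cutoff}: {len(bundle.sites)})",
            "",
        ]
    return "\n".join(lines)
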