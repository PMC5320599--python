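"""From called peaks to predicted regulation targets.

A bacterial transcription factor bound in an intergenic spacer is assumed to
act on the unit(s) whose promoter region the spacer contains: both flanking
units for a divergent (class A) spacer, only the downstream-of-spacer unit
for a tandem (class B) spacer, and none for a convergent (class C) spacer or
a site inside an ORF.  Target counts therefore bracket the regulon size:

    min_targets = n_A + n_B        (one unit per A site)
    max_targets = 2*n_A + n_B      (both units per A site)

Location is decided by the peak summit alone — a peak may straddle a
spacer/gene boundary, but each site gets a single class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import networkx as nx
import pandas as pd

from ._util import percent, round_half_up
from .annotation import GenomeAnnotation
from .chip_signal import Peak
from .errors import ValidationError

LOCATIONS = ("A", "B", "C", "ORF")


@dataclass(frozen=True)
class BindingSite:
    """A called peak resolved to a spacer class or ORF-internal location."""

    peak: Peak
    location: str  # one of LOCATIONS, or "edge" for terminal-flank summits
    host: str  # spacer id (A/B/C/edge) or gene id (ORF)
    candidate_targets: tuple  # unit ids: 2 for A, 1 for B, 0 for C/ORF


@dataclass(frozen=True)
class TargetCount:
    """Per-class site tallies and the min/max regulon-size bracket."""

    n_A: int
    n_B: int
    n_C: int
    n_ORF: int

    @property
    def total_sites(self) -> int:
        return self.n_A + self.n_B + self.n_C + self.n_ORF

    @property
    def spacer_sites(self) -> int:
        return self.n_A + self.n_B + self.n_C

    @property
    def min_targets(self) -> int:
        return self.n_A + self.n_B

    @property
    def max_targets(self) -> int:
        return 2 * self.n_A + self.n_B


@dataclass(frozen=True)
class CategoryRow:
    """One functional-category coverage row (Table-2 shape)."""

    category: str
    whole_set: int
    identified: int

    @property
    def percent(self) -> int:
        return percent(self.identified, self.whole_set)


@dataclass(frozen=True)
class OverlapStat:
    """Coverage of one reference regulon list by the predicted targets."""

    name: str
    reference_size: int
    overlap: int

    @property
    def percent(self) -> int:
        return percent(self.overlap, self.reference_size)


def locate_site(peak: Peak, annotation: GenomeAnnotation) -> BindingSite:
    """Resolve a peak to its binding-site location by summit coordinate.

    A summit inside a gene body is ORF-internal (no targets).  Otherwise the
    enclosing spacer's orientation class decides the candidate targets:
    A -> both flanking units; B -> the unit reading away from the spacer
    ((+,+): right unit, (-,-): left unit); C -> none.  Summits in the
    unclassifiable terminal flanks of a linear genome get location "edge"
    and are excluded from counting.  A summit falling in an intra-unit gap
    (between genes of one operon) counts as ORF-internal, hosted by the
    nearest member gene.
    """
    pos = peak.summit
    if not (0 <= pos < annotation.genome_length):
        raise ValidationError(
            f"peak {peak.peak_id}: summit {pos} outside genome "
            f"[0,{annotation.genome_length})"
        )

    gene = annotation.gene_at(pos)
    if gene is not None:
        return BindingSite(peak, "ORF", gene.id, ())

    spacer = annotation.spacer_at(pos)
    if spacer is None:
        # Inside a unit span but between member genes: operon-internal.
        host = _nearest_gene_in_unit(pos, annotation)
        return BindingSite(peak, "ORF", host, ())

    if spacer.cls is None:
        return BindingSite(peak, "edge", spacer.spacer_id, ())
    if spacer.cls == "A":
        targets = (spacer.left_unit, spacer.right_unit)
    elif spacer.cls == "B":
        # Downstream-of-spacer unit: forced by strand geometry.
        right = annotation.units_by_id[spacer.right_unit]
        targets = (spacer.right_unit,) if right.strand == "+" else (spacer.left_unit,)
    else:  # C
        targets = ()
    return BindingSite(peak, spacer.cls, spacer.spacer_id, targets)


def _nearest_gene_in_unit(pos: int, annotation: GenomeAnnotation) -> str:
    return min(
        annotation.genes,
        key=lambda g: min(abs(pos - g.start), abs(pos - (g.end - 1))),
    ).id


def locate_sites(peaks: Iterable[Peak], annotation: GenomeAnnotation) -> list:
    return [locate_site(p, annotation) for p in peaks]


def count_targets(sites: Iterable[BindingSite]) -> TargetCount:
    """Tally sites per location class; edge sites are tallied nowhere."""
    tally = {c: 0 for c in LOCATIONS}
    for s in sites:
        if s.location in tally:
            tally[s.location] += 1
    return TargetCount(tally["A"], tally["B"], tally["C"], tally["ORF"])


def predicted_target_units(sites: Iterable[BindingSite]) -> set:
    """Union of candidate target unit ids over all sites."""
    return {u for s in sites for u in s.candidate_targets}


def predicted_target_genes(
    sites: Iterable[BindingSite], annotation: GenomeAnnotation
) -> set:
    """Candidate target units expanded to their member gene ids."""
    return {
        gid
        for uid in predicted_target_units(sites)
        for gid in annotation.units_by_id[uid].gene_ids
    }


def summarize_categories(
    sites: Iterable[BindingSite],
    annotation: GenomeAnnotation,
    whole_set_sizes: Mapping[str, int],
) -> list:
    """Per-category coverage of the genome's functional gene sets.

    ``identified`` counts distinct candidate-target genes carrying the
    category; ``percent`` is round-half-up so printed tables reproduce
    exactly.  Categories with a zero whole-set size are rejected.
    """
    for cat, n in whole_set_sizes.items():
        if n <= 0:
            raise ValidationError(f"category {cat!r}: whole-set size must be > 0")
    genes = predicted_target_genes(sites, annotation)
    rows = []
    for cat in whole_set_sizes:
        identified = sum(
            1 for gid in genes if cat in annotation.genes_by_id[gid].categories
        )
        rows.append(CategoryRow(cat, int(whole_set_sizes[cat]), identified))
    return rows


def whole_set_sizes_from_annotation(annotation: GenomeAnnotation) -> dict:
    """Category totals over all annotated genes (default whole sets)."""
    sizes: dict[str, int] = {}
    for g in annotation.genes:
        for c in g.categories:
            sizes[c] = sizes.get(c, 0) + 1
    return sizes


def regulon_overlap(
    predicted_targets: Iterable[str], reference_list: Sequence[str], name: str
) -> OverlapStat:
    """Coverage of a reference regulon (e.g. curated-DB or ChIP-chip list)."""
    reference = set(reference_list)
    if not reference:
        raise ValidationError(f"reference list {name!r} is empty")
    overlap = len(set(predicted_targets) & reference)
    return OverlapStat(name, len(reference), overlap)


def fold_expansion(n_predicted: int, n_reference: int) -> float:
    """Fold change of the predicted regulon size over a prior estimate,
    rounded half-up to one decimal (e.g. 296 over 130 -> 2.3)."""
    if n_reference <= 0:
        raise ValidationError("reference regulon size must be positive")
    return round_half_up(n_predicted / n_reference, 1)


def build_tf_network(
    sites: Iterable[BindingSite],
    annotation: GenomeAnnotation,
    regulator: str = "lrp",
) -> list:
    """Directed regulator->TF edges over transcription-factor-tagged targets.

    One deduplicated edge per distinct TF gene among the candidate targets,
    self-loop permitted (a factor bound upstream of its own gene).  Edges are
    returned sorted for deterministic output.
    """
    if regulator not in annotation.genes_by_id:
        raise ValidationError(f"regulator gene {regulator!r} not in annotation")
    tf_targets = {
        gid
        for gid in predicted_target_genes(sites, annotation)
        if "transcription_factor" in annotation.genes_by_id[gid].categories
    }
    return sorted((regulator, t) for t in tf_targets)


def network_graph(edges: Iterable[tuple]) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_edges_from(edges)
    return g


# ---------------------------------------------------------------------------
# Tabular output


def sites_table(sites: Sequence[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "peak_id": [s.peak.peak_id for s in sites],
            "summit": [s.peak.summit for s in sites],
            "height": [s.peak.height for s in sites],
            "location": [s.location for s in sites],
            "host": [s.host for s in sites],
            "candidates": [",".join(s.candidate_targets) for s in sites],
        }
    )


def counts_table(tc: TargetCount) -> pd.DataFrame:
    """Per-location site summary with the min-max target bracket."""
    rows = [
        ("Within type A spacers", tc.n_A, f"{tc.n_A}-{2 * tc.n_A}"),
        ("Within type B spacers", tc.n_B, str(tc.n_B)),
        ("Within type C spacers", tc.n_C, "0"),
        ("Inside ORFs", tc.n_ORF, "-"),
        ("Total", tc.total_sites, f"{tc.min_targets}-{tc.max_targets}"),
    ]
    return pd.DataFrame(rows, columns=["location", "n_sites", "n_targets"])


def categories_table(rows: Sequence[CategoryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category for r in rows],
            "whole_set": [r.whole_set for r in rows],
            "identified": [r.identified for r in rows],
            "percent": [r.percent for r in rows],
        }
    )


def overlaps_table(stats: Sequence[OverlapStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "reference": [s.name for s in stats],
            "reference_size": [s.reference_size for s in stats],
            "overlap": [s.overlap for s in stats],
            "percent": [s.percent for s in stats],
        }
    )


def write_network_tsv(edges: Sequence[tuple], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("regulator\ttarget\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


def write_network_dot(edges: Sequence[tuple], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("digraph tf_network {\n")
        for a, b in edges:
            fh.write(f'  "{a}" -> "{b}";\n')
        fh.write("}\n")
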