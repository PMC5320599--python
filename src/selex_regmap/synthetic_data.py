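"""Seeded toy genomes with planted binding sites and simulated probe tables.

The generator emulates the screen's assay design: a tiling array of 60-bp
probes every 105 bp over a bacterial genome, a reference channel whose
probe-to-probe fluctuation stays below two-fold, and multiplicative signal
enrichment where a planted binding site overlaps a probe.  Planted sites are
placed at spacer midpoints (classes A/B/C) or gene midpoints (ORF-internal),
so the intended location class and target units are known exactly and
end-to-end recovery can be scored.

Signal model: each probe's reference intensity cy3 is a truncated lognormal
(truncation enforces the two-fold bound by construction); the test channel is
cy5 = cy3 * (1 + (enrichment - 1) * f) for a probe overlapping a planted
site window with overlap fraction f, and cy5 = cy3 * lognormal(1, sigma)
elsewhere.  Fully covered probes thus sit exactly at the enrichment ratio and
the summit of a called peak lands within half a window of the planted
coordinate.  One integer seed drives layout, planting and noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import (
    GeneFeature,
    GenomeAnnotation,
    derive_spacers,
    derive_units,
)
from .errors import ConfigError
from .target_prediction import BindingSite

#: Default per-gene functional-category frequencies (one tag per gene),
#: loosely shaped like a bacterial genome's composition.
DEFAULT_CATEGORY_PROBS = {
    "transporter": 0.08,
    "aa_metabolism": 0.15,
    "tRNA": 0.05,
    "tRNA_charging": 0.03,
    "rRNA": 0.02,
    "transcription_factor": 0.08,
    "other": 0.59,
}

#: cy3 values are clipped to reference_mean / and * this factor, keeping the
#: max/min reference fluctuation at 1.4^2 = 1.96 < 2 by construction.
REFERENCE_CLIP_FACTOR = 1.4


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults follow the assay being emulated: 60-bp probes at 105-bp
    spacing, a reference channel with lognormal sigma 0.1 truncated below
    two-fold fluctuation, 20-fold enrichment over a 200-bp bound-fragment
    window, and a modest 60-gene genome with a mixed planted-site panel.
    """

    n_genes: int = 60
    genome_length: int | None = None  # None: sized to fit the layout
    gene_length: tuple = (600, 1200)
    gap_length: tuple = (250, 400)
    strand_pattern: Sequence[str] | None = None  # None: random strands
    terminal_flank: int = 300
    circular: bool = False
    probe_length: int = 60
    probe_spacing: int = 105
    reference_mean: float = 1000.0
    reference_noise: float = 0.1
    enrichment: float = 20.0
    site_width: int = 200
    planted_class_counts: Mapping[str, int] = field(
        default_factory=lambda: {"A": 3, "B": 5, "C": 1, "ORF": 3}
    )
    category_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    regulator_id: str = "lrp"
    seed: int = 0

    def __post_init__(self):
        if self.probe_spacing < 1:
            raise ConfigError("probe_spacing must be >= 1")
        if self.probe_length < 1:
            raise ConfigError("probe_length must be >= 1")
        if self.enrichment <= 1:
            raise ConfigError("enrichment must exceed 1")
        if self.reference_noise < 0:
            raise ConfigError("reference_noise must be >= 0")
        if self.site_width < 1:
            raise ConfigError("site_width must be >= 1")
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        for lo, hi, nm in (
            (*self.gene_length, "gene_length"),
            (*self.gap_length, "gap_length"),
        ):
            if lo < 1 or hi < lo:
                raise ConfigError(f"invalid {nm} range ({lo},{hi})")
        if self.strand_pattern is not None:
            if len(self.strand_pattern) != self.n_genes:
                raise ConfigError(
                    f"strand_pattern length {len(self.strand_pattern)} "
                    f"!= n_genes {self.n_genes}"
                )
            bad = set(self.strand_pattern) - {"+", "-"}
            if bad:
                raise ConfigError(f"strand_pattern has invalid symbols {sorted(bad)}")
        for cls, n in self.planted_class_counts.items():
            if cls not in ("A", "B", "C", "ORF") or n < 0:
                raise ConfigError(f"invalid planted count {cls!r}: {n}")


@dataclass(frozen=True)
class PlantedSite:
    """One ground-truth binding site: coordinate, intended class, targets."""

    coord: int
    cls: str
    target_units: tuple


@dataclass(frozen=True)
class GroundTruth:
    sites: tuple

    def __len__(self) -> int:
        return len(self.sites)

    def class_counts(self) -> dict:
        out: dict[str, int] = {}
        for s in self.sites:
            out[s.cls] = out.get(s.cls, 0) + 1
        return out


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    # Independent streams for layout / planting / noise off one seed.
    return np.random.default_rng([config.seed, stream])


def generate_genome(config: SimConfig) -> GenomeAnnotation:
    """Lay out non-overlapping genes and derive units and spacers.

    Genes are placed left to right with seeded lengths and intergenic gaps.
    With an explicit strand pattern the spacer class sequence is fully
    determined by the classification truth table; otherwise strands are
    drawn uniformly.  Deterministic under a fixed seed.
    """
    rng = _rng(config, 0)
    n = config.n_genes
    if config.strand_pattern is not None:
        strands = list(config.strand_pattern)
    else:
        strands = list(rng.choice(["+", "-"], size=n))

    lengths = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=n)
    gaps = rng.integers(config.gap_length[0], config.gap_length[1] + 1, size=max(0, n - 1))

    cats = list(config.category_probs)
    probs = np.array([config.category_probs[c] for c in cats], dtype=float)
    probs = probs / probs.sum()
    drawn = rng.choice(cats, size=n, p=probs) if n else []

    genes: list[GeneFeature] = []
    pos = config.terminal_flank
    for i in range(n):
        start, end = pos, pos + int(lengths[i])
        gid = config.regulator_id if i == 0 else f"g{i + 1:04d}"
        category = "transcription_factor" if i == 0 else str(drawn[i])
        genes.append(
            GeneFeature(
                id=gid,
                name=gid,
                start=start,
                end=end,
                strand=strands[i],
                categories=frozenset({category}),
            )
        )
        pos = end + (int(gaps[i]) if i < n - 1 else 0)

    layout_end = (genes[-1].end if genes else 0) + config.terminal_flank
    if config.genome_length is None:
        genome_length = layout_end
    else:
        genome_length = config.genome_length
        if layout_end > genome_length:
            raise ConfigError(
                f"genes exceed genome: layout needs {layout_end} bp, "
                f"genome_length is {genome_length}"
            )

    units = derive_units(genes)
    spacers = derive_spacers(units, genome_length, config.circular)
    return GenomeAnnotation(
        genome_length=genome_length,
        circular=config.circular,
        genes=genes,
        units=units,
        spacers=spacers,
    )


def plant_sites(annotation: GenomeAnnotation, config: SimConfig) -> GroundTruth:
    """Place the requested number of sites per class at spacer/gene midpoints.

    Spacer-class sites record their intended target units by the same
    orientation rules the classifier applies (A: both flanks; B: the
    downstream-of-spacer unit; C: none); ORF sites record no targets.
    """
    rng = _rng(config, 1)
    sites: list[PlantedSite] = []

    spacer_pool = {
        cls: [s for s in annotation.spacers if s.cls == cls and len(s) >= 2]
        for cls in ("A", "B", "C")
    }
    for cls in ("A", "B", "C"):
        want = int(config.planted_class_counts.get(cls, 0))
        pool = spacer_pool[cls]
        if want > len(pool):
            raise ConfigError(
                f"cannot plant {want} class-{cls} sites: only {len(pool)} "
                f"class-{cls} spacers available"
            )
        if want == 0:
            continue
        chosen = rng.choice(len(pool), size=want, replace=False)
        for i in sorted(int(j) for j in chosen):
            s = pool[i]
            coord = ((s.start + s.end) // 2) % annotation.genome_length
            if cls == "A":
                targets = (s.left_unit, s.right_unit)
            elif cls == "B":
                right = annotation.units_by_id[s.right_unit]
                targets = (s.right_unit,) if right.strand == "+" else (s.left_unit,)
            else:
                targets = ()
            sites.append(PlantedSite(coord, cls, targets))

    want_orf = int(config.planted_class_counts.get("ORF", 0))
    if want_orf > len(annotation.genes):
        raise ConfigError(
            f"cannot plant {want_orf} ORF sites: only "
            f"{len(annotation.genes)} genes available"
        )
    if want_orf:
        chosen = rng.choice(len(annotation.genes), size=want_orf, replace=False)
        for i in sorted(int(j) for j in chosen):
            g = annotation.genes[i]
            sites.append(PlantedSite(g.midpoint, "ORF", ()))

    return GroundTruth(tuple(sorted(sites, key=lambda s: s.coord)))


def simulate_probes(
    annotation: GenomeAnnotation, truth: GroundTruth, config: SimConfig
) -> pd.DataFrame:
    """Simulate the raw two-channel probe table over the tiled genome."""
    rng = _rng(config, 2)
    L, step = config.probe_length, config.probe_spacing
    starts = np.arange(0, annotation.genome_length - L + 1, step, dtype=int)
    n = len(starts)

    m = config.reference_mean
    cy3 = rng.lognormal(np.log(m), config.reference_noise, size=n)
    cy3 = np.clip(cy3, m / REFERENCE_CLIP_FACTOR, m * REFERENCE_CLIP_FACTOR)
    background = rng.lognormal(0.0, config.reference_noise, size=n)

    # Overlap fraction of each probe with the union of planted-site windows.
    frac = np.zeros(n)
    half = config.site_width // 2
    glen = annotation.genome_length
    for site in truth.sites:
        for ws, we in _windows(site.coord - half, site.coord + half, glen):
            ov = np.minimum(we, starts + L) - np.maximum(ws, starts)
            frac += np.clip(ov, 0, None)
    frac = np.minimum(frac, L) / L

    cy5 = np.where(
        frac > 0,
        cy3 * (1.0 + (config.enrichment - 1.0) * frac),
        cy3 * background,
    )
    return pd.DataFrame(
        {
            "probe_id": [f"p{i + 1:05d}" for i in range(n)],
            "chrom": "genome",
            "start": starts,
            "end": starts + L,
            "cy3": cy3,
            "cy5": cy5,
        }
    )


def _windows(ws: int, we: int, genome_length: int):
    """Split a possibly origin-wrapping window into linear segments."""
    ws_m, we_m = ws % genome_length, we % genome_length
    if ws < 0 or we > genome_length:
        yield (0, we_m) if we > genome_length else (0, we)
        yield (ws_m, genome_length)
    else:
        yield ws, we


def simulate_dataset(config: SimConfig):
    """Convenience: genome -> planted truth -> probe table, one seed."""
    annotation = generate_genome(config)
    truth = plant_sites(annotation, config)
    probes = simulate_probes(annotation, truth, config)
    return annotation, truth, probes


def published_screen_config(seed: int = 42) -> SimConfig:
    """Study-scale fixture whose planted composition matches the screen's
    published per-class site counts (A 78, B 140, C 10, ORF-internal 86).

    The strand pattern repeats (-, +, +, -), giving per 4-gene block the
    spacer classes A, B, C and a B between blocks: 80 blocks provide
    80 A / 159 B / 80 C spacers, enough for the requested planting.
    """
    blocks = 80
    return SimConfig(
        n_genes=4 * blocks,
        strand_pattern=("-", "+", "+", "-") * blocks,
        planted_class_counts={"A": 78, "B": 140, "C": 10, "ORF": 86},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Recovery scoring


@dataclass(frozen=True)
class RecoveryResult:
    recall: float
    precision: float
    confusion: pd.DataFrame  # rows: intended class, cols: assigned location
    n_planted: int
    n_called: int
    n_recovered: int
    n_matched_calls: int

    @property
    def confusion_is_diagonal(self) -> bool:
        off = 0
        for intended in self.confusion.index:
            for assigned in self.confusion.columns:
                if intended != assigned:
                    off += int(self.confusion.loc[intended, assigned])
        return off == 0


def evaluate_recovery(
    called_sites: Sequence[BindingSite], truth: GroundTruth, tolerance: int
) -> RecoveryResult:
    """Score called sites against the planted truth.

    A planted site is recovered when some called summit lies within
    ``tolerance`` bp; its assigned class is that of the nearest such call.
    Precision is the fraction of called sites whose summit lies within
    tolerance of any planted site (vacuously 1.0 with no calls).
    """
    if tolerance < 0:
        raise ConfigError("tolerance must be >= 0")
    summits = np.array([s.peak.summit for s in called_sites], dtype=float)
    classes = ["A", "B", "C", "ORF", "edge"]
    confusion = pd.DataFrame(
        0, index=["A", "B", "C", "ORF"], columns=classes, dtype=int
    )

    n_recovered = 0
    for planted in truth.sites:
        if len(summits) == 0:
            break
        d = np.abs(summits - planted.coord)
        j = int(np.argmin(d))
        if d[j] <= tolerance:
            n_recovered += 1
            confusion.loc[planted.cls, called_sites[j].location] += 1

    coords = np.array([s.coord for s in truth.sites], dtype=float)
    n_matched = 0
    for s in summits:
        if len(coords) and np.min(np.abs(coords - s)) <= tolerance:
            n_matched += 1

    n_planted, n_called = len(truth.sites), len(called_sites)
    return RecoveryResult(
        recall=n_recovered / n_planted if n_planted else 1.0,
        precision=n_matched / n_called if n_called else 1.0,
        confusion=confusion,
        n_planted=n_planted,
        n_called=n_called,
        n_recovered=n_recovered,
        n_matched_calls=n_matched,
    )


# ---------------------------------------------------------------------------
# Plain-text emission for the downstream modules


def write_gff3(
    annotation: GenomeAnnotation, path: Union[str, Path], seqid: str = "genome"
) -> None:
    """Emit the annotation as GFF3 (1-based inclusive), with operon tags so
    re-loading reproduces the derived units verbatim."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {seqid} 1 {annotation.genome_length}\n")
        for g in annotation.genes:
            attrs = f"ID={g.id};Name={g.name}"
            if g.unit_id is not None:
                attrs += f";operon={g.unit_id}"
            fh.write(
                f"{seqid}\tselex_regmap\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def write_category_map(annotation: GenomeAnnotation, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for g in annotation.genes:
            for c in sorted(g.categories):
                fh.write(f"{g.id}\t{c}\n")


def write_truth_table(truth: GroundTruth, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("coord\tclass\ttarget_units\n")
        for s in truth.sites:
            fh.write(f"{s.coord}\t{s.cls}\t{','.join(s.target_units)}\n")


def read_truth_table(path: Union[str, Path]) -> GroundTruth:
    sites = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            coord, cls, targets = line.rstrip("\n").split("\t")
            sites.append(
                PlantedSite(int(coord), cls, tuple(t for t in targets.split(",") if t))
            )
    return GroundTruth(tuple(sites))


def write_regulon_list(gene_ids: Sequence[str], path: Union[str, Path]) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))


def read_regulon_list(path: Union[str, Path]) -> list:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def make_reference_regulon(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    n_true: int,
    n_decoy: int,
    seed: int = 0,
) -> list:
    """A reference gene list emulating a curated regulon: a sample of true
    target genes diluted with decoys, for coverage statistics."""
    rng = np.random.default_rng([seed, 3])
    true_genes = sorted(
        {
            gid
            for s in truth.sites
            for uid in s.target_units
            for gid in annotation.units_by_id[uid].gene_ids
        }
    )
    decoys = sorted(set(annotation.genes_by_id) - set(true_genes))
    if n_true > len(true_genes) or n_decoy > len(decoys):
        raise ConfigError(
            f"reference regulon infeasible: asked {n_true}/{n_decoy}, "
            f"have {len(true_genes)} true and {len(decoys)} decoy genes"
        )
    pick_t = [true_genes[int(i)] for i in rng.choice(len(true_genes), n_true, replace=False)] if n_true else []
    pick_d = [decoys[int(i)] for i in rng.choice(len(decoys), n_decoy, replace=False)] if n_decoy else []
    return sorted(pick_t + pick_d)
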