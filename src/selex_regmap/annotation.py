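"""Genome annotation: genes, transcription units and intergenic spacers.

The regulatory readout of a binding-site screen hinges on where a site falls
relative to flanking transcription units.  This module loads a bacterial gene
annotation (GFF3), groups genes into transcription units (operons), derives
the intergenic spacers between adjacent units, and classifies each spacer by
the orientation of its flanking units:

* class ``A`` — divergent units ``(-,+)``: the spacer is upstream of both, so
  a bound factor may regulate one or both units;
* class ``B`` — tandem units ``(+,+)`` or ``(-,-)``: upstream of one unit and
  downstream of the other, so exactly one unit is the candidate target;
* class ``C`` — convergent units ``(+,-)``: downstream of both, no target.

Coordinates are 0-based half-open internally; GFF3 is read and written
1-based inclusive, BED 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import gffutils
from intervaltree import IntervalTree

from .errors import GFFParseError, ValidationError

#: Functional categories recognised on genes (Table-2-style summaries).
CATEGORIES = frozenset(
    {
        "transporter",
        "aa_metabolism",
        "tRNA",
        "tRNA_charging",
        "rRNA",
        "transcription_factor",
        "other",
    }
)

SPACER_CLASSES = ("A", "B", "C")

#: Default intergenic gap (bp) under which consecutive same-strand genes are
#: merged into one transcription unit when no operon map is supplied.
DEFAULT_MAX_INTRA_OPERON_GAP = 50


@dataclass
class GeneFeature:
    """A strand-annotated gene with optional functional-category tags."""

    id: str
    name: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str
    categories: frozenset = frozenset()
    unit_id: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"gene {self.id}: start must precede end ({self.start} >= {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.id}: invalid strand {self.strand!r}")
        bad = set(self.categories) - CATEGORIES
        if bad:
            raise ValidationError(f"gene {self.id}: unknown categories {sorted(bad)}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class TranscriptionUnit:
    """An ordered run of same-strand genes treated as one regulatory unit."""

    unit_id: str
    gene_ids: tuple
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class Spacer:
    """Intergenic interval between two adjacent transcription units.

    ``cls`` is ``None`` for the unclassifiable terminal flanks of a linear
    genome (only one flanking unit); such flanks never enter A/B/C counts.
    For the single wrap-around spacer of a circular genome ``wraps`` is True
    and ``end`` may exceed the genome length (coordinates are modular).
    """

    spacer_id: str
    left_unit: str | None
    right_unit: str | None
    start: int
    end: int
    cls: str | None
    wraps: bool = False

    def __len__(self) -> int:
        return max(0, self.end - self.start)


def classify_spacer(left_strand: str, right_strand: str) -> str:
    """Orientation class of a spacer from its flanking unit strands.

    ``(-,+)`` -> A (divergent, upstream of both); ``(+,+)`` and ``(-,-)`` -> B
    (tandem); ``(+,-)`` -> C (convergent, downstream of both).
    """
    try:
        return _CLASS_TABLE[(left_strand, right_strand)]
    except KeyError:
        raise ValidationError(
            f"invalid strand pair ({left_strand!r}, {right_strand!r})"
        ) from None


_CLASS_TABLE = {
    ("-", "+"): "A",
    ("+", "+"): "B",
    ("-", "-"): "B",
    ("+", "-"): "C",
}


def derive_units(
    genes: Sequence[GeneFeature],
    operon_map: Mapping[str, str] | None = None,
    max_intra_operon_gap: int = DEFAULT_MAX_INTRA_OPERON_GAP,
) -> list:
    """Group sorted genes into transcription units.

    With ``operon_map`` (gene id -> operon id) the grouping follows the map
    verbatim; unmapped genes become singleton units named after the gene.
    Without a map, consecutive same-strand genes whose intergenic gap is at
    most ``max_intra_operon_gap`` bp merge into one unit.  Every gene ends up
    in exactly one unit and ``gene.unit_id`` is set as a side effect.
    """
    genes = list(genes)
    for prev, cur in zip(genes, genes[1:]):
        if cur.start < prev.start:
            raise ValidationError("genes must be sorted by start coordinate")

    if operon_map is not None:
        unknown = set(operon_map) - {g.id for g in genes}
        if unknown:
            raise ValidationError(
                f"operon map names unknown gene ids: {sorted(unknown)}"
            )
        groups: dict[str, list[GeneFeature]] = {}
        order: list[str] = []
        for g in genes:
            key = operon_map.get(g.id, g.id)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(g)
        units = []
        for key in order:
            members = groups[key]
            strands = {g.strand for g in members}
            if len(strands) != 1:
                raise ValidationError(
                    f"operon {key!r}: member genes lie on both strands"
                )
            units.append(
                TranscriptionUnit(
                    unit_id=key,
                    gene_ids=tuple(g.id for g in members),
                    strand=members[0].strand,
                    start=min(g.start for g in members),
                    end=max(g.end for g in members),
                )
            )
        units.sort(key=lambda u: u.start)
    else:
        units = []
        run: list[GeneFeature] = []

        def _close(run: list[GeneFeature]):
            units.append(
                TranscriptionUnit(
                    unit_id=f"TU{len(units) + 1:04d}",
                    gene_ids=tuple(g.id for g in run),
                    strand=run[0].strand,
                    start=run[0].start,
                    end=run[-1].end,
                )
            )

        for g in genes:
            if run and (
                g.strand != run[-1].strand
                or g.start - run[-1].end > max_intra_operon_gap
            ):
                _close(run)
                run = []
            run.append(g)
        if run:
            _close(run)

    _check_unit_overlap(units)
    by_gene = {gid: u.unit_id for u in units for gid in u.gene_ids}
    for g in genes:
        g.unit_id = by_gene[g.id]
    return units


def _check_unit_overlap(units: Sequence[TranscriptionUnit]) -> None:
    for a, b in zip(units, units[1:]):
        if b.start < a.end:
            raise ValidationError(
                f"transcription units overlap: {a.unit_id} "
                f"[{a.start},{a.end}) and {b.unit_id} [{b.start},{b.end})"
            )


def derive_spacers(
    units: Sequence[TranscriptionUnit], genome_length: int, circular: bool
) -> list:
    """Ordered spacers between adjacent units, classified by orientation.

    On a linear genome the two terminal flanks (before the first and after
    the last unit) are reported with ``cls=None`` and excluded from class
    counts; a circular genome instead gets one wrap-around spacer.
    Zero-length spacers (abutting units) are retained.
    """
    units = sorted(units, key=lambda u: u.start)
    _check_unit_overlap(units)
    if units and units[-1].end > genome_length:
        raise ValidationError(
            f"unit {units[-1].unit_id} extends past genome length {genome_length}"
        )

    spacers: list[Spacer] = []
    if not units:
        return [
            Spacer("flank_all", None, None, 0, genome_length, None)
        ]

    n_internal = 0

    def _internal(left: TranscriptionUnit, right: TranscriptionUnit, start, end, wraps):
        nonlocal n_internal
        n_internal += 1
        return Spacer(
            spacer_id=f"sp{n_internal:04d}",
            left_unit=left.unit_id,
            right_unit=right.unit_id,
            start=start,
            end=end,
            cls=classify_spacer(left.strand, right.strand),
            wraps=wraps,
        )

    if not circular:
        spacers.append(
            Spacer("flank_start", None, units[0].unit_id, 0, units[0].start, None)
        )
    for left, right in zip(units, units[1:]):
        spacers.append(_internal(left, right, left.end, right.start, wraps=False))
    if circular:
        spacers.append(
            _internal(
                units[-1], units[0], units[-1].end,
                genome_length + units[0].start, wraps=True,
            )
        )
    else:
        spacers.append(
            Spacer(
                "flank_end", units[-1].unit_id, None,
                units[-1].end, genome_length, None,
            )
        )
    return spacers


@dataclass
class GenomeAnnotation:
    """A genome's genes, derived transcription units and classified spacers."""

    genome_length: int
    circular: bool
    genes: list
    units: list
    spacers: list
    _gene_tree: IntervalTree = field(default=None, repr=False, compare=False)
    _spacer_tree: IntervalTree = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: g.start)
        ids = [g.id for g in self.genes]
        if len(ids) != len(set(ids)):
            seen, dups = set(), set()
            for i in ids:
                (dups if i in seen else seen).add(i)
            raise ValidationError(f"duplicate gene ids: {sorted(dups)}")
        self.genes_by_id = {g.id: g for g in self.genes}
        self.units_by_id = {u.unit_id: u for u in self.units}
        self.spacers_by_id = {s.spacer_id: s for s in self.spacers}
        self._gene_tree = IntervalTree()
        for g in self.genes:
            self._gene_tree.addi(g.start, g.end, g)
        self._spacer_tree = IntervalTree()
        for s in self.spacers:
            if len(s) == 0:
                continue
            if s.wraps:
                self._spacer_tree.addi(s.start, self.genome_length, s)
                if s.end > self.genome_length:
                    self._spacer_tree.addi(0, s.end - self.genome_length, s)
            else:
                self._spacer_tree.addi(s.start, s.end, s)

    def gene_at(self, pos: int):
        """Gene whose body contains ``pos``, leftmost on (rare) overlap."""
        hits = self._gene_tree[pos]
        if not hits:
            return None
        return min(hits, key=lambda iv: iv.begin).data

    def spacer_at(self, pos: int):
        """Spacer containing ``pos``, or None (pos inside a unit span)."""
        hits = self._spacer_tree[pos]
        if not hits:
            return None
        return min(hits, key=lambda iv: iv.begin).data

    def unit_genes(self, unit_id: str) -> list:
        return [self.genes_by_id[g] for g in self.units_by_id[unit_id].gene_ids]

    def class_counts(self) -> dict:
        """Number of internal spacers of each orientation class."""
        counts = {c: 0 for c in SPACER_CLASSES}
        for s in self.spacers:
            if s.cls is not None:
                counts[s.cls] += 1
        return counts


# ---------------------------------------------------------------------------
# GFF3 / TSV input


def read_category_map(source: Union[str, Path, TextIO]) -> dict:
    """Read a 2-column TSV (gene_id, category) into gene_id -> set of tags."""
    close = False
    if isinstance(source, (str, Path)):
        source = open(source)
        close = True
    try:
        out: dict[str, set] = {}
        for ln, line in enumerate(source, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"category map line {ln}: expected 2 tab-separated fields"
                )
            gid, cat = parts
            if cat not in CATEGORIES:
                raise ValidationError(
                    f"category map line {ln}: unknown category {cat!r}"
                )
            out.setdefault(gid, set()).add(cat)
        return out
    finally:
        if close:
            source.close()


def load_annotation(
    gff_stream: Union[str, Path, TextIO],
    category_map: Union[str, Path, TextIO, Mapping, None] = None,
    *,
    genome_length: int | None = None,
    circular: bool = False,
    operon_attr: str = "operon",
    max_intra_operon_gap: int = DEFAULT_MAX_INTRA_OPERON_GAP,
) -> GenomeAnnotation:
    """Load a GFF3 gene annotation and derive units and spacers.

    Accepts a path or an open text stream.  Coordinates are converted from
    GFF3's 1-based inclusive convention to 0-based half-open.  Genome length
    comes from a ``##sequence-region`` directive unless given explicitly.
    Operon membership is taken from the ``operon_attr`` attribute when any
    gene carries it; otherwise units are derived by the same-strand gap rule.
    """
    if isinstance(gff_stream, (str, Path)):
        text = Path(gff_stream).read_text()
    else:
        text = gff_stream.read()

    _prevalidate_gff(text)

    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="error",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        db = None  # directives only: a featureless (or gene-free) annotation
    except ValueError as e:  # gffutils signals duplicate IDs with ValueError
        raise ValidationError(f"GFF3 rejected: {e}") from e

    if isinstance(category_map, Mapping):
        cats = {k: set(v) if not isinstance(v, str) else {v} for k, v in category_map.items()}
    elif category_map is not None:
        cats = read_category_map(category_map)
    else:
        cats = {}

    seqlen = genome_length
    directives = db.directives if db is not None else [
        ln[2:].strip()
        for ln in text.splitlines()
        if ln.startswith("##") and not ln.startswith("###")
    ]
    for directive in directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            if len(parts) >= 4 and seqlen is None:
                seqlen = int(parts[3])

    genes = []
    operon_map: dict[str, str] = {}
    features = db.features_of_type("gene", order_by="start") if db is not None else ()
    for f in features:
        gid = f.id
        name = f.attributes.get("Name", [gid])[0]
        genes.append(
            GeneFeature(
                id=gid,
                name=name,
                start=f.start - 1,
                end=f.end,
                strand=f.strand,
                categories=frozenset(cats.get(gid, ())),
            )
        )
        if operon_attr in f.attributes:
            operon_map[gid] = f.attributes[operon_attr][0]

    if seqlen is None:
        seqlen = max((g.end for g in genes), default=0)

    units = derive_units(
        genes,
        operon_map=operon_map or None,
        max_intra_operon_gap=max_intra_operon_gap,
    )
    spacers = derive_spacers(units, seqlen, circular)
    return GenomeAnnotation(
        genome_length=seqlen, circular=circular,
        genes=genes, units=units, spacers=spacers,
    )


def _prevalidate_gff(text: str) -> None:
    """Raise a line-numbered parse error for structurally broken GFF3 lines."""
    for ln, line in enumerate(io.StringIO(text), 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise GFFParseError(
                f"expected 9 tab-separated columns, got {len(fields)}", ln
            )
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise GFFParseError("coordinates are not integers", ln) from None
        if start < 1 or end < start:
            raise GFFParseError(f"invalid coordinate range {start}..{end}", ln)


# ---------------------------------------------------------------------------
# TSV output / round-trip


def write_unit_table(units: Iterable[TranscriptionUnit], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("unit_id\tstrand\tstart\tend\tgene_ids\n")
        for u in units:
            fh.write(
                f"{u.unit_id}\t{u.strand}\t{u.start}\t{u.end}\t{','.join(u.gene_ids)}\n"
            )


def read_unit_table(path: Union[str, Path]) -> list:
    units = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("unit_id\t"):
            raise ValidationError("unit table: missing header")
        for line in fh:
            uid, strand, start, end, gids = line.rstrip("\n").split("\t")
            units.append(
                TranscriptionUnit(uid, tuple(gids.split(",")), strand, int(start), int(end))
            )
    return units


def write_spacer_table(spacers: Iterable[Spacer], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("spacer_id\tleft_unit\tright_unit\tstart\tend\tclass\twraps\n")
        for s in spacers:
            fh.write(
                f"{s.spacer_id}\t{s.left_unit or '.'}\t{s.right_unit or '.'}\t"
                f"{s.start}\t{s.end}\t{s.cls or '.'}\t{int(s.wraps)}\n"
            )


def read_spacer_table(path: Union[str, Path]) -> list:
    spacers = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("spacer_id\t"):
            raise ValidationError("spacer table: missing header")
        for line in fh:
            sid, lu, ru, start, end, cls, wraps = line.rstrip("\n").split("\t")
            spacers.append(
                Spacer(
                    sid,
                    None if lu == "." else lu,
                    None if ru == "." else ru,
                    int(start),
                    int(end),
                    None if cls == "." else cls,
                    bool(int(wraps)),
                )
            )
    return spacers
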