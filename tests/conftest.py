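import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from selex_regmap.annotation import (
    GeneFeature,
    GenomeAnnotation,
    derive_spacers,
    derive_units,
)

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


def make_genes(strands, gene_len=300, gap=200, offset=100):
    """Evenly laid out single-gene-per-unit toy genes with given strands."""
    genes = []
    pos = offset
    for i, s in enumerate(strands):
        genes.append(
            GeneFeature(
                id=f"g{i + 1}", name=f"g{i + 1}", start=pos, end=pos + gene_len, strand=s
            )
        )
        pos += gene_len + gap
    return genes


def make_annotation(strands, gene_len=300, gap=200, offset=100, circular=False,
                    categories=None):
    """Toy annotation: one gene per unit, spacers classified by strand pairs.

    ``categories`` maps gene id -> set of category tags.
    """
    genes = make_genes(strands, gene_len, gap, offset)
    if categories:
        for g in genes:
            if g.id in categories:
                g.categories = frozenset(categories[g.id])
    length = genes[-1].end + offset if genes else 1000
    units = derive_units(genes)
    spacers = derive_spacers(units, length, circular)
    return GenomeAnnotation(
        genome_length=length, circular=circular,
        genes=genes, units=units, spacers=spacers,
    )


def probe_frame(ratios, start0=0, length=60, spacing=105):
    """Normalized-shape probe table with given ratios (cy3=1, cy5=ratio)."""
    starts = start0 + spacing * np.arange(len(ratios))
    return pd.DataFrame(
        {
            "probe_id": [f"p{i}" for i in range(len(ratios))],
            "chrom": "genome",
            "start": starts,
            "end": starts + length,
            "cy3": 1.0,
            "cy5": np.asarray(ratios, dtype=float),
            "usable": True,
            "ratio": np.asarray(ratios, dtype=float),
        }
    )


@pytest.fixture
def divergent_pair():
    """Two divergent genes: a single internal class-A spacer."""
    return make_annotation(["-", "+"])
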