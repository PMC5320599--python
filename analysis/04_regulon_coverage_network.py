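#!/usr/bin/env python
"""Reference-regulon coverage and the downstream TF network.

Compares the predicted target-gene set with a reference regulon list
(emulating a curated database / ChIP-chip target set), reports the fold
expansion of the predicted regulon over the reference, and exports the
regulator -> transcription-factor network as TSV and DOT.
"""

from pathlib import Path

from selex_regmap import annotation as ann_mod
from selex_regmap import chip_signal as sig
from selex_regmap import synthetic_data as sd
from selex_regmap import target_prediction as tp

SIM = Path("results/sim")
OUT = Path("results/network")


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    annotation = ann_mod.load_annotation(SIM / "genome.gff3", SIM / "categories.tsv")
    probes = sig.normalize(sig.read_probe_table(SIM / "probes.tsv"))
    sites = tp.locate_sites(sig.call_peaks(probes, cutoff=10), annotation)

    predicted = tp.predicted_target_genes(sites, annotation)
    reference = sd.read_regulon_list(SIM / "reference_regulon.txt")
    stat = tp.regulon_overlap(predicted, reference, "reference")
    tp.overlaps_table([stat]).to_csv(OUT / "regulon_overlap.tsv", sep="\t", index=False)
    print(
        f"reference regulon: {stat.overlap} of {stat.reference_size} covered "
        f"({stat.percent}%)"
    )
    tc = tp.count_targets(sites)
    fold = tp.fold_expansion(tc.max_targets, stat.reference_size)
    print(
        f"predicted regulon expands {fold}-fold over the reference "
        f"({tc.max_targets} vs {stat.reference_size})"
    )

    edges = tp.build_tf_network(sites, annotation, regulator="lrp")
    tp.write_network_tsv(edges, OUT / "tf_network.tsv")
    tp.write_network_dot(edges, OUT / "tf_network.dot")
    self_loop = ("lrp", "lrp") in edges
    print(f"TF network: {len(edges)} TF genes under direct control (self-loop: {self_loop})")


if __name__ == "__main__":
    main()
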