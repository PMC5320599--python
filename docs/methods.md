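# Methods

## Model and assumptions

The pipeline analyses a two-channel tiling-array readout of an in vitro
binding screen. Its statistical model is deliberately minimal, mirroring
the assay design it targets:

* The reference channel (Cy3, the unselected genomic library) is assumed to
  have bounded probe-to-probe fluctuation (below two-fold). Under that
  assumption the per-probe ratio `Cy5/Cy3` cancels probe affinity and
  labelling effects, and no further normalization (loess, quantile,
  background subtraction) is applied. `check_reference_fluctuation` reports
  `max(Cy3)/min(Cy3)` so a violated assumption is surfaced as a warning —
  never silently corrected.
* Binding is detected by a plain ratio threshold. A peak is a maximal run
  of probes with ratio ≥ cutoff; `max_gap` (default 0) sub-threshold probes
  may be tolerated inside a run for robustness studies, but the default is
  strict because no merging rule is part of the screen's published
  procedure. Probes with `Cy3 = 0` are treated as array failures and
  dropped, not imputed; a dropped probe leaves a hole that a run continues
  across (the two flanking probes become adjacent).
* The peak summit is the midpoint of the maximum-ratio member probe
  (leftmost on ties), and all downstream location calls use the summit
  alone. A peak may straddle a spacer/gene boundary; using one coordinate
  guarantees each site receives exactly one location class.

## Site classification and target counting

Transcription units are taken verbatim from an operon map when provided
(the realistic case — operon structure is assumed known); otherwise
consecutive same-strand genes with intergenic gap ≤ 50 bp are merged. Unit
spans must not overlap; overlapping units are rejected rather than resolved
by guesswork.

Spacers between adjacent units are classified purely from the flanking
strands: `(-,+) → A`, `(+,+)/(-,-) → B`, `(+,-) → C`. On a linear genome
the two terminal flanks have only one flanking unit, are unclassifiable,
and are excluded from all class counts (sites landing there are reported
with location `edge` and tallied nowhere); a circular genome instead has a
single wrap-around spacer. A summit inside a gene body is ORF-internal by
the half-open convention (the gene's first base belongs to the gene, the
base before it to the spacer). A summit inside a unit span but between two
member genes of an operon is counted as ORF-internal, hosted by the nearest
member gene — such intra-operon sites are inside transcribed territory and
assigning them a spacer class would be wrong.

Candidate targets per site: A → both flanking units; B → the unit reading
away from the spacer (for `(+,+)` the right unit, for `(-,-)` the left,
forced by strand geometry); C and ORF → none. Hence
`min_targets = n_A + n_B` and `max_targets = 2·n_A + n_B`; the bracket
width always equals `n_A`.

Coverage percentages (category tables, reference-regulon overlap) are
rounded half-up to integers, and fold expansions half-up to one decimal, so
published tables reproduce digit-for-digit. Category summaries expand
candidate units to member genes before tagging, because published category
tables count genes, not units.

## Synthetic-data generator

The generator emulates the assay's design parameters: 60-bp probes at
105-bp spacing, a reference channel drawn lognormal (σ = 0.1 by default)
and clipped to ±1.4× the mean — the clip enforces the two-fold fluctuation
bound by construction (1.4² = 1.96 < 2) — and 20-fold multiplicative
enrichment at planted sites. Genes (600–1200 bp) are laid left to right
with 250–400 bp intergenic gaps; gaps exceed the 50-bp operon-merge
threshold, so each gene is its own unit and spacer classes follow directly
from the strand pattern. Planted sites sit at spacer midpoints (classes
A/B/C) or gene midpoints (ORF), recording their intended class and targets.

The test channel is `Cy5 = Cy3 · (1 + (E − 1)·f)` where `f` is the probe's
overlap fraction with the planted 200-bp site window (a stand-in for
bound-fragment pulldown coverage: the published screen selected 200–300-bp
fragments), and `Cy5 = Cy3 · lognormal(1, σ)` elsewhere. Scaling by overlap
fraction rather than a binary overlap flag makes fully covered probes the
ratio maximum, so the called summit always lies within 70 bp of the planted
coordinate — inside the one-probe-spacing (105 bp) recovery tolerance. In
the noise-free limit fully covered probes sit exactly at the enrichment
ratio and background probes exactly at 1.

One integer seed drives three spawned random streams (genome layout, site
planting, channel noise), so a single seed reproduces any fixture
byte-for-byte while the separate pipeline stages remain independently
callable.

The study-scale fixture (`published_screen_config`) repeats the strand block
`(-, +, +, -)` 80 times: each block contributes spacer classes A, B, C plus
a B between blocks, giving an inventory of 80 A / 159 B / 80 C spacers —
enough to plant the published composition of 78 A, 140 B, 10 C and 86
ORF-internal sites (314 in all) on a ~392-kb genome tiled by ~3,700 probes.
This runs in about a second; no larger problem size is needed because every
downstream statistic is a deterministic function of the planted counts.

### What the simulation does and does not capture

It captures the features the analysis logic depends on: tiling geometry,
bounded reference fluctuation, ratio plateaus at bound sites, and the
orientation bookkeeping. It does not model DNA sequence (no binding motif —
none is assumed by the analysis), dye bias, spatial array artefacts,
cross-hybridisation, overlapping genes, or selection-round kinetics.
Passing recovery tests therefore demonstrate the correctness of the
pipeline's bookkeeping and thresholding under the stated signal model, not
peak-calling power on real arrays with correlated noise.

## Numerical and design choices

* Internal coordinates are 0-based half-open; GFF3 is read/written 1-based
  inclusive, BED 0-based half-open.
* Peak-calling ties at the summit go to the leftmost probe — deterministic
  output matters more than unbiased tie-breaking at one probe's resolution.
* GFF3 written by the generator carries an `operon` attribute naming each
  gene's unit, so re-loading reproduces the derived units verbatim
  (round-trip identity is tested).
* `evaluate_recovery` defines precision as 1.0 when no sites are called
  (vacuous truth) and matches each planted site to its nearest called
  summit within tolerance.
* All outputs are plain-text TSV/BED/GFF3/DOT/JSON and byte-stable under a
  fixed seed and configuration; the JSON run log records every parameter
  that affects any output.

## Known limitations

* Overlapping genes (common on opposite strands of real bacterial genomes)
  are rejected at unit derivation rather than handled; real annotations may
  need pre-flattening.
* Activation-versus-repression direction, effector-dependent target
  switching and promoter architecture are out of scope — the screen
  identifies binding only.
* The relaxed-cutoff rescue (3.0) is exposed but no significance model is
  attached to either threshold; the ratio cutoff is the screen's own
  published procedure.
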