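"""Two-channel tiling-array signal: per-probe ratio normalization, peak calling.

The screen hybridises a factor-bound DNA pool (test channel, Cy5) against the
unselected genomic library (reference channel, Cy3) on a tiling array of
short probes.  Because the reference library is designed to have bounded
probe-to-probe fluctuation (below two-fold), dividing test by reference probe
intensity is the whole normalization — no loess, no background model.  Peaks
are simply maximal runs of probes whose Cy5/Cy3 ratio clears a cut-off
(10 strict, 3.0 relaxed are the conventional settings).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .errors import ValidationError

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "cy3", "cy5"]

#: Strict ratio cut-off for peak calling.
DEFAULT_CUTOFF = 10.0
#: Relaxed cut-off used to rescue weaker known targets.
RELAXED_CUTOFF = 3.0


@dataclass(frozen=True)
class ProbeRecord:
    """One tiling probe with raw two-channel intensities and its ratio."""

    probe_id: str
    start: int
    end: int
    cy3: float
    cy5: float
    ratio: float | None  # None when cy3 == 0 (unusable probe)

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class Peak:
    """A called binding peak: a run of above-cutoff probes.

    ``summit`` is the midpoint of the maximum-ratio member probe (leftmost on
    ties) — the single coordinate downstream location calls are based on.
    """

    peak_id: str
    start: int
    end: int
    summit: int
    height: float
    n_probes: int


def read_probe_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read the tab-delimited probe table (header required)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"probe table missing columns: {missing}")
    return df


def write_probe_table(df: pd.DataFrame, path: Union[str, Path]) -> None:
    cols = [c for c in PROBE_COLUMNS if c in df.columns] + [
        c for c in df.columns if c not in PROBE_COLUMNS
    ]
    df[cols].to_csv(path, sep="\t", index=False)


def normalize(probes: pd.DataFrame) -> pd.DataFrame:
    """Per-probe test/reference ratio; the reference channel is the normalizer.

    Returns a copy sorted by start with ``ratio`` (cy5/cy3) and ``usable``
    columns.  Probes with cy3 == 0 are flagged unusable (array failure) and
    carry ratio NaN; they are excluded from peak calling, not imputed.
    """
    if len(probes) == 0:
        raise ValidationError("probe table is empty")
    missing = [c for c in PROBE_COLUMNS if c not in probes.columns]
    if missing:
        raise ValidationError(f"probe table missing columns: {missing}")
    if (probes["cy3"] < 0).any() or (probes["cy5"] < 0).any():
        raise ValidationError("negative channel intensity")

    out = probes.sort_values("start", kind="mergesort").reset_index(drop=True).copy()
    usable = out["cy3"] > 0
    out["usable"] = usable
    out["ratio"] = np.where(usable, out["cy5"] / out["cy3"].where(usable), np.nan)
    return out


def probe_records(normalized: pd.DataFrame) -> list:
    """View a normalized table as a list of :class:`ProbeRecord`."""
    return [
        ProbeRecord(
            probe_id=str(r.probe_id),
            start=int(r.start),
            end=int(r.end),
            cy3=float(r.cy3),
            cy5=float(r.cy5),
            ratio=None if not r.usable else float(r.ratio),
        )
        for r in normalized.itertuples()
    ]


def check_reference_fluctuation(probes: pd.DataFrame) -> float:
    """Max/min reference-channel intensity over probes with cy3 > 0.

    The array design promises this stays below two-fold; callers should warn
    when the returned value is >= 2 (the ratio normalization then no longer
    cancels probe effects cleanly).
    """
    cy3 = probes.loc[probes["cy3"] > 0, "cy3"]
    if len(cy3) == 0:
        raise ValidationError("no probes with positive reference intensity")
    return float(cy3.max() / cy3.min())


def call_peaks(
    probes: pd.DataFrame, cutoff: float = DEFAULT_CUTOFF, max_gap: int = 0
) -> list:
    """Call peaks as maximal runs of probes with ratio >= cutoff.

    Up to ``max_gap`` consecutive sub-threshold probes are tolerated inside a
    run (default 0: strict runs); runs always start and end on an
    above-threshold probe.  ``n_probes`` counts the above-threshold members.
    Peaks come back in genomic order with disjoint intervals.
    """
    if cutoff <= 0:
        raise ValidationError(f"cutoff must be positive, got {cutoff}")
    if max_gap < 0:
        raise ValidationError(f"max_gap must be >= 0, got {max_gap}")
    if "ratio" not in probes.columns:
        raise ValidationError("probes are not normalized (no ratio column)")

    use = probes.loc[probes["usable"]] if "usable" in probes.columns else probes
    starts = use["start"].to_numpy()
    ends = use["end"].to_numpy()
    ratios = use["ratio"].to_numpy(dtype=float)

    peaks: list[Peak] = []
    run: list[int] = []  # indices of above-threshold probes in current run
    gap = 0

    def _close(run: Sequence[int]):
        heights = ratios[list(run)]
        best = int(np.argmax(heights))  # argmax is leftmost on ties
        i_best = run[best]
        peaks.append(
            Peak(
                peak_id=f"peak{len(peaks) + 1:04d}",
                start=int(starts[run[0]]),
                end=int(ends[run[-1]]),
                summit=int((starts[i_best] + ends[i_best]) // 2),
                height=float(heights[best]),
                n_probes=len(run),
            )
        )

    for i, r in enumerate(ratios):
        if r >= cutoff:
            run.append(i)
            gap = 0
        elif run:
            gap += 1
            if gap > max_gap:
                _close(run)
                run, gap = [], 0
    if run:
        _close(run)
    return peaks


def write_peaks_bed(
    peaks: Sequence[Peak], path: Union[str, Path], chrom: str = "genome"
) -> None:
    """BED6 peak export; score is height x10 capped at 1000, strand '.'."""
    with open(path, "w") as fh:
        for p in peaks:
            score = min(1000, int(round(p.height * 10)))
            fh.write(f"{chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t.\n")


def write_peaks_tsv(peaks: Sequence[Peak], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tstart\tend\tsummit\theight\tn_probes\n")
        for p in peaks:
            fh.write(
                f"{p.peak_id}\t{p.start}\t{p.end}\t{p.summit}\t{p.height:.6g}\t{p.n_probes}\n"
            )
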