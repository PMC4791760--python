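"""Interval algebra for panel design and window generation.

Coordinates are 0-based half-open (BED convention): an interval ``[start, end)``
has length ``end - start``. Target regions shorter than a minimum length are
padded symmetrically about their center before probe-style merging; depth
analysis then tiles each target with fixed-size sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

WINDOW_SIZE = 30
WINDOW_STEP = 25


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval has empty chromosome name")
        if self.start < 0:
            raise ValueError(f"interval {self.chrom}:{self.start}-{self.end} has negative start")
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Window:
    """A depth-analysis window: an interval plus its reference GC fraction."""

    interval: GenomicInterval
    gc: float = float("nan")
    origin_target: int = -1

    def __post_init__(self) -> None:
        if self.gc == self.gc and not 0.0 <= self.gc <= 1.0:  # NaN allowed (not yet annotated)
            raise ValueError(f"window {self.interval} GC {self.gc} outside [0, 1]")


@dataclass
class Panel:
    """A capture panel: ordered merged targets plus sex-marker gene sets.

    ``gene_of`` maps each target index to a gene symbol; ``x_markers`` and
    ``y_markers`` name the uniquely-mapping chrX/chrY genes whose windows feed
    the sex-dosage ratios (homologous/pseudoautosomal targets stay out).
    """

    targets: list[GenomicInterval]
    gene_of: dict[int, str] = field(default_factory=dict)
    x_markers: set[str] = field(default_factory=set)
    y_markers: set[str] = field(default_factory=set)

    def gene(self, target_index: int) -> str:
        return self.gene_of.get(target_index, "")


def pad_and_merge(
    targets: Iterable[GenomicInterval], min_len: int = 100
) -> list[GenomicInterval]:
    """Pad sub-``min_len`` targets to ``min_len`` about their center, then merge overlaps.

    An odd padding deficit puts the extra base on the end side; padding never
    extends below coordinate 0 (the clipped amount shifts to the right).
    Output is sorted and non-overlapping, and covers every input base.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    padded = []
    for iv in targets:
        deficit = min_len - iv.length
        if deficit > 0:
            left = deficit // 2
            right = deficit - left
            start = iv.start - left
            if start < 0:
                right += -start
                start = 0
            padded.append(GenomicInterval(iv.chrom, start, iv.end + right))
        else:
            padded.append(iv)
    padded.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in padded:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def make_windows(
    target: GenomicInterval,
    win: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    origin_target: int = -1,
) -> list[Window]:
    """Tile a target with ``win``-bp windows at ``step``-bp spacing.

    Targets shorter than ``win`` are padded equally from both ends to ``win``
    and yield a single window; otherwise only full-length windows are emitted
    (a sub-``win`` tail is dropped).
    """
    if win < 1 or step < 1:
        raise ValueError("win and step must be >= 1")
    if target.length < win:
        deficit = win - target.length
        left = deficit // 2
        right = deficit - left
        start = target.start - left
        if start < 0:
            right += -start
            start = 0
        return [Window(GenomicInterval(target.chrom, start, start + win), origin_target=origin_target)]
    n = (target.length - win) // step + 1
    return [
        Window(
            GenomicInterval(target.chrom, target.start + k * step, target.start + k * step + win),
            origin_target=origin_target,
        )
        for k in range(n)
    ]


def window_span(n_windows: int, win: int = WINDOW_SIZE, step: int = WINDOW_STEP) -> int:
    """Genomic span of ``n_windows`` consecutive windows: ``(n-1)*step + win``."""
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    return (n_windows - 1) * step + win


def window_gc(window: GenomicInterval, sequence: str) -> float:
    """GC fraction of a window's reference sequence, case-insensitive.

    Ambiguous bases (N) count in the denominator only.
    """
    if len(sequence) != window.length:
        raise ValueError(
            f"sequence length {len(sequence)} does not match window {window} length {window.length}"
        )
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def panel_windows(panel: Panel, win: int = WINDOW_SIZE, step: int = WINDOW_STEP) -> list[Window]:
    """All windows over a panel's targets, in target order."""
    out: list[Window] = []
    for i, target in enumerate(panel.targets):
        out.extend(make_windows(target, win=win, step=step, origin_target=i))
    return out


def annotate_gc_from_fasta(windows: Sequence[Window], fasta_path: str) -> list[Window]:
    """Fill each window's GC fraction from an indexed FASTA reference."""
    from pyfaidx import Fasta

    ref = Fasta(fasta_path)
    out = []
    for w in windows:
        seq = str(ref[w.interval.chrom][w.interval.start : w.interval.end])
        out.append(Window(w.interval, gc=window_gc(w.interval, seq), origin_target=w.origin_target))
    return out


# ---------------------------------------------------------------------------
# BED / TSV interfaces


def read_bed(path: str) -> tuple[list[GenomicInterval], dict[int, str]]:
    """Read a 3+ column BED; column 4 (if present) is taken as the gene symbol."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    intervals, genes = [], {}
    for i, row in enumerate(df.itertuples(index=False)):
        intervals.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2])))
        if len(row) > 3 and isinstance(row[3], str):
            genes[i] = row[3]
    return intervals, genes


def write_bed(intervals: Iterable[GenomicInterval], path: str, genes: dict[int, str] | None = None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        row = [iv.chrom, iv.start, iv.end]
        if genes is not None:
            row.append(genes.get(i, "."))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_windows_tsv(windows: Sequence[Window], path: str) -> None:
    pd.DataFrame(
        {
            "chrom": [w.interval.chrom for w in windows],
            "start": [w.interval.start for w in windows],
            "end": [w.interval.end for w in windows],
            "gc": [w.gc for w in windows],
            "target_index": [w.origin_target for w in windows],
        }
    ).to_csv(path, sep="\t", index=False)


def read_windows_tsv(path: str) -> list[Window]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        Window(
            GenomicInterval(r.chrom, int(r.start), int(r.end)),
            gc=float(r.gc),
            origin_target=int(r.target_index),
        )
        for r in df.itertuples(index=False)
    ]
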