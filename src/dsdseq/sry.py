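"""SRY-positivity detection in samples whose dosage classifies them as XX.

Translocation of the Y-linked sex-determining gene SRY onto another
chromosome causes testicular development in a 46,XX individual. Upstream,
XX samples are realigned to a chrY-free reference, unmapped read pairs are
remapped to chrY, and per-base depth over the SRY target is tabulated; this
module consumes that depth table and calls positivity from coverage breadth
and depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import GenomicInterval


@dataclass
class SRYEvidence:
    """Coverage evidence over the SRY target.

    ``breadth`` is the fraction of target bases at or above ``depth_floor``.
    """

    gene_interval: GenomicInterval
    breadth: float
    mean_depth: float
    n_reads: int = 0
    depth_floor: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.breadth <= 1.0:
            raise ValueError("breadth must be in [0, 1]")
        if self.mean_depth < 0:
            raise ValueError("mean depth must be non-negative")


@dataclass
class SRYCall:
    positive: bool
    rationale: str
    evidence: SRYEvidence
    # confirmation PCR products (whole-gene / 5' fragment), report text only
    pcr_note: str = "confirmation primers: whole-gene 735 bp; first 200 bp 257 bp"


def evidence_from_depths(
    gene_interval: GenomicInterval,
    depths: np.ndarray,
    depth_floor: float = 10.0,
    n_reads: int = 0,
) -> SRYEvidence:
    """Summarize a per-base depth vector over the SRY target."""
    depths = np.asarray(depths, dtype=float)
    if len(depths) != gene_interval.length:
        raise ValueError(
            f"depth vector length {len(depths)} does not match target {gene_interval}"
        )
    return SRYEvidence(
        gene_interval=gene_interval,
        breadth=float((depths >= depth_floor).mean()),
        mean_depth=float(depths.mean()),
        n_reads=n_reads,
        depth_floor=depth_floor,
    )


def detect_sry(
    evidence: SRYEvidence,
    karyotype_label: str = "XX",
    breadth_min: float = 0.9,
    depth_floor: float = 10.0,
) -> SRYCall:
    """Call SRY-positivity for an XX sample from coverage evidence.

    Positive iff the fraction of target bases covered at >= ``depth_floor``
    reaches ``breadth_min``. Applying the check to a non-XX sample is an
    error: XY/XXY samples carry SRY constitutively.
    """
    if karyotype_label != "XX":
        raise ValueError("SRY check applies to XX samples only")
    if evidence.depth_floor != depth_floor:
        raise ValueError(
            f"evidence was summarized at depth floor {evidence.depth_floor}, not {depth_floor}"
        )
    positive = evidence.breadth >= breadth_min
    rationale = (
        f"breadth {evidence.breadth:.3f} at >= {depth_floor:g}x "
        f"({'>=' if positive else '<'} {breadth_min:g}); "
        f"mean depth {evidence.mean_depth:.1f}x"
    )
    return SRYCall(positive=positive, rationale=rationale, evidence=evidence)


def read_sry_depth_tsv(path: str, gene_interval: GenomicInterval) -> np.ndarray:
    """Read a (pos, depth) TSV covering the SRY target; absent positions are 0."""
    df = pd.read_csv(path, sep="\t")
    depths = np.zeros(gene_interval.length)
    pos = df.iloc[:, 0].to_numpy(dtype=int) - gene_interval.start
    ok = (pos >= 0) & (pos < gene_interval.length)
    depths[pos[ok]] = df.iloc[:, 1].to_numpy(dtype=float)[ok]
    return depths
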