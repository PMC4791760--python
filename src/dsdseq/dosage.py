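"""Autosome-normalized sex-chromosome dosage and karyotype classification.

After GC correction, the trimmed mean depth of all autosomal windows (chrATO)
becomes the baseline; mean depth over designated chrX- and chrY-marker
windows divided by that baseline gives the dosage ratios chrX/chrATO and
chrY/chrATO. A sample is assigned the sex-chromosome complement of the
nearest centroid in (x_ratio, y_ratio) space.

Default centroids come from empirical targeted-capture cluster means: one X
copy 0.5134, two X copies 1.0188, one Y copy 0.4160 (capture/mapping
efficiency on chrY pulls this below the theoretical 0.5), null Y 0.0031;
XXX/XYY are linear extrapolations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gcnorm import DepthMatrix
from .regions import Panel

ONE_X = 0.5134
TWO_X = 1.0188
ONE_Y = 0.4160
NULL_Y = 0.0031

DEFAULT_CENTROIDS: dict[str, tuple[float, float]] = {
    "XX": (TWO_X, NULL_Y),
    "XY": (ONE_X, ONE_Y),
    "XXY": (TWO_X, ONE_Y),
    "XO": (ONE_X, NULL_Y),
    "XXX": (1.53, NULL_Y),
    "XYY": (ONE_X, 0.83),
}


@dataclass
class DosageProfile:
    baseline_ato: float
    x_ratio: float | None
    y_ratio: float | None
    n_windows_used: dict[str, int]


@dataclass
class KaryotypeCall:
    label: str
    centroid_distance: float
    second_distance: float


def autosomal_baseline(corrected: np.ndarray, trim: float = 0.05) -> float:
    """Mean autosomal window depth after discarding both quantile tails.

    Values strictly below the ``trim`` quantile or above the ``1 - trim``
    quantile are excluded before averaging (trim 0 = plain mean).
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.size < 100:
        raise ValueError(f"only {corrected.size} autosomal windows; need >= 100")
    if trim > 0:
        lo, hi = np.quantile(corrected, [trim, 1.0 - trim])
        kept = corrected[(corrected >= lo) & (corrected <= hi)]
    else:
        kept = corrected
    baseline = float(kept.mean())
    if baseline <= 0:
        raise ValueError("autosomal baseline is not positive")
    return baseline


def _marker_mask(dm: DepthMatrix, panel: Panel, markers: set[str]) -> np.ndarray:
    return np.array([panel.gene(w.origin_target) in markers for w in dm.windows])


def sex_dosage(
    dm: DepthMatrix, sample: str, panel: Panel, baseline: float, trim: float = 0.05
) -> DosageProfile:
    """Dosage ratios for one sample: marker-window means over the autosomal baseline.

    Windows flagged low-confidence during GC correction are excluded. A
    chromosome with zero usable marker windows reports its ratio as missing.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if dm.corrected is None:
        raise ValueError("matrix is not GC-corrected")
    i = dm.sample_index(sample)
    usable = ~dm.low_confidence[i] if dm.low_confidence is not None else np.ones(len(dm.windows), bool)
    counts: dict[str, int] = {}
    ratios: dict[str, float | None] = {}
    for key, markers in (("chrX", panel.x_markers), ("chrY", panel.y_markers)):
        mask = _marker_mask(dm, panel, markers) & usable
        counts[key] = int(mask.sum())
        ratios[key] = float(dm.corrected[i, mask].mean() / baseline) if mask.any() else None
    return DosageProfile(
        baseline_ato=baseline, x_ratio=ratios["chrX"], y_ratio=ratios["chrY"], n_windows_used=counts
    )


def autosomal_mask(dm: DepthMatrix) -> np.ndarray:
    chroms = dm.chroms
    return (chroms != "chrX") & (chroms != "chrY") & (chroms != "X") & (chroms != "Y")


def classify_karyotype(
    profile: DosageProfile,
    centroids: dict[str, tuple[float, float]] | None = None,
    ambiguity_radius: float = 0.15,
    margin: float = 0.05,
) -> KaryotypeCall:
    """Nearest-centroid karyotype assignment in (x_ratio, y_ratio) space.

    The call is ``ambiguous`` when the winning centroid is farther than
    ``ambiguity_radius`` or the two best distances differ by less than
    ``margin``.
    """
    if profile.x_ratio is None or profile.y_ratio is None:
        raise ValueError("dosage unavailable: a sex-chromosome ratio is missing")
    table = centroids if centroids else DEFAULT_CENTROIDS
    if not table:
        raise ValueError("no centroids supplied")
    point = np.array([profile.x_ratio, profile.y_ratio])
    labels = list(table)
    dists = np.array([np.hypot(*(point - np.array(table[k]))) for k in labels])
    order = np.argsort(dists)
    best, second = order[0], (order[1] if len(order) > 1 else order[0])
    d_best = float(dists[best])
    d_second = float(dists[second])
    label = labels[best]
    if d_best > ambiguity_radius or (len(order) > 1 and d_second - d_best < margin):
        label = "ambiguous"
    return KaryotypeCall(label=label, centroid_distance=d_best, second_distance=d_second)


def karyotype_batch(
    dm: DepthMatrix,
    panel: Panel,
    trim: float = 0.05,
    centroids: dict[str, tuple[float, float]] | None = None,
    ambiguity_radius: float = 0.15,
    margin: float = 0.05,
) -> dict[str, tuple[DosageProfile, KaryotypeCall]]:
    """Dosage + karyotype for every sample of a GC-corrected batch."""
    auto = autosomal_mask(dm)
    out = {}
    for i, sample in enumerate(dm.samples):
        usable = auto.copy()
        if dm.low_confidence is not None:
            usable &= ~dm.low_confidence[i]
        baseline = autosomal_baseline(dm.corrected[i, usable], trim=trim)
        profile = sex_dosage(dm, sample, panel, baseline, trim=trim)
        call = classify_karyotype(
            profile, centroids=centroids, ambiguity_radius=ambiguity_radius, margin=margin
        )
        out[sample] = (profile, call)
    return out


def plot_dosage(results: dict[str, tuple[DosageProfile, KaryotypeCall]], path: str) -> None:
    """Scatter of (chrX/chrATO, chrY/chrATO) colored by karyotype call."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    labels = sorted({c.label for _, c in results.values()})
    for lab in labels:
        xs = [p.x_ratio for p, c in results.values() if c.label == lab]
        ys = [p.y_ratio for p, c in results.values() if c.label == lab]
        ax.scatter(xs, ys, label=lab, s=18)
    ax.set_xlabel("chrX / chrATO")
    ax.set_ylabel("chrY / chrATO")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
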