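"""GC-bias correction of per-window depths by LOWESS regression.

For each sample, depth is regressed on window GC fraction with LOWESS; the
regression value divided by the sample's mean window depth (the baseline)
gives a per-window correction factor, and each window's depth is divided by
its factor. Correction redistributes depth across the GC range without
rescaling the sample globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .regions import Window

MIN_WINDOWS_FOR_FIT = 30


@dataclass
class GCModel:
    """Per-sample LOWESS depth-vs-GC model.

    ``fitted`` is the smoothed expected depth at each window's GC;
    ``baseline`` the sample mean raw depth; ``factor = fitted / baseline``.
    """

    fitted: np.ndarray
    baseline: float
    factor: np.ndarray
    span: float


@dataclass
class DepthMatrix:
    """Samples x windows depth matrix for one batch.

    ``raw`` holds observed window depths; ``corrected`` is filled by
    :func:`correct_matrix`. ``low_confidence`` flags windows whose correction
    factor fell below the divisor floor for a given sample; flagged cells are
    excluded from dosage baselines downstream.
    """

    samples: list[str]
    windows: list[Window]
    raw: np.ndarray
    corrected: np.ndarray | None = None
    low_confidence: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.shape != (len(self.samples), len(self.windows)):
            raise ValueError(
                f"raw shape {self.raw.shape} != ({len(self.samples)}, {len(self.windows)})"
            )
        if (self.raw < 0).any():
            raise ValueError("raw depths must be non-negative")

    @property
    def gc(self) -> np.ndarray:
        return np.array([w.gc for w in self.windows])

    @property
    def chroms(self) -> np.ndarray:
        return np.array([w.interval.chrom for w in self.windows])

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(f"sample {sample!r} not in batch") from None


def fit_gc_model(gc: np.ndarray, depth: np.ndarray, span: float = 0.3, iters: int = 2) -> GCModel:
    """Fit the LOWESS depth-on-GC model for one sample.

    Parameters
    ----------
    gc, depth : arrays of equal length (per window).
    span : LOWESS fraction of points per local fit.
    iters : robustness (re-weighting) iterations.
    """
    gc = np.asarray(gc, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if gc.shape != depth.shape:
        raise ValueError("gc and depth must have the same length")
    if not (depth > 0).any():
        raise ValueError("sample has no coverage")
    if (depth > 0).sum() < MIN_WINDOWS_FOR_FIT or len(gc) * span < 2:
        raise ValueError(
            f"too few covered windows ({int((depth > 0).sum())}) to support a LOWESS fit"
        )
    fitted = lowess(depth, gc, frac=span, it=iters, xvals=gc)
    baseline = float(depth.mean())
    return GCModel(fitted=fitted, baseline=baseline, factor=fitted / baseline, span=span)


def correct_sample(
    depth: np.ndarray, model: GCModel, floor: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Divide each window's depth by its GC factor (clamped below at ``floor``).

    Returns ``(corrected, flagged)`` where ``flagged`` marks windows whose
    factor fell below the floor (low-confidence correction).
    """
    depth = np.asarray(depth, dtype=float)
    if depth.shape != model.factor.shape:
        raise ValueError("depth and model were fit on different windows")
    flagged = model.factor < floor
    corrected = depth / np.maximum(model.factor, floor)
    return corrected, flagged


def correct_matrix(dm: DepthMatrix, span: float = 0.3, floor: float = 0.1) -> DepthMatrix:
    """GC-correct every sample in a batch in place (per-sample models) and return it."""
    gc = dm.gc
    corrected = np.empty_like(dm.raw)
    flagged = np.zeros(dm.raw.shape, dtype=bool)
    for i in range(len(dm.samples)):
        model = fit_gc_model(gc, dm.raw[i], span=span)
        corrected[i], flagged[i] = correct_sample(dm.raw[i], model, floor=floor)
    dm.corrected = corrected
    dm.low_confidence = flagged
    return dm


# ---------------------------------------------------------------------------
# TSV interface: header row of sample IDs, rows keyed chrom:start-end.


def write_depth_tsv(dm: DepthMatrix, path: str, which: str = "raw") -> None:
    mat = dm.raw if which == "raw" else dm.corrected
    if mat is None:
        raise ValueError("corrected matrix not computed")
    keys = [str(w.interval) for w in dm.windows]
    pd.DataFrame(mat.T, index=pd.Index(keys, name="window"), columns=dm.samples).to_csv(
        path, sep="\t"
    )


def read_depth_tsv(path: str, windows: list[Window]) -> DepthMatrix:
    """Read a depth matrix keyed by chrom:start-end; rows must match ``windows``."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    keys = [str(w.interval) for w in windows]
    if list(df.index) != keys:
        raise ValueError("depth matrix rows do not match the window list")
    return DepthMatrix(samples=list(df.columns), windows=windows, raw=df.to_numpy().T)
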