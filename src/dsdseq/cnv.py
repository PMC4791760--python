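"""Batch QC, negative-binomial calibration, HMM copy-number calling and segmentation.

Within a batch of GC-corrected samples, each window's depth across samples is
fit with a negative binomial (method of moments); a sample's per-window
depth/batch-mean ratios then drive a 5-state (copy number 0-4) hidden Markov
model decoded by Viterbi, and maximal runs of a non-expected state with at
least ``min_windows`` consecutive supporting windows become CNV calls. With
the default 30-bp/25-bp window geometry and 5 supporting windows the smallest
reportable call spans 130 bp.

True CNV breakpoints can lie anywhere between the terminal base inside the
called windows and the adjacent base of the flanking normal windows, so each
call carries both inner (window-bounded) and outer bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gcnorm import DepthMatrix
from .regions import GenomicInterval, Window

COPY_STATES = (0, 1, 2, 3, 4)
# emission mean for the zero-copy state, as a fraction of the window batch mean
# (residual mismapping keeps truly deleted windows slightly above zero)
ZERO_COPY_FRACTION = 0.025


@dataclass
class QCResult:
    sample: str
    per_chrom_corr: dict[str, float]
    mean_corr: float
    n_low_chroms: int
    passed: bool
    reason: str


@dataclass
class NBParams:
    """Negative-binomial window model: variance = mean + mean^2 / size."""

    mean: float
    size: float | None
    poisson_fallback: bool = False


@dataclass
class CopyStatePath:
    states: np.ndarray
    loglik: float


@dataclass
class CNVCall:
    interval: GenomicInterval
    copy_number: int
    n_windows: int
    mean_ratio: float
    outer_start: int
    outer_end: int


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # r is undefined for a constant profile; score 0 (conservative)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def sample_qc(dm: DepthMatrix, sample: str) -> QCResult:
    """Leave-one-out batch-median correlation QC for one sample.

    Per chromosome, the Pearson correlation of the sample's corrected window
    profile with the median profile of the other samples. A sample fails when
    its mean correlation over chromosomes is < 0.6, or more than four
    chromosomes correlate below 4/5 of the other samples' mean correlation for
    that chromosome.
    """
    if dm.corrected is None:
        raise ValueError("matrix is not GC-corrected")
    if len(dm.samples) < 3:
        return QCResult(sample, {}, float("nan"), 0, True,
                        "QC skipped: batch has fewer than 3 samples")
    chroms = dm.chroms
    chrom_list = list(dict.fromkeys(chroms))
    # per (sample, chrom) correlation vs that sample's leave-one-out median
    n = len(dm.samples)
    corr = np.zeros((n, len(chrom_list)))
    for ci, chrom in enumerate(chrom_list):
        mask = chroms == chrom
        sub = dm.corrected[:, mask]
        for si in range(n):
            others = np.delete(sub, si, axis=0)
            corr[si, ci] = _pearson(sub[si], np.median(others, axis=0))
    si = dm.sample_index(sample)
    per_chrom = {c: float(corr[si, ci]) for ci, c in enumerate(chrom_list)}
    mean_corr = float(corr[si].mean())
    others_mean = np.delete(corr, si, axis=0).mean(axis=0)
    n_low = int((corr[si] < 0.8 * others_mean).sum())
    if mean_corr < 0.6:
        return QCResult(sample, per_chrom, mean_corr, n_low, False,
                        f"mean correlation {mean_corr:.3f} < 0.6")
    if n_low > 4:
        return QCResult(sample, per_chrom, mean_corr, n_low, False,
                        f"more than four chromosomes ({n_low}) below 4/5 of batch mean")
    return QCResult(sample, per_chrom, mean_corr, n_low, True, "pass")


def fit_nb(counts: np.ndarray) -> NBParams:
    """Method-of-moments negative-binomial fit: size = m^2 / (v - m).

    Under-dispersed windows (v <= m) fall back to a Poisson model.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 3:
        raise ValueError("need at least 3 counts to fit")
    if not (counts > 0).any():
        raise ValueError("window uncovered in batch")
    m = float(counts.mean())
    v = float(counts.var(ddof=1))
    if v <= m:
        return NBParams(mean=m, size=None, poisson_fallback=True)
    return NBParams(mean=m, size=m * m / (v - m))


def batch_calibrate(dm: DepthMatrix) -> tuple[list[NBParams | None], np.ndarray, np.ndarray]:
    """Per-window NB fits across samples and per-(sample, window) depth ratios.

    Returns ``(params, ratios, masked)``: windows with zero batch mean are
    masked (params ``None``, ratio NaN) and never reach downstream calls.
    """
    if dm.corrected is None:
        raise ValueError("matrix is not GC-corrected")
    params: list[NBParams | None] = []
    ratios = np.full(dm.corrected.shape, np.nan)
    masked = np.zeros(len(dm.windows), dtype=bool)
    for w in range(len(dm.windows)):
        col = dm.corrected[:, w]
        if not (col > 0).any():
            params.append(None)
            masked[w] = True
            continue
        p = fit_nb(col)
        params.append(p)
        ratios[:, w] = col / p.mean
    return params, ratios, masked


def _emission_logpmf(count: float, nb: NBParams, mean: float) -> float:
    k = max(int(round(count)), 0)
    mu = max(mean, 1e-9)
    if nb.poisson_fallback or nb.size is None:
        return float(stats.poisson.logpmf(k, mu))
    r = nb.size
    p = r / (r + mu)
    return float(stats.nbinom.logpmf(k, r, p))


def hmm_copy_number(
    ratios: np.ndarray,
    expected_copies: int,
    nb: list[NBParams],
    stay_prob: float = 0.98,
) -> CopyStatePath:
    """Viterbi decoding of per-window copy number over states 0-4.

    Emission for state CN at window w is the window's negative-binomial (or
    Poisson fallback) density at the observed corrected count, with mean
    scaled to ``mean_w * CN / expected_copies`` (the zero-copy state keeps a
    small residual mean). Transitions stay with ``stay_prob`` and switch
    uniformly among the other states; the initial distribution is uniform.
    """
    if expected_copies not in (1, 2):
        raise ValueError("expected_copies must be 1 or 2")
    ratios = np.asarray(ratios, dtype=float)
    n_win = len(ratios)
    if n_win == 0:
        return CopyStatePath(states=np.array([], dtype=int), loglik=0.0)
    if len(nb) != n_win:
        raise ValueError("one NBParams per window required")
    n_states = len(COPY_STATES)
    log_emit = np.empty((n_win, n_states))
    for w in range(n_win):
        count = ratios[w] * nb[w].mean
        for s, cn in enumerate(COPY_STATES):
            frac = cn / expected_copies if cn > 0 else ZERO_COPY_FRACTION
            log_emit[w, s] = _emission_logpmf(count, nb[w], nb[w].mean * frac)
    log_trans = np.full((n_states, n_states), np.log((1 - stay_prob) / (n_states - 1)))
    np.fill_diagonal(log_trans, np.log(stay_prob))
    # Viterbi
    delta = np.full(n_states, -np.log(n_states)) + log_emit[0]
    back = np.zeros((n_win, n_states), dtype=int)
    for w in range(1, n_win):
        cand = delta[:, None] + log_trans
        back[w] = cand.argmax(axis=0)
        delta = cand.max(axis=0) + log_emit[w]
    states = np.empty(n_win, dtype=int)
    states[-1] = int(delta.argmax())
    loglik = float(delta.max())
    for w in range(n_win - 1, 0, -1):
        states[w - 1] = back[w, states[w]]
    return CopyStatePath(states=np.array([COPY_STATES[s] for s in states]), loglik=loglik)


def segment_cnv(
    path: CopyStatePath,
    windows: list[Window],
    expected_copies: int,
    min_windows: int = 5,
    ratios: np.ndarray | None = None,
) -> list[CNVCall]:
    """Maximal constant-state runs differing from the expected copy number.

    Runs shorter than ``min_windows`` are dropped. Inner bounds span the first
    supporting window's start to the last one's end; outer bounds extend to
    the flanking normal windows (or the inner bound at a chromosome edge).
    """
    states = path.states
    if len(states) != len(windows):
        raise ValueError("path not aligned to windows")
    calls: list[CNVCall] = []
    i = 0
    n = len(states)
    while i < n:
        if states[i] == expected_copies:
            i += 1
            continue
        j = i
        while j < n and states[j] == states[i]:
            j += 1
        run = j - i
        if run >= min_windows:
            first, last = windows[i].interval, windows[j - 1].interval
            mean_ratio = float(np.nanmean(ratios[i:j])) if ratios is not None else float("nan")
            outer_start = windows[i - 1].interval.start if i > 0 else first.start
            outer_end = windows[j].interval.end if j < n else last.end
            calls.append(
                CNVCall(
                    interval=GenomicInterval(first.chrom, first.start, last.end),
                    copy_number=int(states[i]),
                    n_windows=run,
                    mean_ratio=mean_ratio,
                    outer_start=outer_start,
                    outer_end=outer_end,
                )
            )
        i = j
    return calls


def call_cnvs(
    dm: DepthMatrix,
    sample: str,
    expected_copies_of: dict[str, int] | None = None,
    min_windows: int = 5,
    stay_prob: float = 0.98,
) -> list[CNVCall]:
    """Full per-sample CNV pipeline: calibrate, decode per chromosome, segment.

    ``expected_copies_of`` maps chromosome name to expected copy number
    (defaults to 2; set chrX/chrY from the sample's karyotype call).
    """
    params, ratios, masked = batch_calibrate(dm)
    si = dm.sample_index(sample)
    chroms = dm.chroms
    calls: list[CNVCall] = []
    for chrom in dict.fromkeys(chroms):
        mask = (chroms == chrom) & ~masked
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        expected = (expected_copies_of or {}).get(chrom, 2)
        if expected < 1:
            continue  # no copies expected (e.g. chrY in XX): dosage handles it
        nb = [params[w] for w in idx]
        r = ratios[si, idx]
        path = hmm_copy_number(r, expected, nb, stay_prob=stay_prob)
        calls.extend(
            segment_cnv(path, [dm.windows[w] for w in idx], expected,
                        min_windows=min_windows, ratios=r)
        )
    return calls


def write_cnv_tsv(calls: list[CNVCall], path: str) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "chrom": [c.interval.chrom for c in calls],
            "inner_start": [c.interval.start for c in calls],
            "inner_end": [c.interval.end for c in calls],
            "outer_start": [c.outer_start for c in calls],
            "outer_end": [c.outer_end for c in calls],
            "copy_number": [c.copy_number for c in calls],
            "n_windows": [c.n_windows for c in calls],
            "mean_ratio": [c.mean_ratio for c in calls],
        }
    ).to_csv(path, sep="\t", index=False)
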