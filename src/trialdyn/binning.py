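"""Quantile-binning diagnostics and raw/partial correlations.

These are the "naive" single-trial diagnostics: correlate per-trial window
averages directly, split trials into equal-sized bins by a per-trial score,
and average the *unaltered* waveforms per bin. Because the score is derived
from the signal itself, bins computed from raw N400-window averages are
contaminated by trial-wide voltage drift (the bin means separate already
before the component windows); scoring by "N400 average minus whole-segment
average" removes the drift contribution from the bin assignment without
altering the displayed data.

The partial correlation of N400- and P600-window averages given the
whole-segment average is the quantitative counterpart of the subtraction
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .epochs import EpochSet, WaveformSummary
from .errors import DegenerateInputError, DomainError

_VAR_TOL = 1e-12


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise DegenerateInputError(f"{name} contains non-finite values")
    return arr


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation of two equal-length per-trial score vectors."""
    x, y = _as_1d(x, "x"), _as_1d(y, "y")
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise DomainError("need at least 3 paired observations")
    if np.var(x) < _VAR_TOL or np.var(y) < _VAR_TOL:
        raise DegenerateInputError("zero variance input")
    return float(stats.pearsonr(x, y).statistic)


def partial_correlation(x, y, z) -> float:
    """Partial correlation r_xy.z controlling for a third variable.

    Computed from the three pairwise correlations:
    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),
    which equals the correlation of the residuals of x and y after
    least-squares regression on z.
    """
    x, y, z = _as_1d(x, "x"), _as_1d(y, "y"), _as_1d(z, "z")
    if not (x.size == y.size == z.size):
        raise DomainError("x, y, z must have equal length")
    if x.size < 4:
        raise DomainError("need at least 4 paired observations")
    r_xy = pearson_correlation(x, y)
    r_xz = pearson_correlation(x, z)
    r_yz = pearson_correlation(y, z)
    if 1.0 - r_xz ** 2 < _VAR_TOL or 1.0 - r_yz ** 2 < _VAR_TOL:
        raise DegenerateInputError(
            "x or y is perfectly collinear with z; partial correlation undefined"
        )
    return float((r_xy - r_xz * r_yz) / np.sqrt((1.0 - r_xz ** 2) * (1.0 - r_yz ** 2)))


def subtraction_scores(n400_avg, segment_avg) -> np.ndarray:
    """Per-trial binning score: N400-window average minus segment average.

    The score is used only to assign trials to bins; displayed voltages are
    never altered by it.
    """
    n400_avg = _as_1d(n400_avg, "n400_avg")
    segment_avg = _as_1d(segment_avg, "segment_avg")
    if n400_avg.size != segment_avg.size:
        raise DomainError("length mismatch between n400_avg and segment_avg")
    return n400_avg - segment_avg


@dataclass
class BinAssignment:
    """Per-trial bin indices (1..k) from ranking a score vector."""

    scores: np.ndarray
    bins: np.ndarray  # int, 1..k
    k: int

    def sizes(self) -> np.ndarray:
        return np.bincount(self.bins, minlength=self.k + 1)[1:]


def assign_bins(scores, k: int = 3) -> BinAssignment:
    """Rank trials by score (ascending, ties stable in input order) and
    split into k near-equal bins; remainder trials go to the lowest bins.
    """
    scores = _as_1d(scores, "scores")
    n = scores.size
    if n < k:
        raise DomainError(f"cannot form {k} bins from {n} trials")
    order = np.argsort(scores, kind="stable")
    base, rem = divmod(n, k)
    sizes = np.full(k, base)
    sizes[:rem] += 1
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes, start=1):
        bins[order[start:start + size]] = b
        start += size
    return BinAssignment(scores=scores, bins=bins, k=k)


def bin_waveforms(epochs: EpochSet, bins: BinAssignment, electrode: str,
                  se_unit: str = "trial") -> WaveformSummary:
    """Average unaltered voltages per bin at one electrode.

    ``se_unit`` selects the aggregation unit of the error ribbon: "trial"
    (standard error across trials within the bin, the default) or "subject"
    (standard error across per-subject bin means).
    """
    if se_unit not in ("trial", "subject"):
        raise DomainError(f"se_unit must be 'trial' or 'subject', got {se_unit!r}")
    if bins.bins.size != epochs.n_trials:
        raise DomainError(
            f"bin assignment covers {bins.bins.size} trials but epochs has "
            f"{epochs.n_trials}"
        )
    e = epochs.electrode_index(electrode)
    records = []
    for b in range(1, bins.k + 1):
        idx = np.flatnonzero(bins.bins == b)
        if idx.size == 0:
            raise DomainError(f"bin {b} is empty")
        wave = epochs.voltages[idx, e, :]
        mean = wave.mean(axis=0)
        if se_unit == "trial":
            n_units = idx.size
            se = wave.std(axis=0, ddof=1) / np.sqrt(n_units) if n_units > 1 \
                else np.zeros_like(mean)
        else:
            groups = epochs.trials.iloc[idx].groupby("subject", observed=True).indices
            stack = np.stack([wave[g].mean(axis=0) for g in groups.values()])
            n_units = stack.shape[0]
            se = stack.std(axis=0, ddof=1) / np.sqrt(n_units) if n_units > 1 \
                else np.zeros_like(mean)
        records.append(pd.DataFrame({
            "bin": b,
            "electrode": electrode,
            "time_ms": epochs.times,
            "mean_uv": mean,
            "se_uv": se,
            "n_units": n_units,
        }))
    data = pd.concat(records, ignore_index=True)
    return WaveformSummary(data=data, group_by=("bin",), unit=se_unit)


def component_correlations(epochs: EpochSet, n400_window, p600_window,
                           segment_window, electrode: str,
                           center_within_subject: bool = False) -> dict[str, float]:
    """Raw and Segment-partialed N400–P600 correlations at one electrode.

    Trials are pooled across subjects (and conditions); with
    ``center_within_subject`` each subject's mean window average is removed
    before pooling. Returns raw_n400_p600, partial_n400_p600_given_segment
    and p600_segment correlations.
    """
    from .epochs import window_average  # local to avoid cycle at import time

    a_n400 = window_average(epochs, n400_window, electrode)
    a_p600 = window_average(epochs, p600_window, electrode)
    a_seg = window_average(epochs, segment_window, electrode)
    if center_within_subject:
        subj = epochs.trials["subject"].to_numpy()
        for arr in (a_n400, a_p600, a_seg):
            df = pd.Series(arr).groupby(subj).transform("mean")
            arr -= df.to_numpy()
    return {
        "raw_n400_p600": pearson_correlation(a_n400, a_p600),
        "partial_n400_p600_given_segment": partial_correlation(a_n400, a_p600, a_seg),
        "p600_segment": pearson_correlation(a_p600, a_seg),
    }
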