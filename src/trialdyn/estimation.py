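"""Forward estimates with predictor neutralization, and condition summaries.

Given fitted per-cell coefficients, the forward estimate of a trial is

    yhat_st = beta0_st + beta1_st * N400_st + beta2_st * Segment_st

and a predictor is *neutralized* by setting its value to its mean — zero
for z-standardized predictors — WITHOUT refitting the models. Neutralizing
both predictors leaves the intercept (the per-subject average); neutralizing
one isolates the other's contribution. The residual y - yhat is stored
alongside so yhat + residual reconstructs the observed data bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet, WaveformSummary, grand_average
from .errors import AlignmentError, DomainError
from .rerp import CoefficientSet, PredictorTable, INTERCEPT, TERM_N400, TERM_SEGMENT

NEUTRALIZABLE = frozenset({TERM_N400, TERM_SEGMENT})


@dataclass
class EstimateSet:
    """Per-trial forward estimates and residuals.

    ``yhat`` and ``residual`` have the EpochSet voltage shape
    (n_trials, n_electrodes, n_samples); ``neutralized`` records which
    predictors were fixed at zero when computing yhat.
    """

    yhat: np.ndarray
    residual: np.ndarray
    neutralized: frozenset
    electrodes: list[str]
    times: np.ndarray


def forward_estimate(coeffs: CoefficientSet, predictors: PredictorTable | None,
                     epochs: EpochSet, neutralize=()) -> EstimateSet:
    """Compute yhat and y - yhat for every trial from fitted coefficients.

    ``neutralize`` is a subset of {"N400", "Segment"}; the named predictors
    enter the estimate as 0. Coefficients are never refit here. For
    intercept-only coefficient sets ``predictors`` may be None.
    """
    neutralize = frozenset(neutralize)
    unknown = neutralize - NEUTRALIZABLE
    if unknown:
        raise DomainError(f"cannot neutralize unknown predictors {sorted(unknown)}")
    if list(coeffs.electrodes) != list(epochs.electrodes):
        raise AlignmentError("electrode sets of coefficients and epochs differ")
    if not np.array_equal(coeffs.times, epochs.times):
        raise AlignmentError("time grids of coefficients and epochs differ")
    has_predictor_terms = [t for t in coeffs.terms if t != INTERCEPT]
    if has_predictor_terms:
        if predictors is None:
            raise AlignmentError("coefficients carry predictor terms but no "
                                 "predictor table was given")
        if predictors.n_trials != epochs.n_trials:
            raise AlignmentError(
                f"predictor table covers {predictors.n_trials} trials but "
                f"epochs has {epochs.n_trials}"
            )

    subj = epochs.trials["subject"].to_numpy()
    missing = set(subj) - set(coeffs.subjects)
    if missing:
        raise AlignmentError(
            f"epochs contain trials of subjects absent from the coefficient "
            f"set: {sorted(missing)}"
        )
    sidx = np.array([coeffs.subject_index(s) for s in subj])

    yhat = coeffs.beta[sidx, :, :, 0].copy()  # (n_trials, n_elec, n_samples)
    for term in has_predictor_terms:
        k = coeffs.term_index(term)
        if term in neutralize:
            continue
        vals = predictors.values(term)  # (n_trials, n_elec)
        yhat += vals[:, :, None] * coeffs.beta[sidx, :, :, k]
    residual = epochs.voltages - yhat
    return EstimateSet(yhat=yhat, residual=residual, neutralized=neutralize,
                       electrodes=list(epochs.electrodes),
                       times=epochs.times.copy())


def _summarize(values: np.ndarray, epochs: EpochSet) -> WaveformSummary:
    """Per-subject then per-condition average with across-subject se."""
    carrier = epochs.with_voltages(values)
    return grand_average(carrier, group_by=("condition",))


def estimate_by_condition(estimates: EstimateSet, epochs: EpochSet) -> WaveformSummary:
    """Forward estimates averaged per subject then per condition."""
    _check_alignment(estimates, epochs)
    return _summarize(estimates.yhat, epochs)


def residual_by_condition(estimates: EstimateSet, epochs: EpochSet) -> WaveformSummary:
    """Residual error averaged per subject per sample, split by condition.

    For a well-fitting model these traces stay near zero; for the
    intercept-only estimate they show exactly the part of the condition
    contrast the average cannot explain.
    """
    _check_alignment(estimates, epochs)
    return _summarize(estimates.residual, epochs)


def _check_alignment(estimates: EstimateSet, epochs: EpochSet) -> None:
    if estimates.yhat.shape != epochs.voltages.shape:
        raise AlignmentError(
            f"estimate shape {estimates.yhat.shape} does not match epochs "
            f"shape {epochs.voltages.shape}"
        )
    if not np.array_equal(estimates.times, epochs.times):
        raise AlignmentError("time grids of estimates and epochs differ")
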