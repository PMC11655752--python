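"""Regression-ERP (rERP) fitting.

The EEG is modelled independently at every subject x time sample x
electrode cell as

    yhat_st = beta0_st + beta1_st * N400_st + beta2_st * Segment_st

where N400_st and Segment_st are trial-level predictors: per-electrode
window averages of the trial's own signal (300–500 ms and 0–1200 ms by
default), z-standardized and multiplied by -1. The inversion makes a
*positive* raw correlation appear as a *negative* N400 coefficient, so the
coefficient traces read like ERP waveforms. With no predictors the model is
intercept-only and the averaged intercepts reproduce the two-stage grand
average exactly ("all ERPs are rERPs").

Fits are ordinary least squares per cell, vectorized over time samples
(the design matrix of a subject x electrode cell is shared by all samples).
Coefficient standard errors use the classical homoskedastic estimate per
cell; the across-subject dispersion of the coefficients is computed in
:func:`summarize_coefficients`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epochs import (EpochSet, WaveformSummary, WindowSpec, N400_WINDOW,
                     SEGMENT_WINDOW, window_average)
from .errors import (AlignmentError, DegenerateInputError, DomainError,
                     SingularDesignError)

logger = logging.getLogger(__name__)

INTERCEPT = "intercept"
TERM_N400 = "N400"
TERM_SEGMENT = "Segment"

_SD_TOL = 1e-12


@dataclass
class PredictorTable:
    """z-standardized, inverted trial-level predictors per electrode.

    ``n400`` and ``segment`` have shape (n_trials, n_electrodes) and align
    with the EpochSet they were built from. ``standardization`` records the
    raw-µV mean and sample sd of each (electrode, predictor) group so raw
    window averages can be mapped to predictor units.
    """

    n400: np.ndarray
    segment: np.ndarray
    electrodes: list[str]
    standardization: pd.DataFrame  # columns: electrode, predictor, mean_uv, sd_uv, group
    scope: str = "pooled"  # "pooled" | "per_subject"

    @property
    def n_trials(self) -> int:
        return self.n400.shape[0]

    def values(self, term: str) -> np.ndarray:
        if term == TERM_N400:
            return self.n400
        if term == TERM_SEGMENT:
            return self.segment
        raise DomainError(f"unknown predictor term {term!r}")


def _zscore_invert(raw: np.ndarray, groups: np.ndarray | None, label: str,
                   electrode: str) -> tuple[np.ndarray, list[dict]]:
    """z-standardize (sample sd, n-1) within groups, then invert (* -1)."""
    out = np.empty_like(raw)
    meta = []
    if groups is None:
        group_iter = [("all", np.arange(raw.size))]
    else:
        group_iter = [(g, np.flatnonzero(groups == g)) for g in pd.unique(groups)]
    for gname, idx in group_iter:
        mean = raw[idx].mean()
        sd = raw[idx].std(ddof=1) if idx.size > 1 else 0.0
        if sd < _SD_TOL:
            raise DegenerateInputError(
                f"predictor {label!r} on electrode {electrode!r} has zero "
                f"variance in standardization group {gname!r}"
            )
        out[idx] = -(raw[idx] - mean) / sd
        meta.append({"electrode": electrode, "predictor": label,
                     "group": gname, "mean_uv": mean, "sd_uv": sd})
    return out, meta


def build_predictors(epochs: EpochSet,
                     n400_window: WindowSpec = N400_WINDOW,
                     segment_window: WindowSpec = SEGMENT_WINDOW,
                     scope: str = "pooled") -> PredictorTable:
    """Window-average, z-standardize and invert the two trial-level predictors.

    ``scope`` selects the standardization group: "pooled" (one scale per
    electrode across all trials entering the fit; the default, so
    coefficients are comparable across subjects) or "per_subject".
    """
    if scope not in ("pooled", "per_subject"):
        raise DomainError(f"scope must be 'pooled' or 'per_subject', got {scope!r}")
    groups = epochs.trials["subject"].to_numpy() if scope == "per_subject" else None
    n400 = np.empty((epochs.n_trials, len(epochs.electrodes)))
    segment = np.empty_like(n400)
    meta: list[dict] = []
    for e, el in enumerate(epochs.electrodes):
        raw_n = window_average(epochs, n400_window, el)
        raw_s = window_average(epochs, segment_window, el)
        n400[:, e], m1 = _zscore_invert(raw_n, groups, TERM_N400, el)
        segment[:, e], m2 = _zscore_invert(raw_s, groups, TERM_SEGMENT, el)
        meta.extend(m1)
        meta.extend(m2)
    return PredictorTable(n400=n400, segment=segment,
                          electrodes=list(epochs.electrodes),
                          standardization=pd.DataFrame(meta), scope=scope)


# ---------------------------------------------------------------------------
# Cell-level OLS
# ---------------------------------------------------------------------------

def fit_cell(voltages, predictors=None) -> tuple[np.ndarray, np.ndarray]:
    """OLS with intercept for one subject x time sample x electrode cell.

    ``voltages`` is the per-trial response (n,), ``predictors`` an optional
    (n, p) matrix of trial-level predictors (no intercept column). Returns
    (beta, se) of length p + 1, intercept first. Standard errors are the
    classical sqrt(sigma^2 * diag((X'X)^-1)) with sigma^2 = SSR / (n - p - 1).
    """
    y = np.asarray(voltages, dtype=float).ravel()
    n = y.size
    if predictors is None:
        X = np.ones((n, 1))
    else:
        P = np.asarray(predictors, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        X = np.column_stack([np.ones(n), P])
    p1 = X.shape[1]
    if n <= p1:
        raise DomainError(f"need more trials ({n}) than model terms ({p1})")
    beta, se, _ = _ols(X, y[:, None])
    return beta[:, 0], se[:, 0]


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of many responses on one design matrix.

    X: (n, p) full-rank design (with intercept column); Y: (n, m) responses.
    Returns beta (p, m), se (p, m), residuals (n, m).
    """
    n, p = X.shape
    xtx = X.T @ X
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {p} terms)"
        )
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.diag(xtx_inv)[:, None] * sigma2[None, :])
    return beta, se, resid


# ---------------------------------------------------------------------------
# Coefficient container
# ---------------------------------------------------------------------------

@dataclass
class CoefficientSet:
    """Per subject x electrode x time sample x term OLS estimates.

    ``beta`` and ``se_ols`` have shape (n_subjects, n_electrodes, n_samples,
    n_terms); ``terms`` is ["intercept"] or ["intercept", "N400", "Segment"].
    """

    subjects: list
    electrodes: list[str]
    times: np.ndarray
    terms: list[str]
    beta: np.ndarray
    se_ols: np.ndarray
    n_trials: np.ndarray  # per-subject trial counts

    def subject_index(self, subject) -> int:
        try:
            return self.subjects.index(subject)
        except ValueError:
            raise AlignmentError(f"subject {subject!r} not in coefficient set") from None

    def term_index(self, term: str) -> int:
        try:
            return self.terms.index(term)
        except ValueError:
            raise DomainError(f"unknown term {term!r}; have {self.terms}") from None

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: subject, electrode, time_ms, term, estimate, se, n_trials."""
        n_s, n_e, n_t, n_k = self.beta.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.electrodes, self.times, self.terms],
            names=["subject", "electrode", "time_ms", "term"],
        )
        df = pd.DataFrame({
            "estimate": self.beta.reshape(-1),
            "se": self.se_ols.reshape(-1),
        }, index=idx).reset_index()
        counts = pd.Series(self.n_trials, index=self.subjects, name="n_trials")
        df["n_trials"] = df["subject"].map(counts)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoefficientSet":
        subjects = list(pd.unique(df["subject"]))
        electrodes = list(pd.unique(df["electrode"]))
        times = np.sort(df["time_ms"].unique())
        terms = list(pd.unique(df["term"]))
        shape = (len(subjects), len(electrodes), len(times), len(terms))
        piv = df.set_index(["subject", "electrode", "time_ms", "term"])
        full = pd.MultiIndex.from_product([subjects, electrodes, times, terms])
        piv = piv.reindex(full)
        beta = piv["estimate"].to_numpy().reshape(shape)
        se = piv["se"].to_numpy().reshape(shape)
        counts = df.groupby("subject", sort=False)["n_trials"].first()
        return cls(subjects=subjects, electrodes=electrodes, times=times,
                   terms=terms, beta=beta, se_ols=se,
                   n_trials=counts.loc[subjects].to_numpy())


def fit_rerp(epochs: EpochSet, predictors: PredictorTable | None = None,
             min_trials: int = 4) -> CoefficientSet:
    """Fit the per-cell OLS models for every subject, electrode and sample.

    With ``predictors=None`` the models are intercept-only and the fitted
    intercepts are the per-subject average waveforms. Subjects with fewer
    than ``min_trials`` trials are skipped with a logged warning; if a
    subject's design matrix is rank deficient (e.g. constant predictors) a
    SingularDesignError is raised.
    """
    if predictors is not None and predictors.n_trials != epochs.n_trials:
        raise AlignmentError(
            f"predictor table covers {predictors.n_trials} trials but epochs "
            f"has {epochs.n_trials}"
        )
    terms = [INTERCEPT] if predictors is None else [INTERCEPT, TERM_N400, TERM_SEGMENT]
    n_terms = len(terms)
    subj_groups = epochs.trials.groupby("subject", sort=False, observed=True).indices

    kept: list = []
    betas, ses, counts = [], [], []
    n_e, n_t = len(epochs.electrodes), len(epochs.times)
    for subject, idx in subj_groups.items():
        if idx.size < max(min_trials, n_terms + 1):
            logger.warning("subject %r has only %d trials; skipped", subject, idx.size)
            continue
        beta_s = np.empty((n_e, n_t, n_terms))
        se_s = np.empty_like(beta_s)
        for e in range(n_e):
            if predictors is None:
                X = np.ones((idx.size, 1))
            else:
                X = np.column_stack([
                    np.ones(idx.size),
                    predictors.n400[idx, e],
                    predictors.segment[idx, e],
                ])
            Y = epochs.voltages[idx, e, :]  # (n_trials_s, n_samples)
            b, s, _ = _ols(X, Y)
            beta_s[e] = b.T
            se_s[e] = s.T
        kept.append(subject)
        betas.append(beta_s)
        ses.append(se_s)
        counts.append(idx.size)
    if not kept:
        raise DomainError("no subject has enough trials to fit")
    return CoefficientSet(
        subjects=kept, electrodes=list(epochs.electrodes),
        times=epochs.times.copy(), terms=terms,
        beta=np.stack(betas), se_ols=np.stack(ses),
        n_trials=np.asarray(counts),
    )


def summarize_coefficients(coeffs: CoefficientSet, add_intercept: bool = False,
                           ribbon: str = "subjects") -> WaveformSummary:
    """Across-subject mean coefficient traces with error ribbons.

    One trace per term; with ``add_intercept`` the non-intercept traces are
    beta0 + betak ("coefficients added to their intercept", the ERP-like
    display) and the ribbon is the across-subject dispersion of that sum.
    ``ribbon`` is "subjects" (sd of per-subject values / sqrt(n), default)
    or "ols" (mean of the per-cell OLS standard errors).
    """
    if ribbon not in ("subjects", "ols"):
        raise DomainError(f"ribbon must be 'subjects' or 'ols', got {ribbon!r}")
    n_subj = len(coeffs.subjects)
    records = []
    for k, term in enumerate(coeffs.terms):
        vals = coeffs.beta[:, :, :, k]
        if add_intercept and term != INTERCEPT:
            vals = vals + coeffs.beta[:, :, :, 0]
        mean = vals.mean(axis=0)
        if ribbon == "subjects":
            se = vals.std(axis=0, ddof=1) / np.sqrt(n_subj) if n_subj > 1 \
                else np.zeros_like(mean)
        else:
            se = coeffs.se_ols[:, :, :, k].mean(axis=0)
        for e, el in enumerate(coeffs.electrodes):
            records.append(pd.DataFrame({
                "term": term,
                "electrode": el,
                "time_ms": coeffs.times,
                "mean_uv": mean[e],
                "se_uv": se[e],
                "n_units": n_subj,
            }))
    return WaveformSummary(data=pd.concat(records, ignore_index=True),
                           group_by=("term",), unit="subject")


def fit_by_condition(epochs: EpochSet, condition: str,
                     n400_window: WindowSpec = N400_WINDOW,
                     segment_window: WindowSpec = SEGMENT_WINDOW,
                     scope: str = "pooled",
                     reuse_predictors: PredictorTable | None = None,
                     min_trials: int = 4) -> CoefficientSet:
    """Fit the rERP models on a single condition's trials.

    Predictors are rebuilt (re-standardized) within the condition subset by
    default, keeping the mean-0/sd-1 predictor contract valid in the subset;
    pass ``reuse_predictors`` (built on the full data) to instead keep the
    global standardization.
    """
    mask = epochs.trials["condition"] == condition
    if not mask.any():
        raise DomainError(f"no trials in condition {condition!r}")
    idx = np.flatnonzero(mask.to_numpy())
    sub = epochs.subset(idx)
    if reuse_predictors is not None:
        preds = PredictorTable(
            n400=reuse_predictors.n400[idx],
            segment=reuse_predictors.segment[idx],
            electrodes=list(reuse_predictors.electrodes),
            standardization=reuse_predictors.standardization.copy(),
            scope=reuse_predictors.scope,
        )
    else:
        preds = build_predictors(sub, n400_window, segment_window, scope=scope)
    return fit_rerp(sub, preds, min_trials=min_trials)
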