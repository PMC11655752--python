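"""Single-trial epoch container, CSV I/O, baseline correction, window
averages, and grand-average ERPs.

The central object is :class:`EpochSet`: a table of trials (subject, item,
condition) together with a ``[trial x electrode x sample]`` voltage array on
a uniform time grid in milliseconds relative to stimulus onset (time 0 =
target-word onset, negative times are pre-stimulus). Voltages are in
microvolts throughout.

Grand averages follow the classical two-stage ERP convention: trials are
first averaged within subject, then subject means are averaged; the error
ribbon is the standard error of the subject means. Fitting an intercept-only
regression per subject and time sample and averaging the intercepts gives
exactly the same waveform (see :mod:`trialdyn.rerp`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

logger = logging.getLogger(__name__)

#: Column order of the long-format CSV dialect.
CSV_COLUMNS = ["subject", "item", "condition", "electrode", "time_ms", "voltage_uv"]

_GRID_TOL_MS = 1e-9


@dataclass(frozen=True)
class WindowSpec:
    """A named closed time window [start_ms, end_ms], endpoints inclusive."""

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not self.start_ms < self.end_ms:
            raise DomainError(
                f"window {self.name!r}: start_ms ({self.start_ms}) must be "
                f"< end_ms ({self.end_ms})"
            )

    def mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean mask of grid samples inside the window (inclusive)."""
        m = (times >= self.start_ms - _GRID_TOL_MS) & (times <= self.end_ms + _GRID_TOL_MS)
        if not m.any():
            raise DomainError(
                f"window {self.name!r} ({self.start_ms}..{self.end_ms} ms) "
                "contains no sample of the time grid"
            )
        return m


#: Default windows used across the analysis (ms post onset).
N400_WINDOW = WindowSpec("N400", 300.0, 500.0)
P600_WINDOW = WindowSpec("P600", 600.0, 1000.0)
SEGMENT_WINDOW = WindowSpec("Segment", 0.0, 1200.0)
BASELINE_WINDOW = WindowSpec("baseline", -200.0, 0.0)


@dataclass
class WaveformSummary:
    """Grouped waveform mean and across-unit standard error.

    ``data`` is a tidy frame with the grouping columns, ``electrode``,
    ``time_ms``, ``mean_uv``, ``se_uv`` and ``n_units``. ``unit`` records
    what the standard error is computed across (e.g. "subject", "trial").
    """

    data: pd.DataFrame
    group_by: tuple[str, ...]
    unit: str = "subject"

    def groups(self) -> list:
        if not self.group_by:
            return []
        return sorted(self.data[list(self.group_by)].drop_duplicates().itertuples(index=False))


@dataclass
class EpochSet:
    """Single-trial epoched EEG voltages plus trial metadata.

    trials : DataFrame with columns subject, item, condition (one row per
        trial; extra columns such as a bin label are allowed).
    electrodes : ordered electrode labels.
    times : strictly increasing, uniformly spaced sample times in ms.
    voltages : float array of shape (n_trials, n_electrodes, n_samples), µV.
    """

    trials: pd.DataFrame
    electrodes: list[str]
    times: np.ndarray
    voltages: np.ndarray

    def __post_init__(self):
        self.trials = self.trials.reset_index(drop=True)
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        for col in ("subject", "item", "condition"):
            if col not in self.trials.columns:
                raise FormatError(f"trials table lacks required column {col!r}")
        n_tr, n_el, n_sm = len(self.trials), len(self.electrodes), len(self.times)
        if self.voltages.shape != (n_tr, n_el, n_sm):
            raise FormatError(
                f"voltage array shape {self.voltages.shape} does not match "
                f"(trials={n_tr}, electrodes={n_el}, samples={n_sm})"
            )
        if n_sm >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise FormatError("time grid is not strictly increasing")
            if np.ptp(steps) > _GRID_TOL_MS:
                raise FormatError("time grid spacing is not uniform")
        if n_tr:
            dup = self.trials.duplicated(subset=["subject", "item"])
            if dup.any():
                s, i = self.trials.loc[dup.idxmax(), ["subject", "item"]]
                raise FormatError(f"duplicate trial (subject={s!r}, item={i!r})")
            if self.trials["condition"].isna().any():
                raise FormatError("every trial must carry exactly one condition")
        if not np.all(np.isfinite(self.voltages)):
            raise FormatError("voltages contain non-finite values")

    # -- basic accessors --------------------------------------------------
    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.trials["subject"]))

    @property
    def conditions(self) -> list:
        return list(pd.unique(self.trials["condition"]))

    def electrode_index(self, electrode: str) -> int:
        try:
            return self.electrodes.index(electrode)
        except ValueError:
            raise DomainError(
                f"unknown electrode {electrode!r}; have {self.electrodes}"
            ) from None

    def subset(self, index: Iterable[int] | np.ndarray) -> "EpochSet":
        """New EpochSet restricted to the given trial positions."""
        idx = np.asarray(list(index) if not isinstance(index, np.ndarray) else index)
        return EpochSet(
            trials=self.trials.iloc[idx].reset_index(drop=True),
            electrodes=list(self.electrodes),
            times=self.times.copy(),
            voltages=self.voltages[idx].copy(),
        )

    def with_voltages(self, voltages: np.ndarray) -> "EpochSet":
        """Copy of this EpochSet with a replacement voltage array."""
        return EpochSet(
            trials=self.trials.copy(),
            electrodes=list(self.electrodes),
            times=self.times.copy(),
            voltages=voltages,
        )

    def with_trial_column(self, name: str, values) -> "EpochSet":
        out = self.with_voltages(self.voltages.copy())
        out.trials[name] = np.asarray(values)
        return out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_epochs(path) -> EpochSet:
    """Read a long-format epochs CSV into an :class:`EpochSet`.

    The file must contain the header ``subject,item,condition,electrode,
    time_ms,voltage_uv`` and a complete time grid for every trial and
    electrode. Row order in the file is irrelevant; trials are ordered by
    (subject, item) and electrodes by first appearance in that ordering.
    """
    df = pd.read_csv(path, dtype={"subject": str, "item": str, "condition": str,
                                  "electrode": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"epochs CSV lacks columns {missing}")
    volts = pd.to_numeric(df["voltage_uv"], errors="coerce")
    if volts.isna().any():
        row = int(volts.isna().idxmax())
        raise FormatError(f"non-numeric voltage at CSV row {row + 2}")
    df["voltage_uv"] = volts.astype(float)
    df["time_ms"] = pd.to_numeric(df["time_ms"], errors="raise").astype(float)

    if df.duplicated(subset=["subject", "item", "electrode", "time_ms"]).any():
        dup = df[df.duplicated(subset=["subject", "item", "electrode", "time_ms"])].iloc[0]
        raise FormatError(
            f"duplicate rows for trial (subject={dup['subject']!r}, "
            f"item={dup['item']!r}) electrode {dup['electrode']!r} "
            f"at t={dup['time_ms']} ms"
        )

    times = np.sort(df["time_ms"].unique())
    df = df.sort_values(["subject", "item"], kind="stable")
    electrodes = list(pd.unique(df["electrode"]))
    trial_keys = df[["subject", "item", "condition"]].drop_duplicates(["subject", "item"])
    trial_keys = trial_keys.sort_values(["subject", "item"]).reset_index(drop=True)

    # one condition per trial
    n_cond = df.groupby(["subject", "item"])["condition"].nunique()
    if (n_cond > 1).any():
        s, i = n_cond.index[int(np.argmax(n_cond.values > 1))]
        raise FormatError(f"trial (subject={s!r}, item={i!r}) has multiple conditions")

    t_pos = pd.Series(np.arange(len(times)), index=times)
    e_pos = pd.Series(np.arange(len(electrodes)), index=electrodes)
    key = pd.MultiIndex.from_frame(trial_keys[["subject", "item"]])
    tr_pos = pd.Series(np.arange(len(trial_keys)), index=key)

    vol = np.full((len(trial_keys), len(electrodes), len(times)), np.nan)
    ti = tr_pos.loc[pd.MultiIndex.from_frame(df[["subject", "item"]])].to_numpy()
    ei = e_pos.loc[df["electrode"]].to_numpy()
    si = t_pos.loc[df["time_ms"]].to_numpy()
    vol[ti, ei, si] = df["voltage_uv"].to_numpy()

    if np.isnan(vol).any():
        t_i, e_i, _ = np.argwhere(np.isnan(vol))[0]
        s, i = trial_keys.loc[t_i, ["subject", "item"]]
        raise FormatError(
            f"incomplete time grid for trial (subject={s!r}, item={i!r}) "
            f"on electrode {electrodes[e_i]!r}"
        )
    return EpochSet(trials=trial_keys, electrodes=electrodes, times=times, voltages=vol)


def write_epochs(epochs: EpochSet, path) -> None:
    """Write an :class:`EpochSet` as long-format CSV.

    Rows are ordered deterministically by (subject, item, electrode, time).
    Voltages are written at full ``repr`` precision so a read/write round
    trip is lossless.
    """
    n_tr, n_el, n_sm = epochs.voltages.shape
    if n_tr == 0:
        pd.DataFrame(columns=CSV_COLUMNS).to_csv(path, index=False)
        return
    order = np.lexsort((epochs.trials["item"].to_numpy(),
                        epochs.trials["subject"].to_numpy()))
    el_order = np.argsort(np.asarray(epochs.electrodes, dtype=object))
    rows = {
        "subject": np.repeat(epochs.trials["subject"].to_numpy()[order], n_el * n_sm),
        "item": np.repeat(epochs.trials["item"].to_numpy()[order], n_el * n_sm),
        "condition": np.repeat(epochs.trials["condition"].to_numpy()[order], n_el * n_sm),
        "electrode": np.tile(np.repeat(np.asarray(epochs.electrodes, dtype=object)[el_order], n_sm), n_tr),
        "time_ms": np.tile(epochs.times, n_tr * n_el),
        "voltage_uv": epochs.voltages[order][:, el_order, :].reshape(-1),
    }
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Baseline correction and window averaging
# ---------------------------------------------------------------------------

def baseline_correct(epochs: EpochSet, interval: WindowSpec = BASELINE_WINDOW) -> EpochSet:
    """Subtract the per-trial, per-electrode mean over ``interval``.

    The default interval is the 200 ms pre-stimulus period. After
    correction the mean over the interval is zero for every trial and
    electrode; applying the operation twice is a no-op.
    """
    if interval.start_ms < epochs.times[0] - _GRID_TOL_MS or \
            interval.end_ms > epochs.times[-1] + _GRID_TOL_MS:
        raise DomainError(
            f"baseline interval {interval.start_ms}..{interval.end_ms} ms lies "
            f"outside the epoch {epochs.times[0]}..{epochs.times[-1]} ms"
        )
    m = interval.mask(epochs.times)
    corrected = epochs.voltages - epochs.voltages[:, :, m].mean(axis=2, keepdims=True)
    return epochs.with_voltages(corrected)


def window_average(epochs: EpochSet, window: WindowSpec, electrode: str) -> np.ndarray:
    """Per-trial mean voltage over a closed window at one electrode (µV)."""
    e = epochs.electrode_index(electrode)
    m = window.mask(epochs.times)
    return epochs.voltages[:, e, m].mean(axis=1)


# ---------------------------------------------------------------------------
# Grand averages
# ---------------------------------------------------------------------------

def grand_average(epochs: EpochSet, group_by: Sequence[str] = ("condition",)) -> WaveformSummary:
    """Two-stage grand average with across-subject standard errors.

    Trials are first averaged within subject (per group), then the subject
    means are averaged; ``se_uv`` is the standard deviation of the subject
    means (ddof=1) divided by sqrt(n_subjects), and is 0 when only one
    subject contributes. Subjects without trials in a group are excluded
    from that group with a logged warning.
    """
    group_by = tuple(group_by)
    for col in group_by:
        if col not in epochs.trials.columns:
            raise DomainError(f"unknown grouping column {col!r}")

    trials = epochs.trials
    if group_by:
        group_iter = trials.groupby(list(group_by), sort=True, observed=True).indices.items()
    else:
        group_iter = [((), np.arange(epochs.n_trials))]

    all_subjects = epochs.subjects
    records = []
    for gkey, idx in group_iter:
        gkey = gkey if isinstance(gkey, tuple) else (gkey,)
        sub_means = []
        present = trials.iloc[idx].groupby("subject", sort=False, observed=True).indices
        for s in all_subjects:
            if s not in present:
                logger.warning("subject %r has no trials in group %r; excluded", s, gkey)
                continue
            sub_means.append(epochs.voltages[idx[present[s]]].mean(axis=0))
        stack = np.stack(sub_means)  # (n_units, n_elec, n_samples)
        n_units = stack.shape[0]
        mean = stack.mean(axis=0)
        if n_units > 1:
            se = stack.std(axis=0, ddof=1) / np.sqrt(n_units)
        else:
            se = np.zeros_like(mean)
        for e, el in enumerate(epochs.electrodes):
            rec = pd.DataFrame({
                "electrode": el,
                "time_ms": epochs.times,
                "mean_uv": mean[e],
                "se_uv": se[e],
                "n_units": n_units,
            })
            for col, val in zip(group_by, gkey):
                rec[col] = val
            records.append(rec)
    data = pd.concat(records, ignore_index=True)
    cols = list(group_by) + ["electrode", "time_ms", "mean_uv", "se_uv", "n_units"]
    return WaveformSummary(data=data[cols], group_by=group_by, unit="subject")
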