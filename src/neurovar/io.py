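"""Epoched-EEG containers, the on-disk cohort store, and basic preprocessing.

The analysis operates on single-channel (Cz) epochs: per subject a
trials x time matrix in microvolts, sampled uniformly, spanning a
pre-stimulus baseline and a post-stimulus interval, with per-trial
condition and modality labels.  Ratings live in a separate long-format
table.  The store is deliberately language-neutral: binary ``.npy``
arrays for the data, TSV for all metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "EpochSet",
    "validate_ratings",
    "read_ratings",
    "write_ratings",
    "read_epochs",
    "write_epochs",
    "read_cohort",
    "write_cohort",
    "baseline_correct",
    "bandpass",
    "epochs_from_mne",
]

RATINGS_COLUMNS = ["subject_id", "modality", "condition", "trial_index", "rating"]


@dataclass
class EpochSet:
    """One subject's epoched single-channel EEG.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    sfreq : float
        Sampling rate in Hz.
    times : ndarray
        Time axis in milliseconds, uniform step ``1000/sfreq``, with t=0 at
        stimulus onset.  Must contain both pre- and post-stimulus samples.
    data : ndarray, shape (n_trials, n_times)
        Single-trial voltage traces in microvolts (float64).
    condition : ndarray of str, shape (n_trials,)
        Per-trial intensity condition label (e.g. ``"low"``/``"high"``).
    modality : ndarray of str, shape (n_trials,)
        Per-trial stimulus modality label.
    channel : str
        Electrode name; the analysis contract is a single channel (Cz).
    """

    subject_id: str
    sfreq: float
    times: np.ndarray
    data: np.ndarray
    condition: np.ndarray
    modality: np.ndarray = field(default=None)
    channel: str = "Cz"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.data = np.asarray(self.data, dtype=np.float64)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.modality is None:
            self.modality = np.full(self.data.shape[0], "pain", dtype=object)
        self.modality = np.asarray(self.modality, dtype=object)
        if self.data.ndim != 2:
            raise ValueError("data must be a trials x time matrix")
        if self.data.shape[1] != self.times.size:
            raise ValueError(
                f"data has {self.data.shape[1]} samples but times has {self.times.size}"
            )
        if self.condition.size != self.data.shape[0]:
            raise ValueError("condition labels must match trial count")
        if self.modality.size != self.data.shape[0]:
            raise ValueError("modality labels must match trial count")
        dt = np.diff(self.times)
        if self.times.size < 2 or np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.allclose(dt, 1000.0 / self.sfreq, rtol=1e-6, atol=1e-9):
            raise ValueError("times step must equal 1000/sfreq ms")
        if not (self.times[0] < 0 <= self.times[-1]):
            raise ValueError("epoch window must span stimulus onset (t=0)")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "EpochSet":
        return replace(
            self,
            times=self.times.copy(),
            data=self.data.copy(),
            condition=self.condition.copy(),
            modality=self.modality.copy(),
        )

    def select(self, condition: str | None = None, modality: str | None = None) -> "EpochSet":
        """Return the sub-EpochSet with the given condition and/or modality."""
        mask = np.ones(self.n_trials, dtype=bool)
        if condition is not None:
            mask &= self.condition == condition
        if modality is not None:
            mask &= self.modality == modality
        return replace(
            self,
            data=self.data[mask],
            condition=self.condition[mask],
            modality=self.modality[mask],
        )


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a ratings table (0-10 NRS, unique trial keys); return it."""
    missing = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ratings table missing columns: {missing}")
    r = df["rating"].to_numpy(dtype=float)
    if np.any(~np.isfinite(r)) or np.any(r < 0) or np.any(r > 10):
        raise ValueError("ratings must be finite and within [0, 10]")
    keys = df[["subject_id", "modality", "condition", "trial_index"]]
    if keys.duplicated().any():
        raise ValueError("(subject, modality, condition, trial) keys must be unique")
    return df


def write_ratings(df: pd.DataFrame, path: str | Path) -> None:
    validate_ratings(df)
    df.to_csv(path, sep="\t", index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"ratings file not found: {path}")
    return validate_ratings(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Cohort store: <dir>/meta.json, <dir>/trials.tsv, <dir>/<subject>.npy
# ---------------------------------------------------------------------------

def write_cohort(cohort: list[EpochSet], path: str | Path) -> None:
    """Write a cohort of EpochSets to a directory store (lossless float64)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    first = cohort[0]
    meta = {
        "channel": first.channel,
        "sfreq": first.sfreq,
        "times_ms": first.times.tolist(),
        "subjects": [e.subject_id for e in cohort],
    }
    (path / "meta.json").write_text(json.dumps(meta))
    rows = []
    for e in cohort:
        np.save(path / f"{e.subject_id}.npy", e.data)
        for k in range(e.n_trials):
            rows.append((e.subject_id, k, e.condition[k], e.modality[k]))
    pd.DataFrame(rows, columns=["subject_id", "trial_index", "condition", "modality"]).to_csv(
        path / "trials.tsv", sep="\t", index=False
    )


def read_cohort(path: str | Path) -> list[EpochSet]:
    """Read every subject's EpochSet back from a cohort store."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file: {meta_path}")
    trials_path = path / "trials.tsv"
    if not trials_path.exists():
        raise FileNotFoundError(f"missing metadata file: {trials_path}")
    meta = json.loads(meta_path.read_text())
    trials = pd.read_csv(trials_path, sep="\t")
    times = np.asarray(meta["times_ms"], dtype=float)
    cohort = []
    for sid in meta["subjects"]:
        data = np.load(path / f"{sid}.npy")
        t = trials[trials["subject_id"].astype(str) == str(sid)].sort_values("trial_index")
        if len(t) != data.shape[0]:
            raise ValueError(
                f"subject {sid}: {data.shape[0]} trials in array, {len(t)} metadata rows"
            )
        cohort.append(
            EpochSet(
                subject_id=str(sid),
                channel=meta["channel"],
                sfreq=float(meta["sfreq"]),
                times=times,
                data=data,
                condition=t["condition"].to_numpy(dtype=object),
                modality=t["modality"].to_numpy(dtype=object),
            )
        )
    return cohort


def write_epochs(e: EpochSet, path: str | Path) -> None:
    """Write a single subject as a one-subject cohort store."""
    write_cohort([e], path)


def read_epochs(path: str | Path, subject_id: str | None = None) -> EpochSet:
    """Read one subject's EpochSet from a cohort store (the only one by default)."""
    cohort = read_cohort(path)
    if subject_id is None:
        if len(cohort) != 1:
            raise ValueError("store holds several subjects; pass subject_id")
        return cohort[0]
    for e in cohort:
        if e.subject_id == str(subject_id):
            return e
    raise KeyError(f"subject {subject_id!r} not in store")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def epochs_from_mne(
    epochs,
    subject_id: str,
    channel: str = "Cz",
    condition: np.ndarray | list | None = None,
    modality: np.ndarray | list | None = None,
) -> EpochSet:
    """Adapter from an ``mne.Epochs``-like object to a single-channel EpochSet.

    Lets recordings loaded through mne's readers (EDF, BrainVision, ...)
    enter the pipeline; the channel is extracted and volts are converted to
    microvolts.  Condition labels default to the mne event names.  This is
    an adapter only — the core pipeline operates on the documented store.
    """
    if channel not in epochs.ch_names:
        raise ValueError(f"channel {channel!r} not found in {epochs.ch_names[:8]}...")
    data = epochs.get_data(picks=[channel])[:, 0, :] * 1e6
    if condition is None:
        inv = {v: k for k, v in epochs.event_id.items()}
        condition = [inv[code] for code in epochs.events[:, 2]]
    return EpochSet(
        subject_id=subject_id,
        channel=channel,
        sfreq=float(epochs.info["sfreq"]),
        times=epochs.times * 1000.0,
        data=data,
        condition=np.asarray(condition, dtype=object),
        modality=None if modality is None else np.asarray(modality, dtype=object),
    )


def baseline_correct(e: EpochSet, interval: tuple[float, float] = (-500.0, 0.0)) -> EpochSet:
    """Subtract each trial's mean over the pre-stimulus interval (ms, inclusive)."""
    lo, hi = interval
    if lo >= hi:
        raise ValueError(f"invalid baseline interval {interval}")
    mask = (e.times >= lo) & (e.times <= hi)
    if not mask.any() or lo < e.times[0] - 1e-9 or hi > e.times[-1] + 1e-9:
        raise ValueError("baseline interval outside epoch times")
    out = e.copy()
    out.data = out.data - out.data[:, mask].mean(axis=1, keepdims=True)
    return out


def bandpass(e: EpochSet, lo: float, hi: float, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of each trial.

    A 4th-order Butterworth is applied forward and backward (``sosfiltfilt``)
    so N2/P2-like latencies are not shifted by filter delay.
    """
    if not (0 < lo < hi < e.sfreq / 2):
        raise ValueError(f"invalid band ({lo}, {hi}) Hz at sfreq {e.sfreq}")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=e.sfreq, output="sos")
    out = e.copy()
    # generous reflect padding: the low edge (~1 Hz) has a transient long
    # enough to leak into the epoch under scipy's default padlen
    padlen = min(out.data.shape[1] - 1, 3 * int(e.sfreq / lo))
    out.data = signal.sosfiltfilt(sos, out.data, axis=1, padlen=padlen)
    return out
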