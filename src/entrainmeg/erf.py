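"""Sensor-level event-related fields.

Preprocessing follows the conventional evoked-response chain: zero-phase
band-pass filtering of the continuous per-trial recordings, a single
pre-fixation baseline per trial (applied to every stimulus-locked epoch of
that trial), stimulus-locked epoching, trial averaging, and combination of
each planar-gradiometer pair into one nonnegative channel via the Euclidean
norm.  Peak (or mean) amplitudes of the combined ERF are read out from a
set of occipital sensors selected on independent localizer data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .sensors import SensorArray
from .simulate import TrialRecordings
from . import design as design_mod

#: default epoch windows (ms relative to stimulus onset)
DEFAULT_EPOCH_WINDOWS = {
    "E1": (-50.0, 270.0), "E2": (-50.0, 270.0), "E3": (-50.0, 270.0),
    "E4": (-50.0, 600.0), "T": (-400.0, 550.0),
}
#: windows used for decoding segmentation
DECODING_EPOCH_WINDOWS = {
    "E1": (-50.0, 250.0), "E2": (-50.0, 250.0), "E3": (-50.0, 250.0),
    "E4": (-50.0, 600.0), "T": (-400.0, 550.0),
}


@dataclass
class EpochSet:
    data: np.ndarray          # (n_trials, n_channels, n_samples)
    times: np.ndarray         # ms relative to the lock event
    sfreq: float
    metadata: pd.DataFrame    # design rows, one per trial
    lock: str                 # 'fixation' | 'E1'..'E4' | 'T'
    ch_names: list[str]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return replace(self, data=self.data[mask],
                       metadata=self.metadata.iloc[mask].reset_index(drop=True))


@dataclass
class Evoked:
    data: np.ndarray          # (n_channels, n_samples)
    times: np.ndarray
    sfreq: float
    ch_names: list[str]
    n_trials_averaged: int
    lock: str
    combined: bool = False
    sites: np.ndarray | None = None   # combined channel -> site index


class EpochRangeError(ValueError):
    """An event (reported with its trial_id) falls outside the recording."""


def bandpass(rec, lo: float = 0.5, hi: float = 45.0, order: int = 4):
    """Zero-phase Butterworth band-pass along the time axis.

    Accepts :class:`TrialRecordings` or :class:`EpochSet`; filtering the
    continuous recordings (before epoching) avoids edge artifacts inside
    the short stimulus-locked windows.
    """
    if not 0.0 < lo < hi < rec.sfreq / 2.0:
        raise ValueError(f"band [{lo}, {hi}] Hz invalid for "
                         f"sfreq {rec.sfreq} Hz")
    sos = butter(order, [lo, hi], btype="bandpass", fs=rec.sfreq,
                 output="sos")
    return replace(rec, data=sosfiltfilt(sos, rec.data, axis=-1))


def baseline_means(rec: TrialRecordings,
                   window: tuple[float, float] = (-400.0, 0.0)) -> np.ndarray:
    """Per-trial, per-channel mean over the pre-fixation window
    (ms relative to fixation onset)."""
    lo, hi = window
    if lo < rec.times[0] - 1e-9:
        raise EpochRangeError(
            f"baseline window starts at {lo} ms but recordings begin at "
            f"{rec.times[0]} ms")
    mask = (rec.times >= lo) & (rec.times < hi)
    return rec.data[:, :, mask].mean(axis=-1)


def baseline_correct(obj, means: np.ndarray | None = None,
                     window: tuple[float, float] = (-400.0, 0.0)):
    """Subtract the pre-fixation baseline.

    For :class:`TrialRecordings` the baseline is computed from the object
    itself; for :class:`EpochSet` the per-trial means (computed once from
    the continuous recordings, so the same baseline serves all locks of a
    trial) must be supplied.
    """
    if means is None:
        if not isinstance(obj, TrialRecordings):
            raise ValueError("epochs need explicit per-trial baseline means")
        means = baseline_means(obj, window)
    if means.shape != obj.data.shape[:2]:
        raise ValueError("baseline means shape mismatch")
    return replace(obj, data=obj.data - means[:, :, None])


def epoch(rec: TrialRecordings, lock: str,
          window: tuple[float, float] | None = None) -> EpochSet:
    """Cut stimulus-locked epochs; sample 0 of the output time axis is the
    lock-event onset, so jittered trials are realigned on the stimulus."""
    if lock not in design_mod.ONSET_COLUMNS:
        raise ValueError(f"unknown lock {lock!r}")
    if window is None:
        window = DEFAULT_EPOCH_WINDOWS.get(lock, (-50.0, 270.0))
    w0, w1 = window
    dt = 1000.0 / rec.sfreq
    off0 = int(round(w0 / dt))
    n_out = int(round((w1 - w0) / dt)) + 1
    out_times = (off0 + np.arange(n_out)) * dt

    onsets = rec.design[design_mod.ONSET_COLUMNS[lock]].to_numpy(dtype=float)
    keep, slices = [], []
    for i, onset in enumerate(onsets):
        if np.isnan(onset):
            raise EpochRangeError(
                f"trial {rec.design['trial_id'].iloc[i]}: no {lock} event")
        i_on = int(round((onset - rec.times[0]) / dt))
        start = i_on + off0
        if start < 0 or start + n_out > rec.data.shape[-1]:
            raise EpochRangeError(
                f"trial {rec.design['trial_id'].iloc[i]}: {lock} window "
                f"[{w0}, {w1}] ms outside the recording")
        keep.append(i)
        slices.append(rec.data[i, :, start:start + n_out])

    data = (np.stack(slices) if slices
            else np.empty((0, len(rec.ch_names), n_out)))
    return EpochSet(data=data, times=out_times, sfreq=rec.sfreq,
                    metadata=rec.design.iloc[keep].reset_index(drop=True),
                    lock=lock, ch_names=list(rec.ch_names))


def average(epochs: EpochSet, mask=None) -> Evoked:
    sub = epochs if mask is None else epochs.select(mask)
    if sub.n_trials == 0:
        raise ValueError("cannot average an empty EpochSet")
    return Evoked(data=sub.data.mean(axis=0), times=sub.times,
                  sfreq=sub.sfreq, ch_names=list(sub.ch_names),
                  n_trials_averaged=sub.n_trials, lock=sub.lock)


def combine_planar(evoked: Evoked, sensors: SensorArray) -> Evoked:
    """One nonnegative channel per gradiometer pair:
    ``sqrt(g1(t)^2 + g2(t)^2)``; magnetometers are dropped."""
    if evoked.combined:
        raise ValueError("evoked is already planar-combined")
    name_to_idx = {n: i for i, n in enumerate(evoked.ch_names)}
    rows, names, sites = [], [], []
    for site, (i, j) in enumerate(sensors.grad_pairs()):
        try:
            a = evoked.data[name_to_idx[sensors.ch_names[i]]]
            b = evoked.data[name_to_idx[sensors.ch_names[j]]]
        except KeyError as err:
            raise ValueError(f"gradiometer {err} missing from evoked") from None
        rows.append(np.sqrt(a ** 2 + b ** 2))
        names.append(sensors.pair_names()[site])
        sites.append(site)
    return Evoked(data=np.stack(rows), times=evoked.times,
                  sfreq=evoked.sfreq, ch_names=names,
                  n_trials_averaged=evoked.n_trials_averaged,
                  lock=evoked.lock, combined=True, sites=np.asarray(sites))


def select_sensors_by_localizer(localizer_evoked: Evoked, k: int = 5,
                                window: tuple[float, float] = (85.0, 135.0),
                                ) -> list[str]:
    """The ``k`` combined channels with the largest peak amplitude inside
    the window; ties broken lexicographically by channel name."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(localizer_evoked.ch_names):
        raise ValueError("k exceeds the number of channels")
    if not localizer_evoked.combined:
        raise ValueError("localizer evoked must be planar-combined")
    mask = _window_mask(localizer_evoked.times, window)
    peaks = localizer_evoked.data[:, mask].max(axis=1)
    order = sorted(range(len(peaks)),
                   key=lambda i: (-peaks[i], localizer_evoked.ch_names[i]))
    return [localizer_evoked.ch_names[i] for i in order[:k]]


def window_amplitude(evoked: Evoked, sensor_names,
                     window: tuple[float, float] = (85.0, 135.0),
                     mode: str = "peak") -> float:
    """Amplitude of the sensor-averaged combined ERF inside the window
    (``peak`` = maximum, ``mean`` = time average)."""
    if mode not in ("peak", "mean"):
        raise ValueError("mode must be 'peak' or 'mean'")
    names = list(sensor_names)
    if not names:
        raise ValueError("empty sensor set")
    idx = [evoked.ch_names.index(n) for n in names]
    mask = _window_mask(evoked.times, window)
    trace = evoked.data[idx][:, mask].mean(axis=0)
    return float(trace.max() if mode == "peak" else trace.mean())


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    if lo < times[0] - 1e-9 or hi > times[-1] + 1e-9:
        raise ValueError(f"window [{lo}, {hi}] ms outside the time axis "
                         f"[{times[0]}, {times[-1]}] ms")
    return (times >= lo - 1e-9) & (times <= hi + 1e-9)


def epochs_from_fif(path, sensors: SensorArray | None = None) -> EpochSet:
    """Import epochs from a Neuromag FIF epochs file (requires ``mne``).

    Channel typing follows the FIF convention (magnetometer names ending in
    '1', planar gradiometers in '2'/'3'); metadata is taken from the file's
    metadata table if present.
    """
    import mne  # optional dependency

    ep = mne.read_epochs(path, preload=True, verbose="error")
    picks = mne.pick_types(ep.info, meg=True)
    names = [ep.ch_names[i] for i in picks]
    meta = (ep.metadata.reset_index(drop=True) if ep.metadata is not None
            else pd.DataFrame({"trial_id": np.arange(len(ep))}))
    return EpochSet(data=ep.get_data(picks=picks),
                    times=ep.times * 1000.0,
                    sfreq=float(ep.info["sfreq"]),
                    metadata=meta, lock="T", ch_names=names)
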