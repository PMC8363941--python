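"""Synthetic sensor-space MEG generator.

Each trial is simulated as a continuous multichannel recording spanning
400 ms before fixation onset to 400 ms after target offset.  Every stimulus
contributes

* a condition-independent evoked response: a Gaussian-windowed waveform
  peaking ``peak_latency`` ms after stimulus onset, projected through an
  occipital current dipole.  In orientation-predictable conditions the
  dipole moment shrinks linearly across entrainers
  (``1 - (k-1) * suppression_per_entrainer`` at entrainer k), with an extra
  multiplicative reduction at E4 when the timing is jittered
  (``what_only`` condition) - the expectation-suppression structure; and
* an orientation-coded pattern: a second dipole whose moment sign follows
  the target class (vertical vs horizontal), scaled by the per-entrainer
  schedule rho_1..rho_4.  The schedule is applied only in
  orientation-predictable conditions, so decodable orientation information
  grows across entrainers exactly when the orientation is predictable.
  The target itself carries an orientation pattern (predictable conditions)
  and a spatial-frequency pattern (all conditions) via a third dipole.

Additive noise is Gaussian, spatially correlated across channels with an
exponentially decaying covariance ``exp(-d / noise_spatial_corr)`` (plus a
per-channel nugget so the covariance stays full rank), and temporally AR(1).
Identical seeds reproduce identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import h5py
import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import design as design_mod
from .forward import forward_field
from .sensors import SensorArray

#: default dipole geometry (metres, head-sphere frame; occiput toward -y)
EVOKED_DIPOLE_POS = np.array([0.0, -0.065, 0.005])
PATTERN_DIPOLE_POS = np.array([0.018, -0.058, 0.012])
CPD_DIPOLE_POS = np.array([-0.018, -0.058, 0.012])


@dataclass
class EffectSpec:
    """Effect structure injected by the simulator.

    Amplitudes are dipole moments in A*m; the defaults give single-trial
    occipital magnetometer peaks of a few hundred fT against 200 fT sensor
    noise, i.e. realistic single-trial SNR below one.
    """

    peak_latency: float = 100.0          # ms post stimulus onset
    peak_width: float = 15.0             # Gaussian SD, ms
    base_amplitude: float = 50e-9        # evoked dipole moment, A*m
    suppression_per_entrainer: float = 0.15
    extra_E4_suppression_jittered: float = 0.15
    pattern_snr_schedule: tuple = (0.01, 0.02, 0.05, 0.08)
    target_pattern_snr: float = 0.12
    cpd_pattern_snr: float = 0.2
    noise_sd: float = 200e-15            # magnetometer noise SD, T
    grad_noise_factor: float = 20.0      # gradiometer SD = factor * noise_sd
    noise_spatial_corr: float = 0.03     # decay length, metres
    noise_channel_nugget: float = 0.2    # independent variance fraction
    noise_ar1: float = 0.95
    seed: int = 0

    def validate(self) -> list[str]:
        issues = []
        if not 0.0 <= self.suppression_per_entrainer < 1.0:
            issues.append("suppression_per_entrainer must be in [0, 1)")
        if not 0.0 <= self.extra_E4_suppression_jittered < 1.0:
            issues.append("extra_E4_suppression_jittered must be in [0, 1)")
        rho = np.asarray(self.pattern_snr_schedule, dtype=float)
        if rho.shape != (4,) or np.any(rho < 0):
            issues.append("pattern_snr_schedule must be 4 nonnegative values")
        elif np.any(rho > 0) and np.any(np.diff(rho) < 0):
            issues.append("nonzero pattern_snr_schedule must be nondecreasing")
        if not 0.0 <= self.noise_ar1 < 1.0:
            issues.append("noise_ar1 must be in [0, 1)")
        if self.noise_sd < 0:
            issues.append("noise_sd must be nonnegative")
        return issues


@dataclass
class TrialRecordings:
    """Rectangular per-trial continuous recordings with a shared time axis
    (ms, 0 = fixation onset) and the design rows they realise."""

    data: np.ndarray           # (n_trials, n_channels, n_samples)
    times: np.ndarray          # ms
    sfreq: float
    design: pd.DataFrame
    ch_names: list[str]
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def events(self) -> pd.DataFrame:
        """Long-format event list: one row per (trial, stimulus) onset."""
        rows = []
        t0 = self.times[0]
        for stim, col in design_mod.ONSET_COLUMNS.items():
            onsets = self.design[col].to_numpy(dtype=float)
            for tid, onset in zip(self.design["trial_id"], onsets):
                if np.isnan(onset):
                    continue
                sample = int(round((onset - t0) * self.sfreq / 1000.0))
                rows.append((int(tid), stim, onset, sample))
        return pd.DataFrame(rows, columns=["trial_id", "stimulus",
                                           "onset_ms", "sample"])


class TimingError(ValueError):
    """Raised when stimulus windows overlap or fall outside the recording."""


def _tangential_unit(pos: np.ndarray, reference: np.ndarray) -> np.ndarray:
    radial = pos / np.linalg.norm(pos)
    tang = reference - (reference @ radial) * radial
    return tang / np.linalg.norm(tang)


def _stimulus_amplitude(effects: EffectSpec, condition: str,
                        stimulus: str) -> float:
    """Evoked dipole moment for one stimulus under the suppression
    schedule."""
    base = effects.base_amplitude
    if stimulus == "T" or condition not in design_mod.ORIENTATION_PREDICTABLE:
        return base
    k = int(stimulus[1])  # E1..E4
    amp = base * (1.0 - (k - 1) * effects.suppression_per_entrainer)
    if stimulus == "E4" and condition not in design_mod.TIME_PREDICTABLE:
        amp *= 1.0 - effects.extra_E4_suppression_jittered
    return amp


def _pattern_amplitude(effects: EffectSpec, condition: str, stimulus: str,
                       target_deg: float) -> float:
    """Signed orientation-pattern dipole moment (0 when no information is
    injected)."""
    predictable = condition in design_mod.ORIENTATION_PREDICTABLE
    if condition == "localizer":
        rho = effects.target_pattern_snr if stimulus == "T" else 0.0
    elif not predictable:
        rho = 0.0
    elif stimulus == "T":
        rho = effects.target_pattern_snr
    else:
        rho = float(effects.pattern_snr_schedule[int(stimulus[1]) - 1])
    sign = 1.0 if target_deg == 90.0 else -1.0
    return sign * rho * effects.base_amplitude


def simulate_participant(design: pd.DataFrame, sensors: SensorArray,
                         effects: EffectSpec | None = None,
                         sfreq: float = 1000.0,
                         pad_ms: float = 400.0) -> TrialRecordings:
    """Simulate continuous per-trial recordings for one participant."""
    if sfreq < 500.0:
        raise ValueError("sfreq must be at least 500 Hz")
    effects = effects or EffectSpec()
    problems = effects.validate()
    if problems:
        raise ValueError("invalid EffectSpec: " + "; ".join(problems))
    rng = np.random.default_rng(effects.seed)

    stim_dur = design_mod.STIM_DURATION_MS
    onset_cols = [design_mod.ONSET_COLUMNS[s] for s in design_mod.STIMULI]
    onsets_all = design[onset_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(np.diff(onsets_all, axis=1) < stim_dur - 1e-9):
            raise TimingError("stimulus windows overlap in the design")

    t_start = -pad_ms
    t_end = float(np.nanmax(onsets_all)) + stim_dur + pad_ms
    n_samples = int(round((t_end - t_start) * sfreq / 1000.0)) + 1
    times = t_start + np.arange(n_samples) * 1000.0 / sfreq

    center = sensors.head_center
    topo_evoked = forward_field(
        EVOKED_DIPOLE_POS,
        _tangential_unit(EVOKED_DIPOLE_POS, np.array([1.0, 0.0, 0.0])),
        center, sensors)
    topo_pattern = forward_field(
        PATTERN_DIPOLE_POS,
        _tangential_unit(PATTERN_DIPOLE_POS, np.array([0.0, 0.0, 1.0])),
        center, sensors)
    topo_cpd = forward_field(
        CPD_DIPOLE_POS,
        _tangential_unit(CPD_DIPOLE_POS, np.array([0.0, 0.0, 1.0])),
        center, sensors)

    n_trials = len(design)
    n_ch = sensors.n_channels
    data = np.zeros((n_trials, n_ch, n_samples))

    sigma = effects.peak_width
    for i, row in enumerate(design.itertuples(index=False)):
        for stim, col in zip(design_mod.STIMULI, onset_cols):
            onset = getattr(row, col)
            if onset is None or np.isnan(onset):
                continue
            mu = onset + effects.peak_latency
            wave = np.exp(-0.5 * ((times - mu) / sigma) ** 2)
            amp = _stimulus_amplitude(effects, row.condition, stim)
            topo = amp * topo_evoked
            rho = _pattern_amplitude(effects, row.condition, stim,
                                     row.target_deg)
            if rho != 0.0:
                topo = topo + rho * topo_pattern
            if stim == "T" and row.condition != "localizer":
                sign = 1.0 if row.target_cpd > row.entrainer_cpd else -1.0
                topo = topo + (sign * effects.cpd_pattern_snr
                               * effects.base_amplitude * topo_cpd)
            data[i] += topo[:, None] * wave[None, :]

    if effects.noise_sd > 0:
        data += _correlated_noise(rng, sensors, effects, n_trials, n_samples)

    return TrialRecordings(data=data, times=times, sfreq=sfreq,
                           design=design.reset_index(drop=True),
                           ch_names=list(sensors.ch_names),
                           seed=effects.seed)


def _correlated_noise(rng, sensors: SensorArray, effects: EffectSpec,
                      n_trials: int, n_samples: int,
                      burn_in: int = 400) -> np.ndarray:
    """Spatially correlated AR(1) Gaussian noise, unit stationary variance
    per channel before per-type scaling."""
    d = np.linalg.norm(sensors.ch_pos[:, None] - sensors.ch_pos[None, :],
                       axis=-1)
    nug = effects.noise_channel_nugget
    corr = ((1.0 - nug) * np.exp(-d / effects.noise_spatial_corr)
            + nug * np.eye(sensors.n_channels))
    chol = np.linalg.cholesky(corr)

    a = effects.noise_ar1
    total = n_samples + burn_in
    scale = np.where(sensors.ch_types == "grad",
                     effects.noise_sd * effects.grad_noise_factor,
                     effects.noise_sd).astype(float)
    out = np.empty((n_trials, sensors.n_channels, n_samples))
    chunk = max(1, int(2e8 // (sensors.n_channels * total)))
    for start in range(0, n_trials, chunk):
        stop = min(start + chunk, n_trials)
        eps = rng.standard_normal((stop - start, sensors.n_channels, total))
        eps = np.einsum("ck,tkn->tcn", chol, eps)
        noise = lfilter([np.sqrt(1.0 - a ** 2)], [1.0, -a], eps, axis=-1)
        out[start:stop] = noise[..., burn_in:] * scale[None, :, None]
    return out


def save_recordings(rec: TrialRecordings, path) -> None:
    """HDF5 layout: /data, /times (s), /events, attrs sfreq and seed; the
    design table travels as a CSV-encoded string dataset."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("times", data=rec.times / 1000.0)
        ev = rec.events()
        f.create_dataset("events",
                         data=np.column_stack([ev["trial_id"],
                                               ev["sample"]]).astype(np.int64))
        f.create_dataset("event_stimulus",
                         data=np.array(ev["stimulus"], dtype="S4"))
        f.create_dataset("design_csv",
                         data=np.bytes_(rec.design.to_csv(index=False)))
        f.create_dataset("ch_names",
                         data=np.array(rec.ch_names, dtype="S16"))
        f.attrs["sfreq"] = rec.sfreq
        f.attrs["seed"] = rec.seed


def load_recordings(path) -> TrialRecordings:
    import io as _io
    with h5py.File(path, "r") as f:
        design = pd.read_csv(_io.BytesIO(f["design_csv"][()]))
        return TrialRecordings(
            data=f["data"][()],
            times=f["times"][()] * 1000.0,
            sfreq=float(f.attrs["sfreq"]),
            design=design,
            ch_names=[n.decode() for n in f["ch_names"][()]],
            seed=int(f.attrs["seed"]),
        )


def effectspec_to_dict(effects: EffectSpec) -> dict:
    d = asdict(effects)
    d["pattern_snr_schedule"] = list(effects.pattern_snr_schedule)
    return d
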