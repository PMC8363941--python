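from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from entrainmeg import design as dz
from entrainmeg import erf
from entrainmeg.erf import EpochSet, Evoked
from entrainmeg.simulate import EffectSpec, simulate_participant


def _toy_recording(data, sfreq=1000.0, t0=-400.0, onsets=None):
    """Wrap an array as TrialRecordings-like input for the ERF helpers."""
    from entrainmeg.simulate import TrialRecordings

    n_trials, n_ch, n_samp = data.shape
    times = t0 + np.arange(n_samp) * 1000.0 / sfreq
    design = dz.generate_design(4, seed=0).iloc[:n_trials].copy()
    design.reset_index(drop=True, inplace=True)
    if onsets is not None:
        for col, val in onsets.items():
            design[col] = val
    return TrialRecordings(data=data, times=times, sfreq=sfreq,
                           design=design,
                           ch_names=[f"c{i}" for i in range(n_ch)])


# ---------------------------------------------------------------- filtering

def test_bandpass_preserves_in_band_and_rejects_out_of_band():
    """Amplitude at the probe frequency (quadrature fit away from the
    edges, so slow edge transients do not contaminate the estimate)."""
    sfreq = 1000.0
    t = np.arange(0, 4.0, 1 / sfreq)
    for freq, expect_keep in ((10.0, True), (100.0, False)):
        sig = np.sin(2 * np.pi * freq * t)[None, None, :]
        rec = _toy_recording(sig.copy(), sfreq=sfreq, t0=0.0)
        out = erf.bandpass(rec, 0.5, 45.0).data[0, 0]
        mid = slice(1000, 3000)
        basis = np.column_stack([np.sin(2 * np.pi * freq * t[mid]),
                                 np.cos(2 * np.pi * freq * t[mid])])
        coef, *_ = np.linalg.lstsq(basis, out[mid], rcond=None)
        amplitude = np.hypot(*coef)
        if expect_keep:
            assert abs(amplitude - 1.0) < 0.01
        else:
            assert amplitude < 0.10


def test_bandpass_zero_in_zero_out_and_bad_band():
    rec = _toy_recording(np.zeros((1, 2, 1000)))
    assert np.all(erf.bandpass(rec).data == 0)
    with pytest.raises(ValueError):
        erf.bandpass(rec, 45.0, 0.5)


# ----------------------------------------------------------------- epoching

def test_epoch_sample_arithmetic(sensors20):
    design = dz.generate_design(4, seed=0)
    rec = simulate_participant(design, sensors20,
                               EffectSpec(noise_sd=0.0))
    ep = erf.epoch(rec, "E1", (-50.0, 250.0))
    assert ep.data.shape[-1] == 301
    assert ep.times[0] == -50.0 and ep.times[-1] == 250.0
    assert ep.times[50] == 0.0


def test_epoch_realigns_jittered_trials_on_the_stimulus(sensors20):
    """The evoked peak lands on the same sample index in every trial even
    though jittered onsets differ trial to trial."""
    design = dz.generate_design(8, seed=1)
    rec = simulate_participant(design, sensors20, EffectSpec(noise_sd=0.0))
    mask = rec.design["condition"].to_numpy() == "random"
    ep = erf.epoch(rec, "E3", (-50.0, 250.0)).select(mask)
    onsets = ep.metadata["e3_onset_ms"].to_numpy()
    assert len(np.unique(onsets)) > 1  # genuinely jittered
    norms = np.linalg.norm(ep.data, axis=1)  # (trials, samples)
    peaks = norms.argmax(axis=1)
    assert np.all(peaks == peaks[0])
    assert ep.times[peaks[0]] == 100.0  # configured peak latency


def test_epoch_empty_design_gives_empty_epochset(sensors20):
    design = dz.generate_design(4, seed=0)
    rec = simulate_participant(design, sensors20, EffectSpec(noise_sd=0.0))
    rec = replace(rec, data=rec.data[:0],
                  design=rec.design.iloc[:0])
    ep = erf.epoch(rec, "E1")
    assert ep.n_trials == 0


def test_epoch_out_of_range_names_the_trial(sensors20):
    design = dz.generate_design(4, seed=0)
    rec = simulate_participant(design, sensors20, EffectSpec(noise_sd=0.0))
    bad = rec.design.copy()
    bad.loc[0, "t_onset_ms"] = rec.times[-1] + 1000.0
    rec = replace(rec, design=bad)
    with pytest.raises(erf.EpochRangeError, match="trial"):
        erf.epoch(rec, "T", (-400.0, 550.0))


# ----------------------------------------------------------------- baseline

def test_baseline_hand_example():
    data = np.zeros((1, 1, 7))
    data[0, 0] = [2.0, 2.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    rec = _toy_recording(data, sfreq=1000.0, t0=-4.0)
    out = erf.baseline_correct(rec, window=(-4.0, 0.0))
    np.testing.assert_allclose(out.data[0, 0, 4:], [1.0, 2.0, 3.0])


def test_baseline_constant_goes_to_zero():
    rec = _toy_recording(np.full((2, 3, 500), 7.5))
    out = erf.baseline_correct(rec, window=(-400.0, 0.0))
    assert np.allclose(out.data, 0.0)


@settings(max_examples=20, deadline=None)
@given(offset=st.floats(-1e3, 1e3, allow_nan=False))
def test_baseline_removes_per_channel_offsets(offset):
    rng = np.random.default_rng(0)
    data = rng.standard_normal((2, 3, 500))
    rec = erf.baseline_correct(_toy_recording(data.copy()))
    rec_off = erf.baseline_correct(_toy_recording(data + offset))
    np.testing.assert_allclose(rec_off.data, rec.data, atol=1e-9)


# --------------------------------------------------------- planar combining

def _evoked_from(data, ch_names, combined=False):
    times = np.arange(data.shape[-1], dtype=float)
    return Evoked(data=data, times=times, sfreq=1000.0, ch_names=ch_names,
                  n_trials_averaged=1, lock="E1", combined=combined)


def test_combine_planar_examples(sensors20):
    ev_data = np.zeros((sensors20.n_channels, 4))
    i, j = sensors20.grad_pairs()[0]
    ev_data[i, 0], ev_data[j, 0] = 3.0, 4.0
    ev = _evoked_from(ev_data, list(sensors20.ch_names))
    comb = erf.combine_planar(ev, sensors20)
    assert comb.data[0, 0] == pytest.approx(5.0)
    assert comb.data[0, 1] == 0.0
    assert comb.data.min() >= 0.0
    assert len(comb.ch_names) == sensors20.n_sites
    with pytest.raises(ValueError):
        erf.combine_planar(comb, sensors20)


def test_combine_planar_matches_elementwise_oracle(sensors20, rng):
    data = rng.standard_normal((sensors20.n_channels, 50))
    comb = erf.combine_planar(_evoked_from(data, list(sensors20.ch_names)),
                              sensors20)
    for site, (i, j) in enumerate(sensors20.grad_pairs()):
        np.testing.assert_array_equal(
            comb.data[site], np.sqrt(data[i] ** 2 + data[j] ** 2))


@settings(max_examples=20, deadline=None)
@given(angle=st.floats(0, 2 * np.pi))
def test_combine_planar_rotation_invariance(angle):
    """The pair norm is invariant under a joint planar rotation of the two
    gradiometer signals."""
    from entrainmeg.sensors import make_sensor_array

    sensors = make_sensor_array(4, neighbor_radius=0.3)
    rng = np.random.default_rng(1)
    data = rng.standard_normal((sensors.n_channels, 30))
    rot = data.copy()
    c, s = np.cos(angle), np.sin(angle)
    for i, j in sensors.grad_pairs():
        rot[i] = c * data[i] - s * data[j]
        rot[j] = s * data[i] + c * data[j]
    a = erf.combine_planar(_evoked_from(data, list(sensors.ch_names)),
                           sensors)
    b = erf.combine_planar(_evoked_from(rot, list(sensors.ch_names)),
                           sensors)
    np.testing.assert_allclose(a.data, b.data, atol=1e-12)


# ------------------------------------------------- averaging and amplitudes

def test_epoch_then_average_equals_average_then_epoch(sensors20):
    """Linearity: for isochronous trials, averaging recordings first and
    epoching after gives the same evoked."""
    design = dz.generate_design(8, seed=2)
    rec = simulate_participant(design, sensors20, EffectSpec(seed=5))
    mask = rec.design["condition"].to_numpy() == "what_when"
    ev = erf.average(erf.epoch(rec, "E2", (-50, 250)), mask)

    mean_rec = replace(rec, data=rec.data[mask].mean(axis=0)[None],
                       design=rec.design[mask].iloc[:1].reset_index(drop=True))
    ev2 = erf.average(erf.epoch(mean_rec, "E2", (-50, 250)))
    np.testing.assert_allclose(ev.data, ev2.data, rtol=1e-10)


def test_select_sensors_dominant_and_ties():
    names = ["pairB", "pairA", "pairC"]
    data = np.zeros((3, 100))
    data[0, 50] = 2.0
    data[1, 50] = 5.0
    ev = _evoked_from(data, names, combined=True)
    assert erf.select_sensors_by_localizer(ev, 1, (40, 60)) == ["pairA"]
    data[2, 50] = 5.0  # tie with pairA -> lexicographic order
    ev = _evoked_from(data, names, combined=True)
    assert erf.select_sensors_by_localizer(ev, 2, (40, 60)) == ["pairA",
                                                                "pairC"]
    with pytest.raises(ValueError):
        erf.select_sensors_by_localizer(ev, 0, (40, 60))


def test_localizer_selects_sensors_near_the_occipital_dipole(sensors20):
    """On a noiseless localizer the winning pairs sit at the sites closest
    to the simulated occipital source."""
    from entrainmeg.simulate import EVOKED_DIPOLE_POS

    loc = dz.generate_localizer_design(8, seed=0)
    rec = erf.baseline_correct(
        simulate_participant(loc, sensors20, EffectSpec(noise_sd=0.0)))
    ev = erf.combine_planar(erf.average(erf.epoch(rec, "T", (-50, 270))),
                            sensors20)
    chosen = erf.select_sensors_by_localizer(ev, 3, (85, 135))
    sites = [ev.ch_names.index(n) for n in chosen]
    dist = np.linalg.norm(sensors20.site_pos - EVOKED_DIPOLE_POS, axis=1)
    assert set(sites) <= set(np.argsort(dist)[:8])


def test_window_amplitude_modes():
    data = np.zeros((2, 200))
    ev = _evoked_from(data, ["a", "b"], combined=True)
    assert erf.window_amplitude(ev, ["a", "b"], (50, 150)) == 0.0
    data2 = np.full((2, 200), 3.3)
    ev2 = _evoked_from(data2, ["a", "b"], combined=True)
    assert erf.window_amplitude(ev2, ["a"], (50, 150),
                                mode="mean") == pytest.approx(3.3)
    with pytest.raises(ValueError):
        erf.window_amplitude(ev, [], (50, 150))


def test_window_amplitude_recovers_injected_peak():
    times = np.arange(0.0, 300.0)
    amp = 4.2e-12
    data = amp * np.exp(-0.5 * ((times - 100.0) / 15.0) ** 2)[None, :]
    ev = Evoked(data=data, times=times, sfreq=1000.0, ch_names=["p"],
                n_trials_averaged=1, lock="E1", combined=True)
    got = erf.window_amplitude(ev, ["p"], (85, 135), mode="peak")
    assert got == pytest.approx(amp, rel=1e-6)
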