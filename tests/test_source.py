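import numpy as np
import pytest

from entrainmeg import source as src
from entrainmeg.erf import Evoked
from entrainmeg.forward import forward_field


@pytest.fixture(scope="module")
def model30(sensors30):
    return src.build_source_model(sensors30, spacing=0.015)


def _evoked_from_dipole(sensors, pos, moment=(1e-8, 0.0, 0.0)):
    topo = forward_field(pos, np.asarray(moment), np.zeros(3), sensors)
    times = np.arange(0.0, 200.0)
    wave = np.exp(-0.5 * ((times - 100.0) / 15.0) ** 2)
    data = topo[:, None] * wave[None, :]
    return Evoked(data=data, times=times, sfreq=1000.0,
                  ch_names=list(sensors.ch_names), n_trials_averaged=1,
                  lock="E4")


def test_grid_count_scales_with_sphere_volume(model30):
    expected = 4.0 / 3.0 * np.pi * (0.09 / 0.015) ** 3
    assert abs(len(model30.grid) - expected) / expected < 0.10
    # every retained point strictly inside the head sphere
    r = np.linalg.norm(model30.grid - model30.sphere_center, axis=1)
    assert r.max() < model30.sphere_radius


def test_sphere_fit_recovers_the_sensor_shell(sensors30):
    center, radius = src.fit_sphere(sensors30.site_pos)
    np.testing.assert_allclose(center, 0.0, atol=1e-9)
    assert radius == pytest.approx(0.102, abs=1e-9)


def test_leadfield_rank_reduction_keeps_tangential_power(model30):
    """The discarded third orientation (quasi-radial) carries < 0.1% of the
    lead-field power at representative grid points."""
    from entrainmeg.sensors import make_sensor_array

    sensors = make_sensor_array(30, neighbor_radius=0.075)
    eye = np.eye(3)
    rng = np.random.default_rng(0)
    picks = rng.choice(len(model30.grid), size=15, replace=False)
    for p in picks:
        pos = model30.grid[p]
        if np.linalg.norm(pos) < 1e-9:
            continue
        m = np.column_stack([forward_field(pos, eye[k], np.zeros(3), sensors)
                             for k in range(3)])
        s = np.linalg.svd(m, compute_uv=False)
        assert s[2] ** 2 / (s ** 2).sum() < 1e-3
        # the stored reduced lead field spans the same top-2 subspace
        np.testing.assert_allclose(
            np.linalg.norm(model30.leadfields[p], axis=0) ** 2,
            s[:2] ** 2, rtol=1e-8)


def test_unit_gain_constraint(model30, rng):
    n_ch = model30.leadfields.shape[1]
    a = rng.standard_normal((n_ch, n_ch))
    cov = a @ a.T + n_ch * np.eye(n_ch)
    for p in range(0, len(model30.grid), 29):
        lf = model30.leadfields[p]
        if not np.any(lf):
            continue
        w = src.lcmv_weights(cov, lf)
        np.testing.assert_allclose(w @ lf, np.eye(2), atol=1e-8)


def test_identity_covariance_gives_pseudoinverse(model30):
    lf = model30.leadfields[len(model30.grid) // 3]
    w = src.lcmv_weights(np.eye(lf.shape[0]), lf)
    np.testing.assert_allclose(w, np.linalg.pinv(lf), rtol=1e-8)


def test_data_covariance_contracts(rng):
    class Rec:
        pass

    rec = Rec()
    rec.data = rng.standard_normal((40, 6, 500))
    rec.times = np.arange(500.0)
    cov = src.data_covariance(rec, regularization=0.0)
    assert np.abs(np.diag(cov) - 1.0).max() < 0.05
    off = cov - np.diag(np.diag(cov))
    assert np.abs(off).max() < 0.05

    rec2 = Rec()
    rec2.data = 3.0 * rec.data
    rec2.times = rec.times
    np.testing.assert_allclose(src.data_covariance(rec2, regularization=0.0),
                               9.0 * cov, rtol=1e-10)

    rec3 = Rec()
    rec3.data = np.repeat(rng.standard_normal((1, 6, 1)), 50, axis=2)
    rec3.times = np.arange(50.0)
    with pytest.warns(RuntimeWarning):
        c3 = src.data_covariance(rec3, regularization=0.0)
    assert np.linalg.matrix_rank(c3, tol=1e-12) <= 1
    c3r = src.data_covariance(rec3, regularization=0.05)
    assert np.linalg.matrix_rank(c3r) == 6


def test_single_dipole_recovered_within_one_grid_step(sensors30, model30):
    true_pos = np.array([0.004, -0.052, 0.011])  # deliberately off-grid
    ev = _evoked_from_dipole(sensors30, true_pos)
    cov = (ev.data @ ev.data.T) / ev.data.shape[1]
    cov += 0.05 * np.mean(np.diag(cov)) * np.eye(len(cov))
    smap = src.source_map_evoked(ev, model30, cov, sensors30,
                                 window=(85.0, 125.0))
    found = smap.grid[int(np.argmax(smap.values))]
    assert np.linalg.norm(found - true_pos) <= model30.spacing + 1e-12
    assert smap.local_maxima
    top_pos, top_val = smap.local_maxima[0]
    assert top_val == pytest.approx(smap.values.max())
    np.testing.assert_allclose(top_pos, found)


def test_two_separated_dipoles_give_two_maxima(sensors30, model30):
    """Two well-separated sources with *uncorrelated* activity (the LCMV
    assumption) produce two local maxima ordered by strength."""
    p1 = np.array([0.0, -0.05, 0.01])
    p2 = np.array([0.0, 0.05, 0.01])
    topo1 = forward_field(p1, np.array([1e-8, 0, 0]), np.zeros(3), sensors30)
    topo2 = forward_field(p2, np.array([1e-8, 0, 0]), np.zeros(3), sensors30)
    # covariance of two independently fluctuating sources
    cov = np.outer(topo1, topo1) + np.outer(topo2, topo2)
    cov += 0.05 * np.mean(np.diag(cov)) * np.eye(len(cov))
    times = np.arange(0.0, 200.0)
    wave1 = np.exp(-0.5 * ((times - 100.0) / 15.0) ** 2)
    wave2 = wave1 * np.sign(np.sin(2 * np.pi * 0.05 * times))  # decorrelated
    ev = Evoked(data=np.outer(topo1, wave1) + np.outer(topo2, wave2),
                times=times, sfreq=1000.0, ch_names=list(sensors30.ch_names),
                n_trials_averaged=1, lock="E4")
    smap = src.source_map_evoked(ev, model30, cov, sensors30,
                                 window=(85.0, 125.0))
    maxima = smap.local_maxima
    assert len(maxima) >= 2
    # the two strongest maxima sit on the two true sources
    hits = {np.argmin([np.linalg.norm(m[0] - p) for p in (p1, p2)])
            for m in maxima[:2]
            if min(np.linalg.norm(m[0] - p) for p in (p1, p2)) < 0.03}
    assert hits == {0, 1}


def test_source_amplitude_scale_invariance(sensors30, model30):
    ev = _evoked_from_dipole(sensors30, np.array([0.0, -0.05, 0.01]))
    cov = (ev.data @ ev.data.T) / ev.data.shape[1]
    cov += 0.05 * np.mean(np.diag(cov)) * np.eye(len(cov))
    m1 = src.source_map_evoked(ev, model30, cov, sensors30)
    ev2 = Evoked(data=10.0 * ev.data, times=ev.times, sfreq=ev.sfreq,
                 ch_names=ev.ch_names, n_trials_averaged=1, lock="E4")
    m2 = src.source_map_evoked(ev2, model30, 100.0 * cov, sensors30)
    # the noise-normalised source estimate is unit-free: rescaling the
    # channels and the covariance consistently leaves the map unchanged
    np.testing.assert_allclose(m2.values, m1.values, rtol=1e-6)


def test_zero_evoked_gives_empty_map(sensors30, model30):
    ev = _evoked_from_dipole(sensors30, np.array([0.0, -0.05, 0.01]))
    ev.data = np.zeros_like(ev.data)
    cov = np.eye(len(ev.ch_names))
    smap = src.source_map_evoked(ev, model30, cov, sensors30)
    assert np.all(smap.values == 0.0)
    assert smap.local_maxima == []


def test_sphere_peak_value_cases(model30):
    values = np.zeros(len(model30.grid))
    smap = src.SourceMap(grid=model30.grid, values=values,
                         local_maxima=[], window=(85, 125))
    center = model30.grid[10]
    # radius below spacing, centred on a grid point: that point's value
    values[10] = 3.0
    assert src.sphere_peak_value(smap, center, 0.004) == 3.0
    # constant map returns the constant
    smap2 = src.SourceMap(grid=model30.grid,
                          values=np.full(len(model30.grid), 1.7),
                          local_maxima=[], window=(85, 125))
    assert src.sphere_peak_value(smap2, center, 0.02) == pytest.approx(1.7)
    with pytest.raises(ValueError):
        src.sphere_peak_value(smap, np.array([1.0, 1.0, 1.0]), 0.004)
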