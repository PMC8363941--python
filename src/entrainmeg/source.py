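"""LCMV beamformer source mapping on a single-sphere head model.

The source space is a regular 3D lattice inside a head sphere fitted to
the sensor geometry by least squares.  At each grid point the lead field
for three orthogonal unit dipoles is computed with the analytic
single-sphere forward model and reduced to its first two principal
components (the quasi-radial orientation carries essentially no external
field in a sphere).  Source amplitude is obtained with a unit-gain
linearly constrained minimum-variance spatial filter

    W = (L' C^-1 L)^-1 L' C^-1,      W L = I,

where C is the (diagonally loaded) data covariance.  Magnetometers and
gradiometers are combined after prewhitening each channel type by its
noise scale (square root of the mean covariance diagonal per type).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .erf import Evoked, _window_mask
from .forward import forward_field
from .sensors import SensorArray


@dataclass
class SourceModel:
    grid: np.ndarray            # (n_points, 3) metres
    sphere_center: np.ndarray
    sphere_radius: float
    leadfields: np.ndarray      # (n_points, n_channels, 2)
    grid_shape: tuple           # lattice dimensions
    grid_index: np.ndarray      # (n_points, 3) integer lattice coordinates
    spacing: float
    ch_names: list


@dataclass
class SourceMap:
    grid: np.ndarray
    values: np.ndarray
    local_maxima: list          # [(coordinate, value)] sorted by value desc
    window: tuple


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares sphere through a point cloud (linearised normal
    equations)."""
    p = np.asarray(points, dtype=float)
    a = np.column_stack([2.0 * p, np.ones(len(p))])
    b = (p ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def build_source_model(sensors: SensorArray, spacing: float = 0.005,
                       head_radius: float | None = None) -> SourceModel:
    """Regular grid inside the head sphere with per-point rank-2 lead
    fields."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    center, shell_radius = fit_sphere(sensors.site_pos)
    radius = head_radius if head_radius is not None else sensors.head_radius
    if radius >= shell_radius:
        raise ValueError("head sphere must lie inside the sensor shell")

    n_half = int(np.floor(radius / spacing))
    axis = np.arange(-n_half, n_half + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    lattice = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()])
    pts = center + spacing * lattice
    inside = np.linalg.norm(pts - center, axis=1) < radius
    pts = pts[inside]
    lattice = lattice[inside] + n_half   # nonnegative lattice coordinates

    n_ch = sensors.n_channels
    leadfields = np.zeros((len(pts), n_ch, 2))
    eye = np.eye(3)
    for p, pos in enumerate(pts):
        if np.linalg.norm(pos - center) < 1e-9:
            continue    # centre point: zero lead field, flagged unusable
        m = np.column_stack([forward_field(pos, eye[k], center, sensors)
                             for k in range(3)])
        u, s, _ = np.linalg.svd(m, full_matrices=False)
        leadfields[p] = u[:, :2] * s[:2]

    return SourceModel(grid=pts, sphere_center=center, sphere_radius=radius,
                       leadfields=leadfields,
                       grid_shape=(len(axis),) * 3, grid_index=lattice,
                       spacing=spacing, ch_names=list(sensors.ch_names))


def data_covariance(rec, window: tuple[float, float] | None = None,
                    regularization: float = 0.05) -> np.ndarray:
    """Empirical channel covariance pooled over trials and samples, with
    diagonal loading ``regularization * mean(diag)``.

    ``rec`` is any object with (trials, channels, samples) ``data`` and a
    ``times`` axis (ms); the default window is the full recording, i.e.
    the pre-fixation to post-target range of the simulated trials.
    """
    x = rec.data
    if window is not None:
        x = x[..., _window_mask(rec.times, window)]
    n_trials, n_ch, n_samp = x.shape
    flat = np.moveaxis(x, 1, 2).reshape(-1, n_ch)
    flat = flat - flat.mean(axis=0)
    cov = flat.T @ flat / (len(flat) - 1)
    if regularization == 0.0 and np.linalg.matrix_rank(cov) < n_ch:
        warnings.warn("covariance is rank-deficient without regularization",
                      RuntimeWarning)
    return cov + regularization * np.mean(np.diag(cov)) * np.eye(n_ch)


def type_whitener(cov: np.ndarray, sensors: SensorArray) -> np.ndarray:
    """Per-channel scale factors equalising magnetometer and gradiometer
    noise levels (1 / sqrt of the mean covariance diagonal of each type)."""
    diag = np.diag(cov)
    w = np.empty(len(diag))
    for kind in ("mag", "grad"):
        sel = sensors.ch_types == kind
        if sel.any():
            w[sel] = 1.0 / np.sqrt(diag[sel].mean())
    return w


def lcmv_weights(cov: np.ndarray, leadfield: np.ndarray) -> np.ndarray:
    """Unit-gain LCMV spatial filter W = (L' C^-1 L)^-1 L' C^-1
    (2 x channels)."""
    ci_l = np.linalg.solve(cov, leadfield)
    gram = leadfield.T @ ci_l
    if np.linalg.cond(gram) > 1e12:
        raise np.linalg.LinAlgError("singular L' C^-1 L; grid point unusable")
    return np.linalg.solve(gram, ci_l.T)


def source_map_evoked(evoked: Evoked, model: SourceModel, cov: np.ndarray,
                      sensors: SensorArray,
                      window: tuple[float, float] = (85.0, 125.0),
                      mode: str = "rms") -> SourceMap:
    """Project a (baseline-corrected, uncombined) evoked through the LCMV
    filters; value per grid point = RMS (or max norm) of the two
    orientation components over the window.

    Each filter row is rescaled to unit noise gain (Borgiotti-Kaplan
    normalisation) before projection: without it the weak lead fields of
    deep grid points inflate the filter gain and every map peaks at the
    centre of the head.
    """
    if evoked.combined:
        raise ValueError("source mapping needs the uncombined evoked")
    if list(evoked.ch_names) != list(model.ch_names):
        raise ValueError("channel ordering differs between evoked and model")
    if mode not in ("rms", "max"):
        raise ValueError("mode must be 'rms' or 'max'")
    data = evoked.data[:, _window_mask(evoked.times, window)]

    w = type_whitener(cov, sensors)
    cov_w = cov * np.outer(w, w)
    data_w = data * w[:, None]

    values = np.zeros(len(model.grid))
    for p in range(len(model.grid)):
        lf = model.leadfields[p] * w[:, None]
        if not np.any(lf):
            continue
        try:
            filt = lcmv_weights(cov_w, lf)
        except np.linalg.LinAlgError:
            continue
        filt = filt / np.linalg.norm(filt, axis=1, keepdims=True)
        s = filt @ data_w
        values[p] = (np.sqrt((s ** 2).mean()) if mode == "rms"
                     else float(np.linalg.norm(s, axis=0).max()))

    maxima = _local_maxima(model, values)
    return SourceMap(grid=model.grid, values=values, local_maxima=maxima,
                     window=window)


def _local_maxima(model: SourceModel, values: np.ndarray) -> list:
    """Grid points whose value is >= all 26-neighbourhood neighbours
    (and > 0), sorted by value descending."""
    from scipy.ndimage import maximum_filter

    vol = np.full(model.grid_shape, -np.inf)
    idx = tuple(model.grid_index.T)
    vol[idx] = values
    neigh_max = maximum_filter(vol, size=3, mode="constant", cval=-np.inf)
    is_max = (vol >= neigh_max) & (vol > 0)
    flags = is_max[idx]
    order = np.argsort(-values)
    return [(model.grid[p], float(values[p])) for p in order if flags[p]]


def sphere_peak_value(smap: SourceMap, center: np.ndarray,
                      radius: float = 0.005) -> float:
    """Maximum map value over grid points within ``radius`` of ``center``."""
    center = np.asarray(center, dtype=float)
    sel = np.linalg.norm(smap.grid - center, axis=1) <= radius + 1e-12
    if not sel.any():
        raise ValueError("no grid point inside the query sphere")
    return float(smap.values[sel].max())


def source_map_to_csv(smap: SourceMap, path) -> None:
    import pandas as pd

    df = pd.DataFrame(smap.grid, columns=["x", "y", "z"])
    df["value"] = smap.values
    df.to_csv(path, index=False)
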