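"""Single-sphere MEG forward model.

The magnetic field of a current dipole inside a homogeneously conducting
sphere has the closed analytic form (Sarvas):

    B(r) = mu0 / (4 pi F^2) * ( F (Q x r0) - ((Q x r0) . r) grad F )

with r, r0 the sensor and dipole positions relative to the sphere centre,
a = r - r0, F = a (r a + r^2 - r0 . r) and

    grad F = (a^2 / r + (a . r)/a + 2 a + 2 r) r - (a + 2 r + (a . r)/a) r0.

Volume currents cancel for the radial field component, and a purely radial
dipole produces no external field at all.  Magnetometer channels project
B onto their (radial) orientation; planar gradiometers are evaluated as a
two-point finite difference of that projection along their baseline.
"""

from __future__ import annotations

import numpy as np

from .sensors import SensorArray

MU0 = 4e-7 * np.pi


class GeometryError(ValueError):
    """Dipole/sensor placement incompatible with the sphere model."""


def sarvas_field(sensor_pos: np.ndarray, dipole_pos: np.ndarray,
                 dipole_moment: np.ndarray,
                 sphere_center: np.ndarray) -> np.ndarray:
    """Magnetic field vector (T) at each sensor position.

    Parameters are in metres and A*m; ``sensor_pos`` has shape (n, 3).
    """
    sensor_pos = np.atleast_2d(np.asarray(sensor_pos, dtype=float))
    r = sensor_pos - sphere_center
    r0 = np.asarray(dipole_pos, dtype=float) - sphere_center
    q = np.asarray(dipole_moment, dtype=float)

    a_vec = r - r0
    a = np.linalg.norm(a_vec, axis=1)
    rn = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise GeometryError("sensor coincides with the dipole")
    r0_dot_r = r @ r0
    a_dot_r = np.einsum("ij,ij->i", a_vec, r)

    F = a * (rn * a + rn ** 2 - r0_dot_r)
    grad_f = ((a ** 2 / rn + a_dot_r / a + 2.0 * a + 2.0 * rn)[:, None] * r
              - (a + 2.0 * rn + a_dot_r / a)[:, None] * r0)
    q_x_r0 = np.cross(q, r0)
    b = (MU0 / (4.0 * np.pi * F ** 2)[:, None]
         * (F[:, None] * q_x_r0 - (r @ q_x_r0)[:, None] * grad_f))
    return b


def forward_field(dipole_pos: np.ndarray, dipole_moment: np.ndarray,
                  sphere_center: np.ndarray,
                  sensors: SensorArray) -> np.ndarray:
    """Per-channel topography (T for magnetometers, T/m for gradiometers)
    of one current dipole under the single-sphere model."""
    sphere_center = np.asarray(sphere_center, dtype=float)
    dipole_pos = np.asarray(dipole_pos, dtype=float)
    depth = np.linalg.norm(dipole_pos - sphere_center)
    if depth < 1e-9:
        raise GeometryError("dipole at the sphere centre has no "
                            "tangential component")
    if depth >= sensors.head_radius:
        raise GeometryError(
            f"dipole at {depth * 1e3:.1f} mm from centre lies outside the "
            f"{sensors.head_radius * 1e3:.0f} mm head sphere")
    sensor_depth = np.linalg.norm(sensors.ch_pos - sphere_center, axis=1)
    if np.any(sensor_depth <= sensors.head_radius):
        raise GeometryError("sensors must lie outside the head sphere")

    half = 0.5 * sensors.baseline_length
    is_grad = sensors.ch_types == "grad"
    pts = np.concatenate([
        sensors.ch_pos[~is_grad],
        sensors.ch_pos[is_grad] + half * sensors.ch_baseline_dir[is_grad],
        sensors.ch_pos[is_grad] - half * sensors.ch_baseline_dir[is_grad],
    ])
    b = sarvas_field(pts, dipole_pos, dipole_moment, sphere_center)

    n_mag = int((~is_grad).sum())
    n_grad = int(is_grad.sum())
    out = np.empty(sensors.n_channels)
    out[~is_grad] = np.einsum("ij,ij->i", b[:n_mag],
                              sensors.ch_normal[~is_grad])
    plus = np.einsum("ij,ij->i", b[n_mag:n_mag + n_grad],
                     sensors.ch_normal[is_grad])
    minus = np.einsum("ij,ij->i", b[n_mag + n_grad:],
                      sensors.ch_normal[is_grad])
    out[is_grad] = (plus - minus) / sensors.baseline_length
    return out
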