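"""Sensor array geometry.

A deterministic spherical-cap lattice of sensor *sites*, each carrying one
magnetometer (measuring the field along the outward radial direction) and
two orthogonal planar gradiometers (measuring the tangential derivative of
that radial projection along two orthogonal tangent directions).  The
default layout has 102 sites, mirroring a whole-head triple-sensor system.

The helmet is modelled as a cap of a sphere of radius ``sensor_radius``
centred on the head-sphere centre (the origin); occipital cortex sits
toward -y.  Spatial adjacency between sites (used by the cluster
statistics) connects sites closer than ``neighbor_radius``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SensorArray:
    ch_names: list[str]
    ch_types: np.ndarray          # 'mag' | 'grad' per channel
    ch_pos: np.ndarray            # (n_ch, 3) metres
    ch_normal: np.ndarray         # (n_ch, 3) unit vectors (field projection)
    ch_baseline_dir: np.ndarray   # (n_ch, 3); zero rows for magnetometers
    ch_site: np.ndarray           # (n_ch,) site index
    site_pos: np.ndarray          # (n_sites, 3)
    adjacency: np.ndarray         # (n_sites, n_sites) bool, no self-loops
    baseline_length: float = 0.0168   # gradiometer baseline, metres
    head_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    head_radius: float = 0.09

    @property
    def n_channels(self) -> int:
        return len(self.ch_names)

    @property
    def n_sites(self) -> int:
        return len(self.site_pos)

    @property
    def mag_indices(self) -> np.ndarray:
        return np.flatnonzero(self.ch_types == "mag")

    @property
    def grad_indices(self) -> np.ndarray:
        return np.flatnonzero(self.ch_types == "grad")

    @property
    def pair_map(self) -> dict[str, str]:
        """Perfect matching between the two gradiometers of each site."""
        pairs: dict[str, str] = {}
        for i, j in self.grad_pairs():
            pairs[self.ch_names[i]] = self.ch_names[j]
            pairs[self.ch_names[j]] = self.ch_names[i]
        return pairs

    def grad_pairs(self) -> list[tuple[int, int]]:
        """(index, index) of the gradiometer pair at each site, site order."""
        out = []
        for s in range(self.n_sites):
            idx = np.flatnonzero((self.ch_site == s)
                                 & (self.ch_types == "grad"))
            if len(idx) != 2:
                raise ValueError(f"site {s} has {len(idx)} gradiometers")
            out.append((int(idx[0]), int(idx[1])))
        return out

    def pair_names(self) -> list[str]:
        return [f"{self.ch_names[i]}+{self.ch_names[j][-4:]}"
                for i, j in self.grad_pairs()]

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "ch_name": self.ch_names,
            "ch_type": self.ch_types,
            "site": self.ch_site,
        })
        for k, ax in enumerate("xyz"):
            df[f"pos_{ax}"] = self.ch_pos[:, k]
            df[f"normal_{ax}"] = self.ch_normal[:, k]
            df[f"baseline_{ax}"] = self.ch_baseline_dir[:, k]
        df.to_csv(path, index=False)


def make_sensor_array(n_sites: int = 102,
                      sensor_radius: float = 0.102,
                      head_radius: float = 0.09,
                      cap_angle: float = 2.1,
                      neighbor_radius: float = 0.04,
                      baseline_length: float = 0.0168) -> SensorArray:
    """Deterministic Fibonacci lattice of triple-sensor sites on a spherical
    cap of half-angle ``cap_angle`` (radians, measured from +z).

    ``neighbor_radius`` should scale with the inter-site spacing; the 4 cm
    default suits the 102-site layout (mean degree around 6).
    """
    i = np.arange(n_sites)
    z = 1.0 - (1.0 - np.cos(cap_angle)) * (i + 0.5) / n_sites
    phi = i * GOLDEN_ANGLE
    rho = np.sqrt(np.clip(1.0 - z ** 2, 0.0, None))
    site_pos = sensor_radius * np.column_stack(
        [rho * np.cos(phi), rho * np.sin(phi), z])

    normals = site_pos / np.linalg.norm(site_pos, axis=1, keepdims=True)
    # tangent frame per site; reference axis switched near the pole
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (n_sites, 1))
    polar = np.abs(normals[:, 2]) > 0.95
    ref[polar] = np.array([1.0, 0.0, 0.0])
    t1 = np.cross(ref, normals)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(normals, t1)

    ch_names, ch_types, ch_pos, ch_norm, ch_base, ch_site = [], [], [], [], [], []
    for s in range(n_sites):
        base = f"MEG{s:03d}"
        ch_names += [base + "1", base + "2", base + "3"]
        ch_types += ["mag", "grad", "grad"]
        ch_pos += [site_pos[s]] * 3
        ch_norm += [normals[s]] * 3
        ch_base += [np.zeros(3), t1[s], t2[s]]
        ch_site += [s] * 3

    d = np.linalg.norm(site_pos[:, None] - site_pos[None, :], axis=-1)
    adjacency = (d < neighbor_radius) & ~np.eye(n_sites, dtype=bool)

    return SensorArray(
        ch_names=ch_names,
        ch_types=np.asarray(ch_types, dtype=object),
        ch_pos=np.asarray(ch_pos),
        ch_normal=np.asarray(ch_norm),
        ch_baseline_dir=np.asarray(ch_base),
        ch_site=np.asarray(ch_site),
        site_pos=site_pos,
        adjacency=adjacency,
        baseline_length=baseline_length,
        head_center=np.zeros(3),
        head_radius=head_radius,
    )
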