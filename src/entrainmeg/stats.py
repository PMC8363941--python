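"""Inferential statistics: factorial repeated-measures ANOVA and
nonparametric cluster-based permutation tests.

The cluster machinery follows the standard spatiotemporal recipe for
MEG sensor data: a paired t-map over (sensor, time) is thresholded at a
t-quantile, supra-threshold cells that lack at least ``min_neighbors``
supra-threshold spatial neighbours at the same time point are pruned, the
survivors are grouped into connected components (spatial adjacency at equal
times, temporal adjacency within a sensor), and each component's summed
t-value (cluster mass) is compared against a permutation null built by
flipping condition labels within participants.  For paired designs the
label flip is equivalent to a sign flip of the per-participant difference,
which allows a fully vectorised null: with fixed sum of squared
differences, the permuted t-map is a function of the permuted mean alone.

Decoding accuracies are tested with the one-tailed sign-flip variant over
time only.

p-values use the (r + 1) / (N + 1) convention, so the observed statistic
is effectively a member of its own null and p is never zero.  Exhaustive
enumeration of all 2^n sign patterns replaces Monte Carlo sampling when
requested (n <= 16).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.stats import f as f_dist, t as t_dist

ANOVA_FACTORS = {"entrainer": 0, "what": 1, "when": 2}
ANOVA_EFFECTS = ["entrainer", "what", "when", "entrainer * what",
                 "entrainer * when", "what * when",
                 "entrainer * what * when"]


def rm_anova_3way(amplitudes: np.ndarray) -> pd.DataFrame:
    """Type III repeated-measures ANOVA for a fully balanced
    participant x entrainer(4) x what(2) x when(2) array.

    Every within-subject effect is tested against its own
    effect-by-participant interaction.  For a complete balanced design the
    Type III and sequential decompositions coincide (orthogonal factors).
    Returns a table with one row per effect: sum_sq, df, mean_sq, F, p and
    the matching error stratum (error_ss, error_df).
    """
    y = np.asarray(amplitudes, dtype=float)
    if y.ndim != 4:
        raise ValueError("amplitudes must be participant x entrainer x "
                         "what x when")
    if np.any(np.isnan(y)):
        raise ValueError("missing cells are not supported")
    n = y.shape[0]
    sizes = y.shape[1:]

    rows = []
    for name in ANOVA_EFFECTS:
        factors = [f.strip() for f in name.split("*")]
        axes = [ANOVA_FACTORS[f] + 1 for f in factors]
        other = tuple(ax for ax in range(1, 4) if ax not in axes)
        t = y.mean(axis=other) if other else y
        c = t
        for ax in range(1, c.ndim):
            c = c - c.mean(axis=ax, keepdims=True)
        n_avg = int(np.prod([sizes[ax - 1] for ax in other])) if other else 1
        m = c.mean(axis=0)
        ss_eff = n * n_avg * float((m ** 2).sum())
        ss_err = n_avg * float(((c - m) ** 2).sum())
        df_eff = int(np.prod([sizes[ax - 1] - 1 for ax in axes]))
        df_err = (n - 1) * df_eff
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        f_stat = ms_eff / ms_err if ms_err > 0 else np.inf
        p = float(f_dist.sf(f_stat, df_eff, df_err))
        rows.append({"effect": name, "sum_sq": ss_eff, "df": df_eff,
                     "mean_sq": ms_eff, "F": f_stat, "p": p,
                     "error_ss": ss_err, "error_df": df_err})
    return pd.DataFrame(rows)


def paired_t_map(cond_a: np.ndarray, cond_b: np.ndarray) -> np.ndarray:
    """One-sample t over per-participant differences, cell-wise
    (df = n - 1).  Zero-variance cells yield +/-inf with a warning."""
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have equal shapes")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero = sd == 0
    if np.any(zero):
        warnings.warn("zero-variance cells in paired t-map; t set to "
                      "+/-inf (or 0 for zero mean)", RuntimeWarning)
        t[zero] = np.where(mean[zero] > 0, np.inf,
                           np.where(mean[zero] < 0, -np.inf, 0.0))
    return t


@dataclass
class Cluster:
    members: np.ndarray   # (m, 2) array of (sensor, time) indices
    mass: float
    p: float = np.nan


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    clusters: list[Cluster]
    null_distribution: np.ndarray
    threshold: float
    params: dict = field(default_factory=dict)

    def p_values(self) -> np.ndarray:
        return np.array([c.p for c in self.clusters])

    def significant(self, alpha: float) -> list[Cluster]:
        return [c for c in self.clusters if c.p < alpha]

    def to_dict(self, times: np.ndarray | None = None,
                sensor_names: list[str] | None = None) -> dict:
        clusters = []
        for c in self.clusters:
            d = {"mass": float(c.mass), "p": float(c.p),
                 "members": c.members.tolist()}
            if times is not None:
                tsel = times[c.members[:, 1]]
                d["time_range_ms"] = [float(tsel.min()), float(tsel.max())]
            if sensor_names is not None:
                d["sensors"] = sorted({sensor_names[s]
                                       for s in c.members[:, 0]})
            clusters.append(d)
        return {"threshold": float(self.threshold), "clusters": clusters,
                "params": self.params,
                "n_null": int(len(self.null_distribution))}


class _ClusterEngine:
    """Connected-component clustering over a (sensor, time) grid with a
    fixed sensor adjacency; precomputes the spatial edge list once so the
    per-permutation cost is dominated by thresholding."""

    def __init__(self, adjacency: np.ndarray | None, n_sensors: int,
                 n_times: int, min_neighbors: int = 2):
        if adjacency is None:
            adjacency = np.zeros((n_sensors, n_sensors), dtype=bool)
        adjacency = np.asarray(adjacency, dtype=bool)
        if adjacency.shape != (n_sensors, n_sensors):
            raise ValueError("adjacency must cover all sensors")
        if np.any(np.diag(adjacency)):
            raise ValueError("adjacency must have no self-loops")
        self.adjacency = adjacency | adjacency.T
        self.n_sensors = n_sensors
        self.n_times = n_times
        self.min_neighbors = min_neighbors
        iu = np.triu_indices(n_sensors, k=1)
        keep = self.adjacency[iu]
        self._pairs = np.column_stack([iu[0][keep], iu[1][keep]])

    def _prune(self, supra: np.ndarray) -> np.ndarray:
        """Drop supra-threshold cells with fewer than ``min_neighbors``
        supra-threshold spatial neighbours at the same time (single pass)."""
        if self.min_neighbors <= 0:
            return supra
        counts = self.adjacency.astype(np.int16) @ supra
        return supra & (counts >= self.min_neighbors)

    def _components(self, mask: np.ndarray) -> list[np.ndarray]:
        s, t = self.n_sensors, self.n_times
        flat = np.flatnonzero(mask.ravel())
        if flat.size == 0:
            return []
        node = -np.ones(s * t, dtype=np.int64)
        node[flat] = np.arange(flat.size)
        rows, cols = [], []
        # temporal edges: same sensor, adjacent samples
        tm = mask[:, :-1] & mask[:, 1:]
        if tm.any():
            r, c = np.nonzero(tm)
            rows.append(node[r * t + c])
            cols.append(node[r * t + c + 1])
        # spatial edges: adjacent sensors, same sample
        if len(self._pairs):
            both = mask[self._pairs[:, 0]] & mask[self._pairs[:, 1]]
            pi, ti = np.nonzero(both)
            if pi.size:
                rows.append(node[self._pairs[pi, 0] * t + ti])
                cols.append(node[self._pairs[pi, 1] * t + ti])
        if rows:
            rows = np.concatenate(rows)
            cols = np.concatenate(cols)
        graph = sparse.coo_matrix(
            (np.ones(len(rows) if len(rows) else 0), (rows, cols)),
            shape=(flat.size, flat.size))
        n_comp, labels = connected_components(graph, directed=False)
        return [flat[labels == k] for k in range(n_comp)]

    def clusters(self, t_map: np.ndarray, threshold: float,
                 tail: str) -> list[Cluster]:
        out: list[Cluster] = []
        signs = {"two": (1, -1), "pos": (1,), "neg": (-1,)}[tail]
        t_flat = t_map.ravel()
        for sign in signs:
            supra = self._prune(sign * t_map > threshold)
            for comp in self._components(supra):
                members = np.column_stack(np.unravel_index(
                    comp, (self.n_sensors, self.n_times)))
                out.append(Cluster(members=members,
                                   mass=float(t_flat[comp].sum())))
        out.sort(key=lambda c: -abs(c.mass))
        return out

    def max_mass(self, t_map: np.ndarray, threshold: float,
                 tail: str) -> float:
        best = 0.0
        for c in self.clusters(t_map, threshold, tail):
            best = max(best, abs(c.mass) if tail == "two" else
                       (c.mass if tail == "pos" else -c.mass))
        return best


def _sign_patterns(n: int, n_perm: int, method: str,
                   rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    if method == "exhaustive":
        if n > 16:
            raise ValueError("exhaustive enumeration limited to n <= 16")
        bits = np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]
        return np.where(bits & 1, 1.0, -1.0), True
    return rng.choice([-1.0, 1.0], size=(n_perm, n)), False


def _null_max_masses(d: np.ndarray, engine: _ClusterEngine,
                     threshold: float, tail: str,
                     signs: np.ndarray, chunk: int = 128) -> np.ndarray:
    """Max cluster mass per sign pattern; the permuted t-map is computed
    from the permuted mean only (sum of squares is sign-invariant)."""
    n, s, t = d.shape
    flat = d.reshape(n, -1)
    ssq = (flat ** 2).sum(axis=0)
    out = np.empty(len(signs))
    for start in range(0, len(signs), chunk):
        sg = signs[start:start + chunk]
        m = sg @ flat / n
        var = (ssq[None, :] - n * m ** 2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t_maps = m / np.sqrt(var / n)
        t_maps = np.nan_to_num(t_maps, nan=0.0, posinf=np.inf,
                               neginf=-np.inf)
        for k, tm in enumerate(t_maps):
            out[start + k] = engine.max_mass(tm.reshape(s, t), threshold,
                                             tail)
    return out


def t_threshold(alpha: float, n: int, tail: str = "two") -> float:
    df = n - 1
    if tail == "two":
        return float(t_dist.ppf(1.0 - alpha / 2.0, df))
    return float(t_dist.ppf(1.0 - alpha, df))


def form_clusters(t_map: np.ndarray, threshold: float,
                  adjacency: np.ndarray | None = None,
                  min_neighbors: int = 2,
                  tail: str = "two") -> list[Cluster]:
    """Supra-threshold spatiotemporal clusters of a (sensor, time) t-map."""
    t_map = np.atleast_2d(np.asarray(t_map, dtype=float))
    engine = _ClusterEngine(adjacency, t_map.shape[0], t_map.shape[1],
                            min_neighbors)
    return engine.clusters(t_map, threshold, tail)


def cluster_permutation_test(cond_a: np.ndarray, cond_b: np.ndarray,
                             adjacency: np.ndarray | None = None,
                             times: np.ndarray | None = None,
                             window: tuple[float, float] | None = None,
                             n_perm: int = 1000,
                             threshold_alpha: float = 0.01,
                             min_neighbors: int = 2,
                             tail: str = "two",
                             seed: int = 0,
                             method: str = "montecarlo",
                             ) -> ClusterTestResult:
    """Paired spatiotemporal cluster permutation test between two
    conditions given as (participant, sensor, time) arrays.

    The null distribution of the maximum cluster mass is built by randomly
    flipping each participant's condition labels (equivalently the sign of
    their difference map); the cluster-forming threshold is the
    t-distribution quantile implied by ``threshold_alpha``.
    """
    a = np.asarray(cond_a, dtype=float)
    b = np.asarray(cond_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("need paired (participant, sensor, time) arrays "
                         "of equal shape")
    if n_perm < 100 and method == "montecarlo":
        warnings.warn("fewer than 100 permutations gives coarse p-values",
                      RuntimeWarning)
    if times is not None and window is not None:
        lo, hi = window
        sel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
        a, b = a[..., sel], b[..., sel]
        times = times[sel]

    n = a.shape[0]
    d = a - b
    threshold = t_threshold(threshold_alpha, n, tail)
    engine = _ClusterEngine(adjacency, d.shape[1], d.shape[2], min_neighbors)
    t_map = paired_t_map(a, b)
    clusters = engine.clusters(t_map, threshold, tail)

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_patterns(n, n_perm, method, rng)
    null = _null_max_masses(d, engine, threshold, tail, signs)
    for c in clusters:
        stat = abs(c.mass) if tail == "two" else (
            c.mass if tail == "pos" else -c.mass)
        # relative tolerance: the identity relabeling reproduces the
        # observed mass only up to floating-point round-off
        r = int((null >= stat * (1.0 - 1e-9) - 1e-12).sum())
        c.p = r / len(null) if exhaustive else (r + 1) / (len(null) + 1)

    return ClusterTestResult(
        t_map=t_map, clusters=clusters, null_distribution=null,
        threshold=threshold,
        params={"n_perm": len(signs), "threshold_alpha": threshold_alpha,
                "min_neighbors": min_neighbors, "tail": tail,
                "method": method, "n_participants": n})


def sign_permutation_test(effect: np.ndarray,
                          cluster_defining_p: float = 0.05,
                          n_perm: int = 1000,
                          seed: int = 0,
                          method: str = "montecarlo") -> ClusterTestResult:
    """One-tailed (positive) cluster-corrected sign permutation test for a
    (participant, time) effect array, e.g. decoding accuracy minus chance.

    Temporal clusters of t-values above the one-tailed
    ``cluster_defining_p`` quantile are scored by their mass; the null
    flips the sign of whole participant time courses.
    """
    x = np.asarray(effect, dtype=float)
    if x.ndim != 2:
        raise ValueError("effect must be participant x time")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    threshold = t_threshold(cluster_defining_p, n, tail="pos")
    d = x[:, None, :]   # single pseudo-sensor
    engine = _ClusterEngine(None, 1, x.shape[1], min_neighbors=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_map = x.mean(axis=0) / (x.std(axis=0, ddof=1) / np.sqrt(n))
    t_map = np.nan_to_num(np.atleast_2d(t_map), nan=0.0, posinf=np.inf,
                          neginf=-np.inf)
    clusters = engine.clusters(t_map, threshold, "pos")

    rng = np.random.default_rng(seed)
    signs, exhaustive = _sign_patterns(n, n_perm, method, rng)
    null = _null_max_masses(d, engine, threshold, "pos", signs)
    for c in clusters:
        r = int((null >= c.mass * (1.0 - 1e-9) - 1e-12).sum())
        c.p = r / len(null) if exhaustive else (r + 1) / (len(null) + 1)

    return ClusterTestResult(
        t_map=t_map, clusters=clusters, null_distribution=null,
        threshold=threshold,
        params={"n_perm": len(signs),
                "cluster_defining_p": cluster_defining_p,
                "tail": "pos", "method": method, "n_participants": n})


def anova_to_csv(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"effect": "Effect", "sum_sq": "Sum of Squares",
                                "df": "df", "mean_sq": "Mean Square",
                                "F": "F", "p": "P"})
    out.to_csv(path, index=False)
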