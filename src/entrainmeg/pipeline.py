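"""End-to-end study pipeline: simulate a cohort, run the sensor-level ERF
analyses, the factorial ANOVA, the four pairwise cluster permutation
comparisons, the E4 source-level comparison, and time-resolved decoding,
and collect everything into a single serialisable report.

All randomness derives from the study seed: participant p uses
``seed * 10007 + p`` for the design and ``seed * 10007 + 5000 + p`` for
the sensor noise, keeping every derived seed well below 2**31.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from itertools import combinations

import numpy as np
import yaml
from scipy.stats import ttest_rel

from . import design as design_mod
from . import erf as erf_mod
from . import decoding as dec_mod
from . import source as src_mod
from . import stats as stats_mod
from .sensors import make_sensor_array
from .simulate import EffectSpec, simulate_participant, effectspec_to_dict

log = logging.getLogger("entrainmeg")

#: the four sensor-level pairwise comparisons, in the order they are run:
#: expectation suppression under predictable timing, under jittered timing,
#: the temporal-predictability contrast between the two orientation-
#: predictable conditions (restricted to the evoked-peak window), and the
#: control contrast between the two orientation-unpredictable conditions.
DEFAULT_COMPARISONS = (
    {"name": "when_vs_what_when", "a": "when_only", "b": "what_when",
     "window": (0.0, 270.0), "sig_alpha": 0.01},
    {"name": "random_vs_what", "a": "random", "b": "what_only",
     "window": (0.0, 270.0), "sig_alpha": 0.01},
    {"name": "what_when_vs_what", "a": "what_when", "b": "what_only",
     "window": (75.0, 135.0), "sig_alpha": 0.05},
    {"name": "when_vs_random", "a": "when_only", "b": "random",
     "window": (75.0, 135.0), "sig_alpha": 0.05},
)

ENTRAINERS = ("E1", "E2", "E3", "E4")


@dataclass
class DecodingConfig:
    features: tuple = ("orientation",)
    conditions: tuple = ("what_when", "what_only")
    stimuli: tuple = ("E1", "E2", "E3", "E4")
    target_sfreq: float = 200.0
    bin_size: int = 10
    n_folds: int = 5
    n_repeats: int = 25


@dataclass
class StudyConfig:
    n_participants: int = 16
    n_per_condition: int = 160
    n_localizer: int = 80
    n_sites: int = 102
    neighbor_radius: float = 0.04
    sfreq: float = 1000.0
    seed: int = 0
    effects: EffectSpec = field(default_factory=EffectSpec)
    bandpass: tuple = (0.5, 45.0)
    baseline_window: tuple = (-400.0, 0.0)
    epoch_windows: dict = field(
        default_factory=lambda: dict(erf_mod.DEFAULT_EPOCH_WINDOWS))
    erf_window: tuple = (85.0, 135.0)
    erf_mode: str = "peak"
    n_select_sensors: int = 5
    comparisons: tuple = DEFAULT_COMPARISONS
    cluster_threshold_alpha: float = 0.01
    min_neighbors: int = 2
    n_perm: int = 1000
    run_source: bool = True
    source_spacing: float = 0.005
    source_window: tuple = (85.0, 125.0)
    source_regularization: float = 0.05
    run_decoding: bool = True
    decoding: DecodingConfig = field(default_factory=DecodingConfig)
    #: cohorts small enough to enumerate all 2^n relabelings get the exact
    #: permutation null instead of Monte Carlo sampling
    exhaustive_max_n: int = 12

    def _perm_method(self) -> str:
        return ("exhaustive" if self.n_participants <= self.exhaustive_max_n
                else "montecarlo")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effects"] = effectspec_to_dict(self.effects)
        d["comparisons"] = [dict(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        if "effects" in d and isinstance(d["effects"], dict):
            eff = dict(d["effects"])
            if "pattern_snr_schedule" in eff:
                eff["pattern_snr_schedule"] = tuple(
                    eff["pattern_snr_schedule"])
            d["effects"] = EffectSpec(**eff)
        if "decoding" in d and isinstance(d["decoding"], dict):
            d["decoding"] = DecodingConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in d["decoding"].items()})
        if "comparisons" in d:
            d["comparisons"] = tuple(
                {**c, "window": tuple(c["window"])} for c in d["comparisons"])
        for key in ("bandpass", "baseline_window", "erf_window",
                    "source_window"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "epoch_windows" in d:
            d["epoch_windows"] = {k: tuple(v)
                                  for k, v in d["epoch_windows"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(config: StudyConfig) -> list[str]:
    """Static consistency checks; an empty list means the config is
    runnable."""
    issues = list(config.effects.validate())
    if config.n_participants < 3:
        issues.append("n_participants must be at least 3")
    if config.n_per_condition % 4 != 0:
        issues.append("n_per_condition must be divisible by 4")
    if config.sfreq < 500.0:
        issues.append("sfreq must be at least 500 Hz")
    lo, hi = config.bandpass
    if not 0 < lo < hi < config.sfreq / 2:
        issues.append("bandpass edges out of range")
    for lock, (w0, w1) in config.epoch_windows.items():
        if w0 >= w1:
            issues.append(f"epoch window for {lock} is empty")
    for name, window in (("erf_window", config.erf_window),
                         ("source_window", config.source_window)):
        for lock in ENTRAINERS:
            w0, w1 = config.epoch_windows.get(lock, (None, None))
            if w0 is None:
                issues.append(f"no epoch window for {lock}")
            elif not (w0 <= window[0] < window[1] <= w1):
                issues.append(f"{name} {window} outside the {lock} epoch "
                              f"window ({w0}, {w1})")
    for comp in config.comparisons:
        for cond in (comp["a"], comp["b"]):
            if cond not in design_mod.CONDITIONS:
                issues.append(f"unknown condition {cond!r} in comparison "
                              f"{comp['name']}")
    if config.decoding.bin_size < 1:
        issues.append("decoding bin_size must be >= 1")
    n_class = config.n_per_condition // 2
    n_pseudo = n_class // max(config.decoding.bin_size, 1)
    if config.run_decoding and n_pseudo < config.decoding.n_folds:
        issues.append("too few pseudo-trials per class for the requested "
                      "cross-validation")
    return issues


@dataclass
class StudyReport:
    config: dict
    config_hash: str
    anova: list
    amplitudes: list
    comparisons: dict
    source: dict
    decoding: dict
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=1, default=_jsonify)


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not serialisable: {type(obj)}")


def _participant_seed(config: StudyConfig, p: int, offset: int = 0) -> int:
    return (config.seed * 10007 + offset + p) % (2 ** 31 - 1)


def analyze_participant(config: StudyConfig, sensors, p: int) -> dict:
    """Simulate and reduce one participant; returns per-condition combined
    evokeds, peak amplitudes, the localizer sensor selection, decoding
    accuracy curves, and the source-analysis inputs."""
    effects = replace(config.effects, seed=_participant_seed(config, p, 5000))
    design = design_mod.generate_design(config.n_per_condition,
                                        seed=_participant_seed(config, p))
    rec = simulate_participant(design, sensors, effects, config.sfreq)
    rec = erf_mod.bandpass(rec, *config.bandpass)
    rec = erf_mod.baseline_correct(rec, window=config.baseline_window)

    out: dict = {"evoked": {}, "evoked_raw": {}, "amplitude": {},
                 "decoding": {}, "source_peaks": {}}

    loc_design = design_mod.generate_localizer_design(
        config.n_localizer, seed=_participant_seed(config, p, 9000))
    loc_rec = simulate_participant(loc_design, sensors,
                                   replace(effects, seed=effects.seed + 1),
                                   config.sfreq)
    loc_rec = erf_mod.bandpass(loc_rec, *config.bandpass)
    loc_rec = erf_mod.baseline_correct(loc_rec, window=config.baseline_window)
    loc_epochs = erf_mod.epoch(loc_rec, "T", (-50.0, 270.0))
    loc_evoked = erf_mod.combine_planar(erf_mod.average(loc_epochs), sensors)
    out["selected_sensors"] = erf_mod.select_sensors_by_localizer(
        loc_evoked, config.n_select_sensors, config.erf_window)

    cond = rec.design["condition"].to_numpy()
    epochs_by_lock = {}
    for lock in ENTRAINERS + ("T",):
        epochs_by_lock[lock] = erf_mod.epoch(rec, lock,
                                             config.epoch_windows[lock])
    for condition in design_mod.CONDITIONS:
        mask = cond == condition
        for lock, eps in epochs_by_lock.items():
            ev = erf_mod.average(eps, mask)
            comb = erf_mod.combine_planar(ev, sensors)
            out["evoked"][(condition, lock)] = comb
            if lock == "E4":
                out["evoked_raw"][(condition, lock)] = ev
            if lock != "T":
                out["amplitude"][(condition, lock)] = erf_mod.window_amplitude(
                    comb, out["selected_sensors"], config.erf_window,
                    config.erf_mode)

    if config.run_source:
        out["covariance"] = src_mod.data_covariance(
            rec, regularization=config.source_regularization)

    if config.run_decoding:
        dc = config.decoding
        for feature in dc.features:
            labels_all = dec_mod.derive_labels(rec.design, feature)
            for condition in dc.conditions:
                mask = cond == condition
                for stim in dc.stimuli:
                    eps = epochs_by_lock.get(stim) or erf_mod.epoch(
                        rec, stim, config.epoch_windows[stim])
                    sub = eps.select(mask)
                    sub = dec_mod.downsample(sub, dc.target_sfreq)
                    acc = dec_mod.decode_timecourse(
                        sub.data, labels_all[mask], dc.bin_size, dc.n_folds,
                        dc.n_repeats,
                        seed=_participant_seed(config, p, 70000))
                    out["decoding"][(feature, condition, stim)] = (
                        sub.times, acc)
    return out


def run_study(config: StudyConfig) -> StudyReport:
    """Run the full synthetic study; deterministic given the config."""
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    sensors = make_sensor_array(config.n_sites,
                                neighbor_radius=config.neighbor_radius)
    log.info("study %s: %d participants, %d sites", config.config_hash(),
             config.n_participants, config.n_sites)

    participants = []
    for p in range(config.n_participants):
        log.info("participant %d", p)
        participants.append(analyze_participant(config, sensors, p))

    # ---- three-way repeated-measures ANOVA on the peak amplitudes ----
    n = config.n_participants
    amp = np.zeros((n, 4, 2, 2))
    for p, part in enumerate(participants):
        for e, lock in enumerate(ENTRAINERS):
            for w_what, what_pred in enumerate((False, True)):
                for w_when, when_pred in enumerate((False, True)):
                    condition = _condition_for(what_pred, when_pred)
                    amp[p, e, w_what, w_when] = part["amplitude"][
                        (condition, lock)]
    anova = stats_mod.rm_anova_3way(amp)

    # ---- pairwise spatiotemporal cluster permutation comparisons ----
    comparisons: dict = {}
    for comp in config.comparisons:
        per_lock = {}
        for lock in ENTRAINERS + ("T",):
            a = np.stack([p["evoked"][(comp["a"], lock)].data
                          for p in participants])
            b = np.stack([p["evoked"][(comp["b"], lock)].data
                          for p in participants])
            times = participants[0]["evoked"][(comp["a"], lock)].times
            res = stats_mod.cluster_permutation_test(
                a, b, adjacency=sensors.adjacency, times=times,
                window=comp["window"], n_perm=config.n_perm,
                threshold_alpha=config.cluster_threshold_alpha,
                min_neighbors=config.min_neighbors,
                seed=_participant_seed(config, 0, 40000),
                method=config._perm_method())
            lo, hi = comp["window"]
            wsel = (times >= lo - 1e-9) & (times <= hi + 1e-9)
            summary = res.to_dict(times=times[wsel],
                                  sensor_names=sensors.pair_names())
            summary["significant"] = bool(res.significant(comp["sig_alpha"]))
            per_lock[lock] = summary
        comparisons[comp["name"]] = {
            "a": comp["a"], "b": comp["b"], "window": list(comp["window"]),
            "sig_alpha": comp["sig_alpha"], "by_stimulus": per_lock}

    # ---- source comparison at E4 ----
    source_report: dict = {}
    if config.run_source:
        model = src_mod.build_source_model(sensors, config.source_spacing)
        maps = {}
        for p, part in enumerate(participants):
            for condition in design_mod.CONDITIONS:
                maps[(p, condition)] = src_mod.source_map_evoked(
                    part["evoked_raw"][(condition, "E4")], model,
                    part["covariance"], sensors, config.source_window)
        grand = np.mean([m.values for m in maps.values()], axis=0)
        grand_map = src_mod.SourceMap(
            grid=model.grid, values=grand,
            local_maxima=src_mod._local_maxima(model, grand),
            window=config.source_window)
        if not grand_map.local_maxima:
            source_report["note"] = "no local maximum in the grand map"
        else:
            peak_pos, _ = grand_map.local_maxima[0]
            peaks = {condition: np.array(
                [src_mod.sphere_peak_value(maps[(p, condition)], peak_pos,
                                           max(0.005, config.source_spacing))
                 for p in range(n)])
                for condition in design_mod.CONDITIONS}
            tests = {}
            for c1, c2 in combinations(design_mod.CONDITIONS, 2):
                t, pval = ttest_rel(peaks[c1], peaks[c2])
                tests[f"{c1}_vs_{c2}"] = {"t": float(t), "p": float(pval)}
            source_report = {
                "peak_position_m": np.asarray(peak_pos).tolist(),
                "peak_values": {c: v.tolist() for c, v in peaks.items()},
                "mean_peak": {c: float(v.mean()) for c, v in peaks.items()},
                "t_tests": tests,
            }

    # ---- group-level decoding statistics ----
    decoding_report: dict = {}
    if config.run_decoding:
        dc = config.decoding
        for feature in dc.features:
            for condition in dc.conditions:
                for stim in dc.stimuli:
                    times, _ = participants[0]["decoding"][
                        (feature, condition, stim)]
                    accs = np.stack([p["decoding"][(feature, condition,
                                                    stim)][1]
                                     for p in participants])
                    res = stats_mod.sign_permutation_test(
                        accs - dec_mod.CHANCE, n_perm=config.n_perm,
                        seed=_participant_seed(config, 0, 80000),
                        method=config._perm_method())
                    sig = res.significant(0.01)
                    mean = accs.mean(axis=0)
                    peak_idx = int(mean.argmax())
                    decoding_report[f"{feature}/{condition}/{stim}"] = {
                        "times_ms": times.tolist(),
                        "mean_accuracy": mean.tolist(),
                        "peak_accuracy": float(mean[peak_idx]),
                        "peak_latency_ms": float(times[peak_idx]),
                        "significant_windows_ms": [
                            [float(times[c.members[:, 1].min()]),
                             float(times[c.members[:, 1].max()])]
                            for c in sig],
                        "per_participant_peak": accs.max(axis=1).tolist(),
                    }

    return StudyReport(
        config=config.to_dict(), config_hash=config.config_hash(),
        anova=anova.to_dict(orient="records"),
        amplitudes=[{"participant": p,
                     "condition": c, "stimulus": lock,
                     "amplitude": float(v)}
                    for p, part in enumerate(participants)
                    for (c, lock), v in part["amplitude"].items()],
        comparisons=comparisons, source=source_report,
        decoding=decoding_report,
        provenance={"seed": config.seed,
                    "participant_seeds": [_participant_seed(config, p)
                                          for p in range(n)]},
    )


def _condition_for(what_pred: bool, when_pred: bool) -> str:
    if what_pred and when_pred:
        return "what_when"
    if what_pred:
        return "what_only"
    if when_pred:
        return "when_only"
    return "random"
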