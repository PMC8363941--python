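"""Sensor-level ERF analysis.

Loads the simulated cohort, band-passes (0.5-45 Hz), applies the
pre-fixation baseline, averages stimulus-locked epochs per condition,
combines planar pairs, reads peak amplitudes (85-135 ms) from the five
localizer-selected occipital sensors, and runs (i) the three-way
repeated-measures ANOVA (entrainer x what x when) and (ii) the four
pairwise spatiotemporal cluster permutation comparisons.

Writes results/anova.csv, results/amplitudes.csv and
results/sensor_clusters.json.
"""

import json

import numpy as np

from _common import CONFIG, LOCKS, RESULTS, localizer_path, recording_path
from entrainmeg import design as dz, erf, stats
from entrainmeg.pipeline import DEFAULT_COMPARISONS, _participant_seed
from entrainmeg.sensors import make_sensor_array
from entrainmeg.simulate import load_recordings


def preprocess(path):
    rec = load_recordings(path)
    rec = erf.bandpass(rec, *CONFIG.bandpass)
    return erf.baseline_correct(rec, window=CONFIG.baseline_window)


def main() -> None:
    sensors = make_sensor_array(CONFIG.n_sites,
                                neighbor_radius=CONFIG.neighbor_radius)
    evokeds: dict = {}
    amplitudes = []
    n = CONFIG.n_participants
    amp = np.zeros((n, 4, 2, 2))

    for p in range(n):
        rec = preprocess(recording_path(p))
        loc = preprocess(localizer_path(p))
        loc_ev = erf.combine_planar(
            erf.average(erf.epoch(loc, "T", (-50.0, 270.0))), sensors)
        selected = erf.select_sensors_by_localizer(
            loc_ev, CONFIG.n_select_sensors, CONFIG.erf_window)

        cond = rec.design["condition"].to_numpy()
        for lock in LOCKS:
            epochs = erf.epoch(rec, lock, CONFIG.epoch_windows[lock])
            for condition in dz.CONDITIONS:
                comb = erf.combine_planar(
                    erf.average(epochs, cond == condition), sensors)
                evokeds[(p, condition, lock)] = comb
                if lock == "T":
                    continue
                value = erf.window_amplitude(comb, selected,
                                             CONFIG.erf_window,
                                             CONFIG.erf_mode)
                amplitudes.append({"participant": p, "condition": condition,
                                   "stimulus": lock, "amplitude": value})
                e = int(lock[1]) - 1
                what = int(condition in dz.ORIENTATION_PREDICTABLE)
                when = int(condition in dz.TIME_PREDICTABLE)
                amp[p, e, what, when] = value
        print(f"sub-{p:02d}: occipital sensors {selected}")

    anova = stats.rm_anova_3way(amp)
    stats.anova_to_csv(anova, RESULTS / "anova.csv")
    print("\nRM-ANOVA (peak amplitude 85-135 ms):")
    print(anova[["effect", "F", "p"]].to_string(index=False))

    import pandas as pd
    pd.DataFrame(amplitudes).to_csv(RESULTS / "amplitudes.csv", index=False)

    clusters_out: dict = {}
    for comp in DEFAULT_COMPARISONS:
        per_lock = {}
        for lock in LOCKS:
            a = np.stack([evokeds[(p, comp["a"], lock)].data
                          for p in range(n)])
            b = np.stack([evokeds[(p, comp["b"], lock)].data
                          for p in range(n)])
            times = evokeds[(0, comp["a"], lock)].times
            res = stats.cluster_permutation_test(
                a, b, adjacency=sensors.adjacency, times=times,
                window=comp["window"], n_perm=CONFIG.n_perm,
                threshold_alpha=CONFIG.cluster_threshold_alpha,
                min_neighbors=CONFIG.min_neighbors,
                seed=_participant_seed(CONFIG, 0, 40000),
                method=CONFIG._perm_method())
            lo, hi = comp["window"]
            sel = (times >= lo) & (times <= hi)
            summary = res.to_dict(times=times[sel],
                                  sensor_names=sensors.pair_names())
            for cluster in summary["clusters"]:
                cluster.pop("members")   # keep the summary file compact
            summary["significant"] = bool(res.significant(comp["sig_alpha"]))
            per_lock[lock] = summary
            if summary["significant"]:
                win = summary["clusters"][0]["time_range_ms"]
                print(f"{comp['name']} @ {lock}: cluster "
                      f"{win[0]:.0f}-{win[1]:.0f} ms, "
                      f"p = {summary['clusters'][0]['p']:.4f}")
        clusters_out[comp["name"]] = {"a": comp["a"], "b": comp["b"],
                                      "window": list(comp["window"]),
                                      "by_stimulus": per_lock}

    with open(RESULTS / "sensor_clusters.json", "w") as f:
        json.dump(clusters_out, f, indent=1)
    print(f"\nwrote {RESULTS / 'anova.csv'}, {RESULTS / 'amplitudes.csv'}, "
          f"{RESULTS / 'sensor_clusters.json'}")


if __name__ == "__main__":
    main()
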