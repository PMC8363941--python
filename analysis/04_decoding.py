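"""Time-resolved orientation and spatial-frequency decoding.

Decodes the target-derived class labels from 200 Hz-downsampled epochs
with the pseudo-trial / noise-normalisation / linear-SVM scheme, per
condition and stimulus, then tests group accuracy against chance with the
one-tailed cluster-corrected sign permutation test.

Writes results/decoding_accuracy.csv and results/decoding_summary.json.
"""

import json

import numpy as np
import pandas as pd

from _common import CONFIG, RESULTS, recording_path
from entrainmeg import decoding as dec, erf, stats
from entrainmeg.pipeline import _participant_seed
from entrainmeg.simulate import load_recordings


def main() -> None:
    dc = CONFIG.decoding
    n = CONFIG.n_participants
    curves: dict = {}
    rows = []

    for p in range(n):
        rec = load_recordings(recording_path(p))
        rec = erf.bandpass(rec, *CONFIG.bandpass)
        rec = erf.baseline_correct(rec, window=CONFIG.baseline_window)
        cond = rec.design["condition"].to_numpy()
        for feature in ("orientation", "cpd"):
            labels = dec.derive_labels(rec.design, feature)
            stimuli = dc.stimuli if feature == "orientation" else ("T",)
            for condition in dc.conditions:
                mask = cond == condition
                for stim in stimuli:
                    ep = erf.epoch(rec, stim, CONFIG.epoch_windows[stim])
                    sub = dec.downsample(ep.select(mask), dc.target_sfreq)
                    acc = dec.decode_timecourse(
                        sub.data, labels[mask], dc.bin_size, dc.n_folds,
                        dc.n_repeats,
                        seed=_participant_seed(CONFIG, p, 70000))
                    curves[(feature, condition, stim, p)] = (sub.times, acc)
        print(f"sub-{p:02d} decoded")

    for (feature, condition, stim) in sorted({k[:3] for k in curves}):
        times = curves[(feature, condition, stim, 0)][0]
        accs = np.stack([curves[(feature, condition, stim, p)][1]
                         for p in range(n)])
        rows += [{"condition": condition, "stimulus": stim,
                  "feature": feature, "time_ms": round(float(t), 1),
                  "mean_accuracy": round(float(a), 4),
                  "sd_accuracy": round(float(s), 4)}
                 for t, a, s in zip(times, accs.mean(axis=0),
                                    accs.std(axis=0))]
    pd.DataFrame(rows).to_csv(RESULTS / "decoding_accuracy.csv", index=False)

    summary = {}
    keys = sorted({k[:3] for k in curves})
    for feature, condition, stim in keys:
        times = curves[(feature, condition, stim, 0)][0]
        accs = np.stack([curves[(feature, condition, stim, p)][1]
                         for p in range(n)])
        res = stats.sign_permutation_test(
            accs - dec.CHANCE, n_perm=CONFIG.n_perm,
            seed=_participant_seed(CONFIG, 0, 80000),
            method=CONFIG._perm_method())
        sig = res.significant(0.01)
        mean = accs.mean(axis=0)
        peak = int(mean.argmax())
        windows = [[float(times[c.members[:, 1].min()]),
                    float(times[c.members[:, 1].max()])] for c in sig]
        summary[f"{feature}/{condition}/{stim}"] = {
            "peak_accuracy": float(mean[peak]),
            "peak_latency_ms": float(times[peak]),
            "significant_windows_ms": windows,
        }
        flag = (f"sig {windows}" if windows else "n.s.")
        print(f"{feature:11s} {condition:10s} {stim}: peak "
              f"{mean[peak]:.3f} at {times[peak]:.0f} ms ({flag})")

    with open(RESULTS / "decoding_summary.json", "w") as f:
        json.dump(summary, f, indent=1)
    print(f"\nwrote {RESULTS / 'decoding_accuracy.csv'}, "
          f"{RESULTS / 'decoding_summary.json'}")


if __name__ == "__main__":
    main()
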