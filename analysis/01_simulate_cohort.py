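"""Simulate the synthetic cohort.

Generates the balanced 2x2x4 design per participant (plus a localizer
block), simulates sensor-space recordings with the default effect
structure (15% expectation suppression per entrainer, extra 15% at E4
under temporal jitter, orientation-pattern strength growing across
entrainers only when orientation is predictable), and writes the
recordings to scratch/ as HDF5 with CSV design tables alongside.
"""

from dataclasses import replace

from _common import CONFIG, RESULTS, SCRATCH, localizer_path, recording_path
from entrainmeg import design as dz
from entrainmeg.pipeline import _participant_seed, validate_config
from entrainmeg.sensors import make_sensor_array
from entrainmeg.simulate import save_recordings, simulate_participant


def main() -> None:
    issues = validate_config(CONFIG)
    assert not issues, issues
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    sensors = make_sensor_array(CONFIG.n_sites,
                                neighbor_radius=CONFIG.neighbor_radius)
    sensors.to_csv(SCRATCH / "channels.csv")

    for p in range(CONFIG.n_participants):
        design = dz.generate_design(CONFIG.n_per_condition,
                                    seed=_participant_seed(CONFIG, p))
        effects = replace(CONFIG.effects,
                          seed=_participant_seed(CONFIG, p, 5000))
        rec = simulate_participant(design, sensors, effects, CONFIG.sfreq)
        dz.design_to_csv(design, SCRATCH / f"sub-{p:02d}_design.csv")
        save_recordings(rec, recording_path(p))

        loc = dz.generate_localizer_design(
            CONFIG.n_localizer, seed=_participant_seed(CONFIG, p, 9000))
        loc_rec = simulate_participant(
            loc, sensors, replace(effects, seed=effects.seed + 1),
            CONFIG.sfreq)
        save_recordings(loc_rec, localizer_path(p))
        print(f"sub-{p:02d}: {rec.data.shape[0]} trials, "
              f"{rec.data.shape[1]} channels, "
              f"{rec.data.shape[2]} samples -> {recording_path(p).name}")

    print(f"cohort of {CONFIG.n_participants} written to {SCRATCH}")


if __name__ == "__main__":
    main()
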