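"""Trial design generation for the 2x2x4 entrainment paradigm.

Each trial is a fixation cross followed by four Gabor *entrainers* and a
fifth *target* Gabor.  Two binary factors define four conditions:

* ``what_when`` - entrainer/target orientations follow a predictable
  rotation and stimulus timing is isochronous,
* ``when_only`` - timing isochronous, orientations shuffled,
* ``what_only`` - orientations predictable, timing jittered,
* ``random``    - orientations shuffled and timing jittered.

Orientation predictability means the four entrainer orientations form an
arithmetic progression (step of +/-15 or +/-30 degrees) that extrapolates to
the target orientation (horizontal = 0 deg or vertical = 90 deg).  In the
shuffled conditions the same four angles are presented in a non-monotonic
order, so the target cannot be extrapolated.

Isochronous timing uses 200 ms inter-stimulus gaps between entrainers and a
600 ms gap before the target; jittered timing draws the gaps uniformly from
70-330 ms (entrainers) and 370-850 ms (target).  Every stimulus lasts
200 ms, so the isochronous entrainer onset asynchrony is 400 ms and the
jittered one is 400 +/- 130 ms on average.  Gaps are quantised to 1 ms
(the presentation clock); onsets therefore fall on exact samples of a
1 kHz recording.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CONDITIONS = ("what_when", "when_only", "what_only", "random")
#: conditions in which the entrainer orientations predict the target
ORIENTATION_PREDICTABLE = frozenset({"what_when", "what_only"})
#: conditions with isochronous stimulus timing
TIME_PREDICTABLE = frozenset({"what_when", "when_only"})

STIMULI = ("E1", "E2", "E3", "E4", "T")
ONSET_COLUMNS = {
    "fixation": "fixation_onset_ms",
    "E1": "e1_onset_ms",
    "E2": "e2_onset_ms",
    "E3": "e3_onset_ms",
    "E4": "e4_onset_ms",
    "T": "t_onset_ms",
}

STIM_DURATION_MS = 200.0
FIXED_ISI_MS = (200.0, 200.0, 200.0, 600.0)
JITTER_ENTRAINER_MS = (70.0, 330.0)
JITTER_TARGET_MS = (370.0, 850.0)
TARGET_CPD = {"high": 60.0, "low": 20.0}
ENTRAINER_CPD = 40.0

DESIGN_COLUMNS = [
    "trial_id", "condition", "step_deg",
    "ent1_deg", "ent2_deg", "ent3_deg", "ent4_deg", "target_deg",
    "target_cpd", "entrainer_cpd",
    "fixation_onset_ms", "e1_onset_ms", "e2_onset_ms", "e3_onset_ms",
    "e4_onset_ms", "t_onset_ms",
    "isi1_ms", "isi2_ms", "isi3_ms", "isi4_ms",
]


class BalanceError(ValueError):
    """Raised when a requested design cannot be balanced."""


def _draw_isis(rng: np.random.Generator, jittered: bool) -> np.ndarray:
    if not jittered:
        return np.asarray(FIXED_ISI_MS, dtype=float)
    lo, hi = JITTER_ENTRAINER_MS
    tlo, thi = JITTER_TARGET_MS
    isis = np.empty(4)
    isis[:3] = np.round(rng.uniform(lo, hi, size=3))
    isis[3] = np.round(rng.uniform(tlo, thi))
    return isis


def _entrainer_angles(rng: np.random.Generator, target: float, step: float,
                      predictable: bool) -> np.ndarray:
    """Four entrainer orientations; progression extrapolating to the target
    when predictable, otherwise a shuffled (non-monotonic) order of the same
    angles."""
    progression = target - step * np.arange(4, 0, -1)
    if predictable:
        return progression
    while True:
        order = rng.permutation(4)
        if not np.array_equal(order, np.arange(4)):
            return progression[order]


def generate_design(n_per_condition: int = 160,
                    step_set=(-30.0, -15.0, 15.0, 30.0),
                    seed: int = 0,
                    fixation_duration_ms: float = 500.0) -> pd.DataFrame:
    """Generate a balanced design table over the four conditions.

    Per condition, half the trials have a horizontal (0 deg) and half a
    vertical (90 deg) target, crossed with an equal split of high
    (60 cpd) / low (20 cpd) target spatial frequencies; hence
    ``n_per_condition`` must be divisible by 4.
    """
    if n_per_condition % 4 != 0:
        raise BalanceError(
            f"n_per_condition={n_per_condition} is not divisible by 4; "
            "cannot balance target orientation x spatial frequency")
    rng = np.random.default_rng(seed)
    step_set = np.asarray(step_set, dtype=float)
    quarter = n_per_condition // 4

    rows = []
    for condition in CONDITIONS:
        predictable = condition in ORIENTATION_PREDICTABLE
        jittered = condition not in TIME_PREDICTABLE
        targets = np.repeat([0.0, 90.0], n_per_condition // 2)
        cpds = np.tile(np.repeat(["high", "low"], quarter), 2)
        order = rng.permutation(n_per_condition)
        for t_orient, cpd_class in zip(targets[order], cpds[order]):
            step = float(rng.choice(step_set))
            ents = _entrainer_angles(rng, t_orient, step, predictable)
            isis = _draw_isis(rng, jittered)
            onsets = np.empty(5)
            onsets[0] = fixation_duration_ms
            for k in range(1, 5):
                onsets[k] = onsets[k - 1] + STIM_DURATION_MS + isis[k - 1]
            rows.append({
                "condition": condition,
                "step_deg": step,
                "ent1_deg": ents[0], "ent2_deg": ents[1],
                "ent3_deg": ents[2], "ent4_deg": ents[3],
                "target_deg": t_orient,
                "target_cpd": TARGET_CPD[cpd_class],
                "entrainer_cpd": ENTRAINER_CPD,
                "fixation_onset_ms": 0.0,
                "e1_onset_ms": onsets[0], "e2_onset_ms": onsets[1],
                "e3_onset_ms": onsets[2], "e4_onset_ms": onsets[3],
                "t_onset_ms": onsets[4],
                "isi1_ms": isis[0], "isi2_ms": isis[1],
                "isi3_ms": isis[2], "isi4_ms": isis[3],
            })

    table = pd.DataFrame(rows)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    table.insert(0, "trial_id", np.arange(len(table)))
    return table[DESIGN_COLUMNS]


def generate_localizer_design(n_trials: int = 80, seed: int = 0,
                              fixation_duration_ms: float = 500.0,
                              ) -> pd.DataFrame:
    """Localizer block: single horizontal/vertical Gabors at fixation, used
    downstream only to pick the most responsive occipital sensors."""
    if n_trials % 2 != 0:
        raise BalanceError("localizer n_trials must be even")
    rng = np.random.default_rng(seed)
    targets = rng.permutation(np.repeat([0.0, 90.0], n_trials // 2))
    table = pd.DataFrame({
        "trial_id": np.arange(n_trials),
        "condition": "localizer",
        "step_deg": 0.0,
        "ent1_deg": np.nan, "ent2_deg": np.nan,
        "ent3_deg": np.nan, "ent4_deg": np.nan,
        "target_deg": targets,
        "target_cpd": ENTRAINER_CPD,
        "entrainer_cpd": ENTRAINER_CPD,
        "fixation_onset_ms": 0.0,
        "e1_onset_ms": np.nan, "e2_onset_ms": np.nan,
        "e3_onset_ms": np.nan, "e4_onset_ms": np.nan,
        "t_onset_ms": fixation_duration_ms,
        "isi1_ms": np.nan, "isi2_ms": np.nan,
        "isi3_ms": np.nan, "isi4_ms": np.nan,
    })
    return table[DESIGN_COLUMNS]


def design_to_csv(design: pd.DataFrame, path) -> None:
    design.to_csv(path, index=False)


def design_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def check_design(design: pd.DataFrame,
                 n_per_condition: int | None = None) -> list[str]:
    """Validate the design invariants; returns a list of violations."""
    issues: list[str] = []
    for condition, sub in design.groupby("condition"):
        if condition == "localizer":
            continue
        if n_per_condition is not None and len(sub) != n_per_condition:
            issues.append(f"{condition}: {len(sub)} trials, "
                          f"expected {n_per_condition}")
        n_h = int((sub["target_deg"] == 0.0).sum())
        n_v = int((sub["target_deg"] == 90.0).sum())
        if n_h != n_v:
            issues.append(f"{condition}: orientation imbalance {n_h}/{n_v}")
        n_hi = int((sub["target_cpd"] == TARGET_CPD["high"]).sum())
        n_lo = int((sub["target_cpd"] == TARGET_CPD["low"]).sum())
        if n_hi != n_lo:
            issues.append(f"{condition}: cpd imbalance {n_hi}/{n_lo}")
        ents = sub[["ent1_deg", "ent2_deg", "ent3_deg", "ent4_deg"]].to_numpy()
        tgt = sub["target_deg"].to_numpy()
        step = sub["step_deg"].to_numpy()
        if condition in ORIENTATION_PREDICTABLE:
            seq = np.column_stack([ents, tgt])
            if not np.allclose(np.diff(seq, axis=1), step[:, None]):
                issues.append(f"{condition}: broken progression")
        isis = sub[["isi1_ms", "isi2_ms", "isi3_ms", "isi4_ms"]].to_numpy()
        if condition in TIME_PREDICTABLE:
            if not np.allclose(isis, np.asarray(FIXED_ISI_MS)):
                issues.append(f"{condition}: non-fixed ISIs")
        else:
            lo, hi = JITTER_ENTRAINER_MS
            tlo, thi = JITTER_TARGET_MS
            if isis[:, :3].min() < lo or isis[:, :3].max() > hi:
                issues.append(f"{condition}: entrainer ISI out of range")
            if isis[:, 3].min() < tlo or isis[:, 3].max() > thi:
                issues.append(f"{condition}: target ISI out of range")
    return issues
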