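"""Shared configuration for the analysis drivers.

A desk-scale study: 8 synthetic participants, 40 trials per condition and
24 sensor sites, so the full chain (simulation, sensor statistics, source
mapping, decoding) runs in minutes on one CPU.  With 8 participants the
exact sign-flip null has 256 relabelings, so the 0.01-level cluster
comparisons remain attainable (floor 2/256).  Binary intermediates go to
``scratch/``; tables and summaries go to ``results/``.
"""

import pathlib

from entrainmeg.pipeline import DecodingConfig, StudyConfig

ROOT = pathlib.Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

CONFIG = StudyConfig(
    n_participants=8,
    n_per_condition=40,
    n_localizer=40,
    n_sites=24,
    neighbor_radius=0.085,
    n_perm=500,
    source_spacing=0.02,
    decoding=DecodingConfig(conditions=("what_when", "when_only"),
                            stimuli=("E1", "E4"),
                            bin_size=2, n_folds=5, n_repeats=5),
    seed=7,
)

LOCKS = ("E1", "E2", "E3", "E4", "T")


def recording_path(p: int) -> pathlib.Path:
    return SCRATCH / f"sub-{p:02d}_recordings.h5"


def localizer_path(p: int) -> pathlib.Path:
    return SCRATCH / f"sub-{p:02d}_localizer.h5"
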