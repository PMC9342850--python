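"""Shared configuration and paths for the numbered analysis drivers.

Every driver reads and writes under ``results/pipeline`` so the scripts can
be run in order (01 -> 06) as a narrative version of the packaged study.
"""

from __future__ import annotations

from pathlib import Path

from idpens import study

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline"
PRIORS_DIR = RESULTS / "priors"
DATA_DIR = RESULTS / "data"
BME_DIR = RESULTS / "bme"
MC_DIR = RESULTS / "mc"
ANALYSIS_DIR = RESULTS / "analysis"

#: one shared configuration drives all stages
CONFIG = study.RunConfig(seed=1)

PRIOR_NAMES = ("coil", "matched", "compact")


def ensure_dirs() -> None:
    for d in (PRIORS_DIR, DATA_DIR, BME_DIR, MC_DIR, ANALYSIS_DIR):
        d.mkdir(parents=True, exist_ok=True)
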