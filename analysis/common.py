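"""Shared configuration for the numbered analysis drivers.

All drivers run on the same synthetic study (seed 2026) so their outputs
are mutually consistent; every table lands under ``results/``.
"""
from pathlib import Path

from epicon.sim import SimulationConfig

SEED = 2026
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "synthetic"


def study_config(**overrides) -> SimulationConfig:
    kw = dict(seed=SEED, n_loci=1000)
    kw.update(overrides)
    return SimulationConfig(**kw)


def ensure_dirs() -> None:
    RESULTS.mkdir(exist_ok=True)
    DATA.mkdir(exist_ok=True)
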