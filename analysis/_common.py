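"""Shared condition definitions for the numbered analysis scripts.

Three synthetic conditions emulate the study design: a 1 bar control, a
25 bar hydrostatic analogue (pressure but no dissolved gas: the gas stays
out of the inter-leaflet gap and the channel stays hydrated), and a 25 bar
helium analogue (90 % of the gas pooled in the gap, channel-shell water
halved). Systems are rebuilt deterministically from their specs, so every
script runs standalone.
"""

from functools import lru_cache
from pathlib import Path

from hyperbar import synth

SEED = 1
RESULTS = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"

CONDITIONS = {
    "control": dict(f_gap=0.0, tmd_dehydration=0.0, seed=SEED),
    "hydrostatic": dict(f_gap=0.0, tmd_dehydration=0.0, seed=SEED + 1000),
    "helium": dict(f_gap=0.9, tmd_dehydration=0.5, seed=SEED + 2000),
}


def spec_for(name: str) -> synth.SynthSpec:
    return synth.SynthSpec(**CONDITIONS[name])


@lru_cache(maxsize=None)
def system_for(name: str):
    spec = spec_for(name)
    top, traj = synth.build_system(spec)
    return spec, top, traj


def ensure_dirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
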