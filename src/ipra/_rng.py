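"""Named sub-stream seeding.

Every stochastic stage draws from its own `numpy` Generator derived from
(master seed, iteration index, stage label).  Turning one uncertainty source
on or off therefore never perturbs the draws of any other source, which the
factorial sensitivity analysis relies on, and adding a new stage never
changes existing streams.
"""

from __future__ import annotations

import numpy as np

# Fixed stage identifiers; append only, never renumber.
STAGES = {
    "survey_gen": 101,
    "concentration_gen": 102,
    "dose_response_gen": 103,
    "consumption": 0,
    "concentration": 1,
    "nanofraction": 2,
    "bmd": 3,
    "chronic": 4,
    "inter": 5,
    "intra": 6,
    "exposure_inner": 7,
    "hazard_inner": 8,
}


def substream(master_seed: int, iteration: int, stage: str) -> np.random.Generator:
    """Generator for one (iteration, stage) cell of the Monte Carlo scheme."""
    if stage not in STAGES:
        raise KeyError(f"unknown RNG stage {stage!r}")
    seq = np.random.SeedSequence(int(master_seed), spawn_key=(int(iteration), STAGES[stage]))
    return np.random.default_rng(seq)


def generator_stream(seed: int, stage: str) -> np.random.Generator:
    """Top-level stream for a synthetic-data generator call."""
    return substream(seed, 0, stage)
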