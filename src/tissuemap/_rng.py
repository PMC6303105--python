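"""Deterministic per-stage random-number streams.

A single user-facing seed is expanded into independent streams with
``numpy.random.SeedSequence([seed, stage_code, *extra])``.  The scheme is
documented here once so any stage can be replayed in isolation: the stage
code is a fixed small integer, and ``extra`` words (e.g. a cell index or a
replicate index) separate sub-streams within a stage.  Changing the seed of
one stage never perturbs another.
"""

from __future__ import annotations

import numpy as np

STAGE_CODES = {
    "panel": 11,
    "annotation": 12,
    "cells": 21,
    "cell_perturb": 22,
    "qc_select": 23,
    "bulk": 31,
    "consensus": 41,
    "tsne": 42,
    "pipeline": 51,
}


def stage_sequence(seed: int, stage: str, *extra: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), STAGE_CODES[stage], *map(int, extra)])


def stage_rng(seed: int, stage: str, *extra: int) -> np.random.Generator:
    """Generator for one stage (and optional sub-stream) of a run."""
    return np.random.default_rng(stage_sequence(seed, stage, *extra))


def stage_int_seed(seed: int, stage: str, *extra: int) -> int:
    """A 31-bit integer seed for libraries that take ``random_state`` ints."""
    return int(stage_sequence(seed, stage, *extra).generate_state(1)[0] % (2**31))
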