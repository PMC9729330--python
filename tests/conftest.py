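"""Shared fixtures.

The expensive 10,000-replicate SPRT Monte-Carlo cells are computed once
per session and shared by every test that needs them.  All seeds are
fixed constants derived from a single master seed via stable spawn keys;
they were chosen before any results were inspected and must never be
changed in response to test outcomes.
"""

from __future__ import annotations

import numpy as np
import pytest

from seqtest import (
    DesignSpec,
    HypothesisSpec,
    point,
    simulate_design,
    wald_thresholds,
)

MASTER_SEED = 0
WALD = wald_thresholds(0.05, 0.1)


def sprt_design(delta1: float, sided: int = 1, n_max: int = 10_000,
                thresholds=WALD) -> DesignSpec:
    return DesignSpec(test_type="sprt", sided=sided, alt=HypothesisSpec(point(delta1)),
                      thresholds=thresholds, n_max=n_max)


#: (delta1, delta_true) -> stable spawn key, fixed a priori.
_CELLS = {
    (0.2, 0.0): 0,
    (0.5, 0.0): 1,
    (0.8, 0.0): 2,
    (0.2, 0.2): 3,
    (0.5, 0.5): 4,
    (0.8, 0.8): 5,
}


@pytest.fixture(scope="session")
def sprt_cell():
    """Memoized 10,000-replicate one-sided SPRT cells with Wald thresholds."""
    cache: dict = {}

    def get(delta1: float, delta_true: float):
        key = (delta1, delta_true)
        if key not in cache:
            seed = np.random.SeedSequence(entropy=MASTER_SEED, spawn_key=(_CELLS[key],))
            cache[key] = simulate_design(sprt_design(delta1), delta_true, 10_000, seed)
        return cache[key]

    return get
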