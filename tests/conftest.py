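"""Shared fixtures: small synthetic worlds and an independent
Smith-Waterman scoring oracle.

The oracle is a deliberately naive cubic-time dynamic program (it
enumerates every gap length at every cell) kept fully separate from the
package's Gotoh implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from tirmap import InsertionMapper, ReferenceDatabase
from tirmap.params import AlignmentParams
from tirmap.simulate import make_world

_BASES = np.array(list("ACGT"))


def random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def sw_oracle_score(a: str, b: str, params: AlignmentParams) -> float:
    """Cubic-time local-alignment score: gap of length k costs
    gap_open + k * gap_extend, enumerated explicitly."""
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = params.match if a[i - 1] == b[j - 1] else -params.mismatch_penalty
            best = max(0.0, H[i - 1, j - 1] + s)
            for k in range(1, i + 1):
                best = max(best, H[i - k, j] - params.gap_open - k * params.gap_extend)
            for k in range(1, j + 1):
                best = max(best, H[i, j - k] - params.gap_open - k * params.gap_extend)
            H[i, j] = best
    return float(H.max())


@pytest.fixture(scope="session")
def small_world():
    """A compact study world: 30-kb genome, 3-kb construct, 31-nt TIRs,
    8-nt TSD, 600-nt genome-derived marker."""
    return make_world(11, genome_length=30_000, construct_length=3_000, marker_length=600)


@pytest.fixture(scope="session")
def small_db(small_world) -> ReferenceDatabase:
    return small_world.database()

@pytest.fixture(scope="session")
def small_mapper(small_db) -> InsertionMapper:
    return InsertionMapper(small_db)
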