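"""Counter-based random-number streams for common-random-numbers coupling.

Every stochastic quantity in a simulated life history is drawn from a
stream keyed by ``(base_seed, woman_id, purpose)``.  Streams for the
*natural history* purposes (mortality, onset, tumor attributes,
progression, clinical surfacing, survival, attendance) are consumed
identically under every screening regimen, so between-regimen differences
in outcomes reflect the regimen alone.  Only the SCREEN stream depends on
which screens are actually attended — and its uniforms are indexed by
screen *age*, so regimens whose schedules are nested share the draws at
shared ages.
"""

from __future__ import annotations

import enum

import numpy as np
from numpy.random import Generator, Philox

#: 64-bit draws reserved per woman per purpose stream; generous upper bound
#: on what one history can consume (the screen stream uses at most 3 * 110).
STREAM_STRIDE = 512


class Purpose(enum.IntEnum):
    """Purpose tags identifying the independent streams of one history."""

    MORTALITY = 0     # other-cause death age
    ONSET = 1         # breast-cancer onset age
    TUMOR = 2         # subtype, growth rate, in-situ flag
    PROGRESSION = 3   # annual in-situ/nodal/distant transitions
    SURFACING = 4     # clinical surfacing age
    SURVIVAL = 5      # cure and post-diagnosis survival-time uniforms
    ATTENDANCE = 6    # lifetime screening-participation draw
    SCREEN = 7        # per-screen detection / false-positive / biopsy draws


def stream(base_seed: int, woman_id: int, purpose: Purpose) -> Generator:
    """Return the Generator for one (seed, woman, purpose) stream.

    Philox is counter-based: jumping straight to a woman's block is O(1),
    so aggregation order and cohort size never change any woman's draws.
    """
    if base_seed < 0 or woman_id < 0:
        raise ValueError("base_seed and woman_id must be nonnegative")
    bitgen = Philox(key=np.array([base_seed, int(purpose)], dtype=np.uint64))
    bitgen.advance(int(woman_id) * STREAM_STRIDE)
    return Generator(bitgen)
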