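"""Stage-at-diagnosis labels.

Substages are tracked internally as strings so statistics that need the
Stage 1 / Stage 2A split (the early-invasive fraction) stay computable,
while published-style tables report the coarse 0–4 grouping.
"""

from __future__ import annotations

#: Ordered from least to most advanced; survival parameters are keyed by
#: these and must be monotone along this order.
SUBSTAGES: tuple[str, ...] = ("0", "1", "2A", "2B", "3", "4")

#: Substages counted as "early invasive" in stage-distribution reports.
EARLY_INVASIVE: tuple[str, ...] = ("1", "2A")

_COARSE = {"0": 0, "1": 1, "2A": 2, "2B": 2, "3": 3, "4": 4}

STAGE_ORDER = {s: i for i, s in enumerate(SUBSTAGES)}


def coarse_stage(substage: str) -> int:
    """Map a substage label to the coarse 0–4 stage used in summary tables."""
    try:
        return _COARSE[substage]
    except KeyError:
        raise ValueError(f"unknown stage label {substage!r}") from None


def stage_rank(substage: str) -> int:
    """Ordinal position of a substage (0 = in situ ... 5 = distant)."""
    try:
        return STAGE_ORDER[substage]
    except KeyError:
        raise ValueError(f"unknown stage label {substage!r}") from None
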