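"""Shared fixtures: published worked examples and independent oracles.

The nine C-terminal hexamers of the published scan example, the class I
reference/constraints they were scanned with, and the from-scratch
scoring oracles live here so every test module draws on one copy.
"""

from __future__ import annotations

import math
from functools import lru_cache

import pytest

from pdzcleft import SequenceRecord

# Published scan example: nine choanoflagellate proteins whose C-terminal
# hexamers all sit two substitutions from the class I reference GGGTGL
# under constraints P0 in {F,I,L,V} and P-2 in {S,T}.
SCAN_EXAMPLE_REFERENCE = "GGGTGL"
SCAN_EXAMPLE_CONSTRAINTS = ["P0=FILV", "P-2=ST"]
SCAN_EXAMPLE_ROWS = [
    ("tr|A9UQN5|A9UQN5_MONBE", "GGCTLL", 2),
    ("tr|A9V457|A9V457_MONBE", "YGGTSF", 2),
    ("tr|A9UZY0|A9UZY0_MONBE", "RYGSGV", 2),
    ("tr|A9UWI6|A9UWI6_MONBE", "GGCSLL", 2),
    ("tr|A9UR91|A9UR91_MONBE", "GYGSTI", 2),
    ("tr|A9UU72|A9UU72_MONBE", "GGPTDI", 2),
    ("tr|A9UX10|A9UX10_MONBE", "GLGTTI", 2),
    ("tr|A9UNL7|A9UNL7_MONBE", "GGSTQI", 2),
    ("tr|A9UPF5|A9UPF5_MONBE", "GDGSSF", 2),
]


@pytest.fixture
def scan_example_proteome() -> list[SequenceRecord]:
    """A proteome whose proteins end in the nine published hexamers."""
    return [
        SequenceRecord(id=pid, residues="MSTA" + hexamer)
        for pid, hexamer, _ in SCAN_EXAMPLE_ROWS
    ]


def oracle_local_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Independent affine-gap local alignment optimum, by plain recursion.

    Three mutually recursive quantities per cell — best alignment ending
    in a residue pair, in a gap consuming ``a``, or in a gap consuming
    ``b`` — maximised over every end cell. A gap of length g costs
    gap_open + g·gap_extend. Written from the recurrence definition, not
    shared with the production implementation.
    """
    first = gap_open + gap_extend

    @lru_cache(maxsize=None)
    def pair(i: int, j: int) -> float:
        if i == 0 or j == 0:
            return -math.inf
        prev = max(0.0, pair(i - 1, j - 1), gap_a(i - 1, j - 1), gap_b(i - 1, j - 1))
        return prev + score(a[i - 1], b[j - 1])

    @lru_cache(maxsize=None)
    def gap_a(i: int, j: int) -> float:  # a[i-1] aligned to a gap
        if i == 0:
            return -math.inf
        return max(pair(i - 1, j) - first, gap_a(i - 1, j) - gap_extend)

    @lru_cache(maxsize=None)
    def gap_b(i: int, j: int) -> float:  # b[j-1] aligned to a gap
        if j == 0:
            return -math.inf
        return max(pair(i, j - 1) - first, gap_b(i, j - 1) - gap_extend)

    best = 0.0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            best = max(best, pair(i, j), gap_a(i, j), gap_b(i, j))
    return best


def oracle_substitution_count(window: str, reference: str, allowed: dict[int, set[str]]):
    """Independent substitution count: direct per-position bookkeeping.

    ``allowed`` maps C-terminal offsets (0 = last residue) to allowed
    residue sets. Returns None when a constrained position violates its
    set, otherwise the number of unconstrained positions differing from
    the reference.
    """
    length = len(reference)
    assert len(window) == length
    count = 0
    for offset in range(length):
        idx = length - 1 - offset
        if offset in allowed:
            if window[idx] not in allowed[offset]:
                return None
        elif window[idx] != reference[idx]:
            count += 1
    return count
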