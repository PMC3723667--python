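"""Two-index superindices: scalar combinations of descriptor pairs.

A superindex fuses the value tables of two descriptors I1, I2 into a new
scalar index.  The nine registered combinators are the simplest sum /
product / power polynomial combinations of two indices:

    S1 : I1 + I2
    S2 : I1 * I2
    S3 : I1^2 * I2
    S4 : I1 * I2^2
    S5 : I1 + I2 + I1 * I2
    S6 : I1 - I2
    S7 : I1^2 + I2
    S8 : I1 + I2^2
    S9 : (I1 * I2)^2

The family splits into a "first set" S1..S5 and a "second set" S6..S9;
the purely multiplicative members (S2, S3, S4, S9) annihilate all
information from I2 wherever I1 = 0 (and vice versa), which is why pairing
them with a zero-heavy entropy index stays highly degenerate while the
additive members discriminate almost perfectly.  Each combinator is a pure
elementwise function; domain violations produce non-finite entries (one
shared class in uniqueness counting), never exceptions.

The lossless *tuple baseline* — the ordered pair (I1, I2) — bounds what
any scalar combinator can achieve: ndv(pair) <= min(ndv(I1), ndv(I2)) and
no scalar combination can discriminate better than the pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import ValueTable

__all__ = ["SuperIndexSpec", "COMBINATORS", "EQ_IDS", "combine",
           "tuple_baseline"]


def _s1(a, b):
    return a + b


def _s2(a, b):
    return a * b


def _s3(a, b):
    return a * a * b


def _s4(a, b):
    return a * b * b


def _s5(a, b):
    return a + b + a * b


def _s6(a, b):
    return a - b


def _s7(a, b):
    return a * a + b


def _s8(a, b):
    return a + b * b


def _s9(a, b):
    ab = a * b
    return ab * ab


#: eq_id -> (elementwise function, human-readable formula)
COMBINATORS = {
    "S1": (_s1, "I1 + I2"),
    "S2": (_s2, "I1 * I2"),
    "S3": (_s3, "I1^2 * I2"),
    "S4": (_s4, "I1 * I2^2"),
    "S5": (_s5, "I1 + I2 + I1*I2"),
    "S6": (_s6, "I1 - I2"),
    "S7": (_s7, "I1^2 + I2"),
    "S8": (_s8, "I1 + I2^2"),
    "S9": (_s9, "(I1 * I2)^2"),
}

EQ_IDS = tuple(COMBINATORS)
FIRST_SET = ("S1", "S2", "S3", "S4", "S5")
SECOND_SET = ("S6", "S7", "S8", "S9")


@dataclass(frozen=True)
class SuperIndexSpec:
    """An ordered pair of descriptors plus one of the nine combinators."""

    eq_id: str
    first: str
    second: str

    def __post_init__(self):
        if self.eq_id not in COMBINATORS:
            raise ValueError(
                f"unknown combinator {self.eq_id!r}; known: {', '.join(EQ_IDS)}"
            )
        if self.first == self.second:
            raise ValueError("superindex components must differ by name")


def _check_aligned(v1: ValueTable, v2: ValueTable) -> None:
    if len(v1) != len(v2):
        raise ValueError(
            f"misaligned value tables: {len(v1)} vs {len(v2)} entries"
        )
    if v1.values is None or v2.values is None:
        raise ValueError("superindex components must be scalar tables")


def combine(v1: ValueTable, v2: ValueTable, eq_id: str) -> ValueTable:
    """Elementwise application of combinator ``eq_id`` to two aligned tables."""
    if eq_id not in COMBINATORS:
        raise ValueError(
            f"unknown combinator {eq_id!r}; known: {', '.join(EQ_IDS)}"
        )
    _check_aligned(v1, v2)
    func, _ = COMBINATORS[eq_id]
    with np.errstate(all="ignore"):
        out = func(np.asarray(v1.values, dtype=np.float64),
                   np.asarray(v2.values, dtype=np.float64))
    return ValueTable(f"{v1.name}_{v2.name}:{eq_id}", out, None, "real")


def tuple_baseline(v1: ValueTable, v2: ValueTable) -> ValueTable:
    """The lossless ordered-pair table (I1, I2).

    Its ndv is the information-theoretic floor for any scalar combinator
    of the same two descriptors.
    """
    _check_aligned(v1, v2)
    return ValueTable(
        f"{v1.name}_{v2.name}:pair", None, None, "pair",
        components=(v1, v2),
    )
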