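"""Shared vocabulary of the mismatch analysis.

A mismatch type is written in PM->MM notation: the first letter is the base on
the perfectly matching probe (identical to the consensus base at the aligned
offset) and the second letter is the base the second-design probe carries
instead.  There are 12 such ordered pairs.
"""

from __future__ import annotations

from enum import Enum

BASES = ("A", "C", "G", "T")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: RNA complement used when the hybridization target is cRNA.
COMPLEMENT_RNA = {"A": "U", "C": "G", "G": "C", "T": "A"}

#: Canonical order of the 12 single-base mismatch types (PM base -> MM base).
MISMATCH_TYPES = tuple(
    f"{pm}-{mm}" for pm in BASES for mm in BASES if pm != mm
)

PROBE_LENGTH = 25


class PositionGroup(str, Enum):
    """Binning of the 25 probe positions used for the type-effect summaries.

    Position 1 is the 5' terminus of the probe sequence as written; the 3'
    end (positions 18-25) is the surface-attached end on the array.
    """

    FIVE_PRIME = "five_prime"
    CENTER = "center"
    THREE_PRIME = "three_prime"

    @classmethod
    def of_position(cls, position: int) -> "PositionGroup":
        if not 1 <= position <= PROBE_LENGTH:
            raise ValueError(f"position {position} outside 1..{PROBE_LENGTH}")
        if position <= 8:
            return cls.FIVE_PRIME
        if position <= 17:
            return cls.CENTER
        return cls.THREE_PRIME


def parse_mismatch_type(mismatch_type: str) -> tuple[str, str]:
    """Split a 'X-Y' mismatch type into (PM base, MM base), validating it."""
    if mismatch_type not in MISMATCH_TYPES:
        raise ValueError(
            f"invalid mismatch type {mismatch_type!r}; expected one of "
            f"{', '.join(MISMATCH_TYPES)}"
        )
    pm, mm = mismatch_type.split("-")
    return pm, mm
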