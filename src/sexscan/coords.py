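"""The single audited conversion between file and internal coordinates.

File formats used here (VCF, sync, printed tables) are 1-based inclusive;
everything internal is 0-based half-open.  Keeping the conversion in one
place makes off-by-one errors grep-able.
"""

from __future__ import annotations


def file_to_internal(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive [start, end] -> 0-based half-open [start-1, end)."""
    if start < 1 or end < start:
        raise ValueError(f"invalid 1-based inclusive interval ({start}, {end})")
    return start - 1, end


def internal_to_file(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive [start+1, end]."""
    if start < 0 or end <= start:
        raise ValueError(f"invalid 0-based half-open interval ({start}, {end})")
    return start + 1, end


def pos_file_to_internal(pos: int) -> int:
    """1-based position -> 0-based index."""
    if pos < 1:
        raise ValueError(f"invalid 1-based position {pos}")
    return pos - 1


def pos_internal_to_file(idx: int) -> int:
    """0-based index -> 1-based position."""
    if idx < 0:
        raise ValueError(f"invalid 0-based index {idx}")
    return idx + 1
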