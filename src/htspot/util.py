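"""Small shared helpers: display rounding and delimiter sniffing."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

__all__ = ["round_half_away", "sniff_delimiter"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed clinical tables).

    Python's built-in ``round`` is banker's rounding; clinical reference
    tables round .005 up in magnitude instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    # repr() preserves the shortest faithful decimal form of the float
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sniff_delimiter(path: str | Path) -> str:
    """Return '\\t' if the first line of the file contains a tab, else ','."""
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","
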