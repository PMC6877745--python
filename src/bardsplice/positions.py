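"""Transcript (c./r.) positions with optional intronic offsets.

All computation in this package is carried out in cDNA coordinates; RNA
(r.) positions are numerically equal to their c. counterparts.  Intronic
positions are expressed relative to the nearest exon boundary, in the
usual HGVS style: ``1395+3`` (three bases into the intron downstream of
c.1395) or ``216-780`` (780 bases upstream of c.216).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import total_ordering

from .errors import EventParseError

_POS_RE = re.compile(r"^(\d+)(?:([+-])(\d+))?$")

#: Offset scale used to embed intronic offsets on the c. axis for interval
#: arithmetic.  Intronic offsets in this gene never approach 1e6, so the
#: embedding is strictly monotone.
_OFFSET_EPS = 1e-7


@total_ordering
@dataclass(frozen=True)
class CPos:
    """A transcript position: an exonic c. base plus an intronic offset."""

    base: int
    offset: int = 0

    @classmethod
    def parse(cls, text: str) -> "CPos":
        m = _POS_RE.match(text.strip())
        if not m:
            raise EventParseError(f"cannot parse transcript position {text!r}")
        base = int(m.group(1))
        off = int(m.group(3)) if m.group(3) else 0
        if m.group(2) == "-":
            off = -off
        return cls(base, off)

    def __str__(self) -> str:
        if self.offset == 0:
            return str(self.base)
        return f"{self.base}{self.offset:+d}"

    @property
    def exonic(self) -> bool:
        return self.offset == 0

    def axis(self) -> float:
        """Monotone embedding on the c. axis (for overlap arithmetic)."""
        return self.base + self.offset * _OFFSET_EPS

    def __lt__(self, other: "CPos") -> bool:
        return self.axis() < other.axis()


def as_cpos(value) -> CPos:
    """Coerce an int, string or CPos into a CPos."""
    if isinstance(value, CPos):
        return value
    if isinstance(value, (int,)):
        return CPos(int(value))
    return CPos.parse(str(value))
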