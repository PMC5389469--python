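"""Motif search patterns.

A contiguous pattern is just a site length ``L``.  A bipartite pattern has two
half sites of lengths ``l`` and ``r`` separated by a variable spacer of
``a``..``b`` nucleotides, written ``l<a,b>r`` (e.g. ``6<0,5>6`` for a nuclear
receptor dimer with spacers up to 5 nt).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_BIPARTITE_RE = re.compile(r"^\s*(\d+)\s*<\s*(\d+)\s*,\s*(\d+)\s*>\s*(\d+)\s*$")
_CONTIG_RE = re.compile(r"^\s*(\d+)\s*$")


@dataclass(frozen=True)
class SearchPattern:
    """Shape of the motif being searched for.

    kind
        ``"contiguous"`` or ``"bipartite"``.
    left, right
        Half-site lengths; for contiguous patterns ``left`` is the full site
        length and ``right`` is 0.
    gap_min, gap_max
        Allowed spacer range (both 0 for contiguous patterns).
    """

    kind: str
    left: int
    right: int = 0
    gap_min: int = 0
    gap_max: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("contiguous", "bipartite"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.left < 1 or (self.kind == "bipartite" and self.right < 1):
            raise ValueError("half-site lengths must be >= 1")
        if not (0 <= self.gap_min <= self.gap_max):
            raise ValueError("need 0 <= gap_min <= gap_max")

    @property
    def width(self) -> int:
        """Number of matrix columns (spacer positions carry no weights)."""
        return self.left + self.right

    @property
    def n_gaps(self) -> int:
        return self.gap_max - self.gap_min + 1 if self.kind == "bipartite" else 1

    def span(self, gap: int = 0) -> int:
        """Genomic footprint of a site with the given spacer."""
        if self.kind == "contiguous":
            return self.left
        if not (self.gap_min <= gap <= self.gap_max):
            raise ValueError(f"gap {gap} outside [{self.gap_min},{self.gap_max}]")
        return self.left + gap + self.right

    @property
    def max_span(self) -> int:
        return self.left + (self.gap_max if self.kind == "bipartite" else 0) + self.right

    def __str__(self) -> str:
        if self.kind == "contiguous":
            return str(self.left)
        return f"{self.left}<{self.gap_min},{self.gap_max}>{self.right}"


def contiguous(length: int) -> SearchPattern:
    return SearchPattern("contiguous", length)

def bipartite(left: int, gap_min: int, gap_max: int, right: int) -> SearchPattern:
    return SearchPattern("bipartite", left, right, gap_min, gap_max)


def parse_pattern(text: str) -> SearchPattern:
    """Parse ``"12"`` or ``"6<0,5>6"`` into a :class:`SearchPattern`.

    Raises ``ValueError`` with a grammar hint on malformed input.
    """
    m = _BIPARTITE_RE.match(text)
    if m:
        l, a, b, r = map(int, m.groups())
        if a > b:
            raise ValueError(
                f"bad pattern {text!r}: gap range requires a <= b in l<a,b>r"
            )
        return bipartite(l, a, b, r)
    m = _CONTIG_RE.match(text)
    if m:
        return contiguous(int(m.group(1)))
    raise ValueError(
        f"bad pattern {text!r}: expected a length like '12' or a bipartite "
        "pattern like '6<0,5>6' (l<a,b>r)"
    )
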