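"""Arrow-code dialect: text encoding of curved half arrows.

Each half (fishhook) arrow moves exactly one electron between two sites.
A site is either an atom, written ``a<label>``, or a bond, written
``b<label>-<label>`` (lower label first in canonical output).  Arrows are
written ``source>target`` and joined with ``;``::

    b10-11>a10;b10-11>b11-20;a20>b11-20

is the three-arrow code of a hydrogen abstraction: the C-H sigma bond
(10-11) sends one electron back to the carbon (10) and one into the
nascent H-Cl bond (11-20), which the chlorine somo (20) completes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Union

from .errors import ParseError

__all__ = ["AtomSite", "BondSite", "Arrow", "Site", "parse_arrow_code", "format_arrows"]


@dataclass(frozen=True, order=True)
class AtomSite:
    """A single atom, addressed by its positive integer label."""

    label: int

    def __str__(self) -> str:
        return f"a{self.label}"

    @property
    def labels(self) -> tuple[int, ...]:
        return (self.label,)


@dataclass(frozen=True, order=True)
class BondSite:
    """A bond between two labeled atoms; stored with the lower label first."""

    label1: int
    label2: int

    def __post_init__(self) -> None:
        if self.label1 > self.label2:
            lo, hi = self.label2, self.label1
            object.__setattr__(self, "label1", lo)
            object.__setattr__(self, "label2", hi)

    def __str__(self) -> str:
        return f"b{self.label1}-{self.label2}"

    @property
    def labels(self) -> tuple[int, ...]:
        return (self.label1, self.label2)


Site = Union[AtomSite, BondSite]

_SITE_RE = re.compile(r"^(?:a(\d+)|b(\d+)-(\d+))$")


def _parse_site(text: str) -> Site:
    m = _SITE_RE.match(text.strip())
    if m is None:
        raise ParseError(f"malformed arrow site {text!r}", fragment=text)
    if m.group(1) is not None:
        label = int(m.group(1))
        if label <= 0:
            raise ParseError(f"labels must be positive: {text!r}", fragment=text)
        return AtomSite(label)
    l1, l2 = int(m.group(2)), int(m.group(3))
    if l1 <= 0 or l2 <= 0 or l1 == l2:
        raise ParseError(f"malformed bond site {text!r}", fragment=text)
    return BondSite(l1, l2)


@dataclass(frozen=True)
class Arrow:
    """One single-electron (half-arrow) move from ``source`` to ``target``."""

    source: Site
    target: Site

    def __str__(self) -> str:
        return f"{self.source}>{self.target}"

    @property
    def labels(self) -> tuple[int, ...]:
        return self.source.labels + self.target.labels


def parse_arrow_code(text: str) -> list[Arrow]:
    """Parse an arrow-code string into a list of :class:`Arrow`.

    Whitespace around separators is tolerated.  Raises
    :class:`~rmechkit.errors.ParseError` on malformed input, including an
    empty code or a repeated arrow.
    """
    if not text or not text.strip():
        raise ParseError("empty arrow code", fragment=text)
    arrows = []
    for chunk in text.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            raise ParseError("empty arrow in code", fragment=text)
        parts = chunk.split(">")
        if len(parts) != 2:
            raise ParseError(f"malformed arrow {chunk!r}", fragment=chunk)
        src, tgt = _parse_site(parts[0]), _parse_site(parts[1])
        if src == tgt:
            raise ParseError(f"arrow with identical source and target {chunk!r}", fragment=chunk)
        arrows.append(Arrow(src, tgt))
    if len(set(arrows)) != len(arrows):
        raise ParseError("duplicate arrow in code", fragment=text)
    return arrows


def format_arrows(arrows: Iterable[Arrow]) -> str:
    """Serialize arrows back to the text dialect (order preserved)."""
    return ";".join(str(a) for a in arrows)
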