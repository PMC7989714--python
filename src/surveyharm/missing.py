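"""Tagged missing values for harmonized survey data.

Survey microdata distinguishes *why* a value is absent. A skip pattern
(the question was never asked of this respondent) is structurally
different from nonresponse (asked, but answered "don't know", refused,
or the answer was not stated). Harmonized tables carry this two-level
taxonomy explicitly instead of collapsing both into a bare NaN:

* ``TaggedMissing.NA_A`` — not applicable (skip pattern / variable not
  collected in this cycle);
* ``TaggedMissing.NA_B`` — don't know / refusal / not stated.

Tagged values compare unequal to every category code and to each other,
and propagate through derived-variable functions with ``NA_A``
dominating ``NA_B``.
"""

from __future__ import annotations

import enum
from typing import Iterable, Optional


class TaggedMissing(enum.Enum):
    """Two-level missing taxonomy for harmonized variables."""

    NA_A = "a"  # structurally not applicable
    NA_B = "b"  # don't know / refusal / not stated

    @property
    def token(self) -> str:
        """Worksheet token, e.g. ``NA::a``."""
        return f"NA::{self.value}"

    def render(self) -> str:
        """Text rendering used in CSV output, e.g. ``NA(a)``."""
        return f"NA({self.value})"

    @classmethod
    def from_token(cls, text: str) -> "TaggedMissing":
        for member in cls:
            if text == member.token:
                return member
        raise ValueError(f"not a tagged-missing token: {text!r}")

    @classmethod
    def from_render(cls, text: str) -> Optional["TaggedMissing"]:
        """Inverse of :meth:`render`; returns None if not a rendering."""
        for member in cls:
            if text == member.render():
                return member
        return None

    @classmethod
    def is_token(cls, text: str) -> bool:
        return any(text == member.token for member in cls)

    @classmethod
    def dominant(cls, values: Iterable[object]) -> Optional["TaggedMissing"]:
        """Return the dominating tag among ``values``, or None.

        ``NA_A`` dominates ``NA_B``: if any input is structurally not
        applicable the result is too; otherwise any nonresponse input
        makes the result nonresponse.
        """
        found_b = False
        for v in values:
            if v is cls.NA_A:
                return cls.NA_A
            if v is cls.NA_B:
                found_b = True
        return cls.NA_B if found_b else None

    def __repr__(self) -> str:  # keeps table dumps readable
        return self.render()

    __str__ = __repr__


def is_tagged(value: object) -> bool:
    """True if ``value`` is a tagged missing marker."""
    return isinstance(value, TaggedMissing)
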