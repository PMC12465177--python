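"""Coordinate arithmetic connecting coding-DNA (c.) variant descriptions to
protein (p.) consequences.

Only the arithmetic layer of HGVS is implemented: CDS position -> codon
index, span lengths, reading-frame effects, and the codon range removed by
an in-frame deletion. Intronic offset notation (e.g. ``c.320-443G>C``) is
parsed and stored but excluded from codon arithmetic, and non-codon-aligned
in-frame deletions report the spanned codon range without 3'-rule
re-normalization. Full HGVS grammar, transcript models and translation are
out of scope.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

__all__ = [
    "CdsVariant",
    "parse_cds",
    "cds_to_codon",
    "span_length",
    "frame_effect",
    "inframe_residue_range",
    "protein_residue",
]

_KINDS = ("substitution", "deletion", "insertion", "delins", "duplication")


@dataclass(frozen=True)
class CdsVariant:
    """A variant in CDS coordinates (1-based, both ends inclusive)."""

    cds_start: int
    cds_end: int
    kind: str
    ref: str = ""
    alt: str = ""
    #: intronic offset of the start position (e.g. -443 in "320-443"); 0 for exonic
    start_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.cds_start < 1:
            raise ValueError("CDS positions are 1-based")
        if self.cds_end < self.cds_start:
            raise ValueError("cds_end < cds_start")
        if self.kind == "substitution" and self.cds_end != self.cds_start:
            raise ValueError("substitution must have cds_end == cds_start")

    @property
    def intronic(self) -> bool:
        return self.start_offset != 0

    @property
    def net_length_change(self) -> int:
        """Inserted minus deleted base pairs."""
        span = self.cds_end - self.cds_start + 1
        if self.kind == "substitution":
            return 0
        if self.kind == "deletion":
            return -span
        if self.kind == "duplication":
            return span
        if self.kind == "insertion":
            return len(self.alt)
        # delins: replaced span vs inserted sequence
        removed = len(self.ref) if self.ref else span
        return len(self.alt) - removed


_POS = r"(\d+)([+-]\d+)?"
_C_RE = re.compile(
    rf"^c\.{_POS}(?:_{_POS})?\s*"
    r"(?:"
    r"(?P<ref>[ACGT]+)?\s*>\s*(?P<alt>[ACGT]+)"  # substitution
    r"|(?P<op>delins|del|dup|ins)\s*(?P<seq>[ACGT]*)"
    r")$"
)


def parse_cds(description: str) -> CdsVariant:
    """Parse a c.-style description into a :class:`CdsVariant`.

    Handles the forms used in variant reports: ``c.2908G>A``,
    ``c.4432_4443del``, ``c.531_533delCCT``, ``c.4863_4864delinsAT``,
    ``c.123_124insA``, ``c.12dup`` and intronic offsets like
    ``c.320-443G>C`` (stored, flagged intronic).
    """
    text = description.strip().replace(" ", "")
    m = _C_RE.match(text)
    if not m:
        raise ValueError(f"unparseable CDS description {description!r}")
    start = int(m.group(1))
    start_offset = int(m.group(2) or 0)
    end = int(m.group(3) or start)
    if m.group("alt") is not None and m.group("op") is None:
        return CdsVariant(
            cds_start=start,
            cds_end=end,
            kind="substitution",
            ref=m.group("ref") or "",
            alt=m.group("alt"),
            start_offset=start_offset,
        )
    op = m.group("op")
    seq = m.group("seq") or ""
    if op == "del":
        return CdsVariant(start, end, "deletion", ref=seq, start_offset=start_offset)
    if op == "dup":
        return CdsVariant(start, end, "duplication", ref=seq, start_offset=start_offset)
    if op == "ins":
        return CdsVariant(start, end, "insertion", alt=seq, start_offset=start_offset)
    return CdsVariant(start, end, "delins", alt=seq, start_offset=start_offset)


def cds_to_codon(cds_pos: int) -> int:
    """Map a 1-based coding nucleotide position to its 1-based codon index.

    ``ceil(pos / 3)``: positions 1-3 -> codon 1, 4-6 -> codon 2, ...
    Intronic offset positions have no codon and must be rejected upstream.
    """
    if isinstance(cds_pos, str):
        raise TypeError("cds_to_codon takes a numeric exonic position; parse offsets first")
    if cds_pos < 1:
        raise ValueError(f"CDS position must be >= 1, got {cds_pos}")
    return math.ceil(cds_pos / 3)


def span_length(v: CdsVariant) -> int:
    """Length in bp of a span event (deletion/duplication/delins/insertion)."""
    if v.kind == "substitution":
        raise ValueError("substitutions are point events; span_length undefined")
    return v.cds_end - v.cds_start + 1


def frame_effect(v: CdsVariant) -> str:
    """``in_frame`` iff the net coding-length change is a multiple of 3."""
    return "in_frame" if v.net_length_change % 3 == 0 else "frameshift"


def inframe_residue_range(v: CdsVariant) -> tuple[int, int]:
    """First and last codon spanned by an in-frame deletion.

    Reports the spanned codon range directly; descriptions are not
    re-shifted by the 3' rule, matching how the source reports describe
    non-normalized deletions.
    """
    if v.intronic:
        raise ValueError("intronic variants have no codon range")
    if frame_effect(v) == "frameshift":
        raise ValueError("residue range is only defined for in-frame events")
    return (cds_to_codon(v.cds_start), cds_to_codon(v.cds_end))


_P_RE = re.compile(r"^p\.\(?([A-Za-z*]{1,3})(\d+)")


def protein_residue(p_description: str) -> int:
    """Extract the (first) residue index from a p.-style description."""
    m = _P_RE.match(p_description.strip())
    if not m:
        raise ValueError(f"unparseable protein description {p_description!r}")
    return int(m.group(2))
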