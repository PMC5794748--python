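"""Restriction enzyme models and IUPAC-aware sequence matching.

A methylation-sensitive restriction enzyme is described by its recognition
sequence (possibly degenerate, e.g. GCWGC with W = A or T) and the position
of the cleavage point within it, written with a caret: MspI cuts C^CGG, one
base into the four-base site. The cut offset fixes the geometry relating a
sequencing read's 5' end to the recognition occurrence it came from, which
is what cut-site verification depends on.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

__all__ = [
    "IUPAC_CODES",
    "IUPAC_COMPLEMENT",
    "EnzymeSpec",
    "ENZYME_PRESETS",
    "parse_enzyme_spec",
    "get_enzyme",
    "iupac_match",
    "revcomp_iupac",
    "iupac_pattern_regex",
]

# Expansion of each IUPAC nucleotide code into the concrete bases it stands for.
IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "K": "M", "M": "K",
    "S": "S", "W": "W", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}


class EnzymeSpecError(ValueError):
    """Malformed enzyme specification string."""


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction enzyme: recognition sequence plus cut position.

    Attributes
    ----------
    name : str
        Short label, e.g. ``"MspI"`` or the caret spec it was parsed from.
    recognition : str
        Uppercase IUPAC recognition sequence (caret removed).
    cut_offset : int
        Number of bases 5' of the cleavage point on the sense strand
        (the caret index in the caret-annotated spec).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise EnzymeSpecError("recognition sequence must be non-empty")
        bad = set(self.recognition) - set(IUPAC_CODES)
        if bad:
            raise EnzymeSpecError(
                f"non-IUPAC letters in recognition sequence: {sorted(bad)}"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise EnzymeSpecError(
                f"cut_offset {self.cut_offset} outside [0, {len(self.recognition)}]"
            )

    @property
    def length(self) -> int:
        return len(self.recognition)

    @property
    def palindromic(self) -> bool:
        """True when the recognition sequence equals its IUPAC reverse complement."""
        return self.recognition == revcomp_iupac(self.recognition)

    def __str__(self) -> str:  # caret form round-trip
        r = self.recognition
        return f"{r[: self.cut_offset]}^{r[self.cut_offset:]}"


def parse_enzyme_spec(spec: str, name: str | None = None) -> EnzymeSpec:
    """Parse a caret-annotated recognition string such as ``"C^CGG"``.

    The caret marks the cleavage point on the sense strand; everything else
    must be IUPAC letters (case-insensitive).
    """
    s = spec.strip().upper()
    if s.count("^") != 1:
        raise EnzymeSpecError(
            f"enzyme spec {spec!r} must contain exactly one caret '^'"
        )
    cut = s.index("^")
    recognition = s.replace("^", "")
    return EnzymeSpec(name=name or s, recognition=recognition, cut_offset=cut)


# The three enzymes used in published MRE-seq/msGBS work. ApeKI's recognition
# site is usually quoted without a cut mark; the standard cut G^CWGC is used.
ENZYME_PRESETS: dict[str, str] = {
    "MspI": "C^CGG",
    "ApeKI": "G^CWGC",
    "EcoRI": "G^AATTC",
}


def get_enzyme(name_or_spec: str) -> EnzymeSpec:
    """Resolve a preset name (case-insensitive) or a caret spec to an EnzymeSpec."""
    for preset, caret in ENZYME_PRESETS.items():
        if name_or_spec.lower() == preset.lower():
            return parse_enzyme_spec(caret, name=preset)
    return parse_enzyme_spec(name_or_spec)


def _allowed_bases(pattern_letter: str) -> frozenset[str]:
    # A sequence-side 'N' (assembly gap / unknown base) is unverifiable and
    # matches only the fully-degenerate pattern letter 'N'.
    try:
        allowed = IUPAC_CODES[pattern_letter]
    except KeyError:
        raise EnzymeSpecError(f"non-IUPAC pattern letter {pattern_letter!r}")
    if pattern_letter == "N":
        allowed = allowed | {"N"}
    return allowed


def iupac_match(pattern: str, sequence: str) -> bool:
    """True iff ``sequence`` realises the IUPAC ``pattern`` position by position.

    Both inputs must have the same length. Matching is case-insensitive on
    the sequence side (soft-masked lowercase is uppercased). An ``N`` in the
    sequence matches only pattern letter ``N``.
    """
    if len(pattern) != len(sequence):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(sequence)}"
        )
    seq = sequence.upper()
    return all(s in _allowed_bases(p) for p, s in zip(pattern, seq))


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC string (an involution)."""
    try:
        return "".join(IUPAC_COMPLEMENT[c] for c in reversed(pattern.upper()))
    except KeyError as exc:
        raise EnzymeSpecError(f"non-IUPAC letter {exc.args[0]!r}") from None


def iupac_pattern_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC pattern to a regex over uppercase A/C/G/T/N sequence.

    Uses a lookahead group so overlapping occurrences are all found.
    """
    parts = []
    for letter in pattern:
        allowed = "".join(sorted(_allowed_bases(letter)))
        parts.append(allowed if len(allowed) == 1 else f"[{allowed}]")
    return re.compile(f"(?=({''.join(parts)}))")
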