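"""Virtual restriction digestion with IUPAC-degenerate site matching.

Coordinates are 0-based, half-open; a cut is represented by the index of the
first base of the downstream fragment.  Only the given strand is scanned — the
three scheme enzymes (HinfI GANTC, TaqI TCGA, PstI CTGCAG) have palindromic
recognition sites so nothing is lost; a user-supplied non-palindromic enzyme
triggers a warning.  Digestion is modeled as complete (no partial digests).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

from .scheme import IUPAC_CODES, RestrictionEnzyme

__all__ = ["Amplicon", "FragmentPattern", "find_sites", "digest", "double_digest_report"]

#: IUPAC code -> set of concrete bases it stands for.  Ambiguity codes in the
#: *template* never match (conservative): the character classes below contain
#: concrete bases only.
IUPAC_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


@dataclass(frozen=True)
class Amplicon:
    """One PCR product: a locus amplified from one specimen.

    ``enzyme`` optionally names the digest this amplicon is destined for, used
    to distinguish the pk1 TaqI product from the pk1 PstI reflex product.
    """

    specimen_id: str
    locus: str
    sequence: str
    enzyme: str | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"amplicon {self.specimen_id}|{self.locus}: empty sequence")
        _check_alphabet(seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentPattern:
    """Multiset of fragment lengths (bp) from one complete digestion."""

    fragments: tuple

    def __post_init__(self) -> None:
        frags = tuple(sorted((int(f) for f in self.fragments), reverse=True))
        object.__setattr__(self, "fragments", frags)
        if not frags or any(f <= 0 for f in frags):
            raise ValueError("fragments must be a non-empty list of positive lengths")

    @property
    def total(self) -> int:
        return sum(self.fragments)

    def __iter__(self):
        return iter(self.fragments)


def _check_alphabet(sequence: str) -> None:
    for i, c in enumerate(sequence):
        if c not in IUPAC_CODES:
            raise ValueError(f"invalid nucleotide {c!r} at position {i}")


def reverse_complement(pattern: str) -> str:
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def is_palindromic(pattern: str) -> bool:
    """True if the recognition pattern equals its reverse complement."""
    return pattern.upper() == reverse_complement(pattern)


def _pattern_regex(recognition: str) -> re.Pattern:
    # Lookahead so overlapping occurrences are all reported.
    body = "".join(f"[{IUPAC_EXPANSION[c]}]" for c in recognition.upper())
    return re.compile(f"(?=({body}))")


def find_sites(sequence: str, enzyme: RestrictionEnzyme) -> list:
    """0-based start positions of every recognition-site occurrence.

    Pattern ambiguity codes (e.g. the N in GANTC) match any concrete base;
    ambiguity codes in the template never match.
    """
    sequence = sequence.upper()
    _check_alphabet(sequence)
    if not is_palindromic(enzyme.recognition):
        warnings.warn(
            f"enzyme {enzyme.name}: recognition {enzyme.recognition} is not "
            "reverse-complement palindromic; only the given strand is scanned",
            stacklevel=2,
        )
    rx = _pattern_regex(enzyme.recognition)
    return [m.start() for m in rx.finditer(sequence)]


def cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list:
    """Internal cut coordinates (indices of first downstream bases), sorted."""
    n = len(sequence)
    cuts = sorted(
        {p + enzyme.cut_offset for p in find_sites(sequence, enzyme)}
    )
    # A cut at 0 or n does not split a linear molecule.
    return [c for c in cuts if 0 < c < n]


def digest(amplicon: Amplicon | str, enzyme: RestrictionEnzyme) -> FragmentPattern:
    """Fragment pattern of a complete digestion of a linear molecule.

    Fragment lengths partition ``[0, len)`` at the cut coordinates; with no
    site the whole molecule is returned as a single fragment.  Conservation:
    the fragments always sum to the amplicon length.
    """
    seq = amplicon.sequence if isinstance(amplicon, Amplicon) else amplicon.upper()
    cuts = cut_positions(seq, enzyme)
    bounds = [0] + cuts + [len(seq)]
    return FragmentPattern(tuple(b - a for a, b in zip(bounds, bounds[1:])))


def double_digest_report(amplicon: Amplicon, enzymes) -> dict:
    """Independent single-enzyme digests keyed by enzyme name (not combined)."""
    enzymes = list(enzymes)
    if not enzymes:
        raise ValueError("double_digest_report requires at least one enzyme")
    return {e.name: digest(amplicon, e) for e in enzymes}
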