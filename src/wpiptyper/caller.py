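"""Allele calling: fragment pattern -> allele letter, including the pk1 a/e reflex.

A candidate allele matches an observed pattern iff the fragment counts agree
and each observed fragment pairs one-to-one with an expected fragment within
±tolerance bp.  Both lists are sorted descending and paired greedily, which for
equal-length lists of intervals is the optimal one-to-one matching.  The pk1
TaqI table deliberately leaves alleles a and e indistinguishable (identical
903/430 bp patterns); a PstI digest of the same PCR product separates them
(a: 903/303/141, e: 903/430).

Default size tolerance for user-measured gel data is ±5 bp per fragment;
in-silico fragments are exact and are called at tolerance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .digest import Amplicon, FragmentPattern, digest
from .scheme import MISSING, NULL, SchemeError, TypingScheme

__all__ = [
    "CALLED",
    "AMBIGUOUS",
    "NOCALL",
    "DEFAULT_TOLERANCE",
    "LocusCall",
    "MultilocusProfile",
    "call_allele",
    "resolve_pk1_ae",
    "call_specimen",
    "profile_from_letters",
]

CALLED = "CALLED"
AMBIGUOUS = "AMBIGUOUS"
NOCALL = "NOCALL"
# NULL and MISSING statuses are shared with the scheme state sentinels.

DEFAULT_TOLERANCE = 5


@dataclass(frozen=True)
class LocusCall:
    """Outcome of typing one locus of one specimen.

    status is one of CALLED, AMBIGUOUS, NULL, MISSING, NOCALL; ``letters``
    holds the single called letter or the ambiguity set.  ``match_details``
    maps each candidate letter to its maximum per-fragment size deviation (bp).
    """

    specimen_id: str
    locus: str
    status: str
    letters: frozenset = frozenset()
    enzymes: tuple = ()
    match_details: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.status == CALLED and len(self.letters) != 1:
            raise ValueError("CALLED requires exactly one letter")
        if self.status == AMBIGUOUS and len(self.letters) < 2:
            raise ValueError("AMBIGUOUS requires >= 2 letters")
        if self.status in (NULL, MISSING, NOCALL) and self.letters:
            raise ValueError(f"{self.status} carries no letters")

    @property
    def letter(self) -> str:
        if self.status != CALLED:
            raise ValueError(f"no single letter for status {self.status}")
        return next(iter(self.letters))

    @property
    def is_informative(self) -> bool:
        """True when the call can be compared against a catalog state."""
        return self.status in (CALLED, NULL)

    def state_token(self) -> str:
        """TSV token: letter, comma-joined ambiguity set, '-', '.', or 'NOCALL'."""
        if self.status == CALLED:
            return self.letter
        if self.status == AMBIGUOUS:
            return ",".join(sorted(self.letters))
        if self.status == NULL:
            return "-"
        if self.status == MISSING:
            return "."
        return "NOCALL"


@dataclass(frozen=True)
class MultilocusProfile:
    """Per-locus calls for one specimen across the Wolbachia typing loci."""

    specimen_id: str
    calls: Mapping[str, LocusCall]

    def __post_init__(self) -> None:
        for locus in ("ank2", "pk1"):
            if locus not in self.calls:
                raise ValueError(f"profile {self.specimen_id}: missing {locus} call")

    def call(self, locus: str) -> LocusCall:
        return self.calls[locus]


def _greedy_match(observed: tuple, expected: tuple, tolerance: int):
    """Max per-fragment deviation of the descending-sorted pairing, or None."""
    if len(observed) != len(expected):
        return None
    worst = 0
    for o, e in zip(observed, expected):
        d = abs(o - e)
        if d > tolerance:
            return None
        worst = max(worst, d)
    return worst


def call_allele(
    pattern: FragmentPattern,
    locus: str,
    enzyme: str,
    scheme: TypingScheme,
    tolerance: int = 0,
    specimen_id: str = "",
) -> LocusCall:
    """Match an observed fragment pattern against the scheme's allele table.

    Exactly one candidate within tolerance -> CALLED; several -> AMBIGUOUS
    (the designed pk1 TaqI a/e case); none -> NOCALL.
    """
    candidates = scheme.alleles_for(locus, enzyme)
    if not candidates:
        raise SchemeError(f"no allele definitions for ({locus}, {enzyme})")
    details = {}
    for cand in candidates:
        dev = _greedy_match(pattern.fragments, cand.expected_fragments, tolerance)
        if dev is not None:
            details[cand.label] = dev
    if not details:
        return LocusCall(specimen_id, locus, NOCALL, enzymes=(enzyme,))
    if len(details) == 1:
        (letter,) = details
        return LocusCall(
            specimen_id, locus, CALLED, frozenset([letter]), (enzyme,), details
        )
    return LocusCall(
        specimen_id, locus, AMBIGUOUS, frozenset(details), (enzyme,), details
    )


def resolve_pk1_ae(
    pstI_pattern: FragmentPattern,
    scheme: TypingScheme,
    tolerance: int = 0,
    specimen_id: str = "",
) -> LocusCall:
    """Separate the pk1 TaqI a/e ambiguity with the PstI reflex digest."""
    reflex = scheme.reflex_enzyme("pk1") or "PstI"
    return call_allele(
        pstI_pattern, "pk1", reflex, scheme, tolerance, specimen_id=specimen_id
    )


def call_specimen(
    amplicons,
    scheme: TypingScheme,
    tolerance: int = 0,
    null_loci=(),
    sequenced_calls: Mapping[str, str] | None = None,
) -> MultilocusProfile:
    """Type one specimen from its amplicons, chaining digestion and calling.

    ``amplicons`` may cover any subset of RFLP loci; an absent locus is
    MISSING and a locus listed in ``null_loci`` (flagged failed amplification)
    is NULL.  Sequence-defined loci (GP15/MutL/RepA) take their letters from
    ``sequenced_calls`` ('-' for a null allele).  pk1 is resolved through the
    PstI reflex when the TaqI call is ambiguous and a PstI amplicon is present.
    """
    amplicons = list(amplicons)
    specimen_ids = {a.specimen_id for a in amplicons}
    if len(specimen_ids) > 1:
        raise ValueError(f"amplicons from multiple specimens: {sorted(specimen_ids)}")
    specimen_id = specimen_ids.pop() if specimen_ids else ""

    by_key = {}
    for a in amplicons:
        enz = a.enzyme or scheme.primary_enzyme(a.locus)
        key = (a.locus, enz)
        if key in by_key:
            raise ValueError(
                f"duplicate amplicon for specimen {a.specimen_id!r}, "
                f"locus {a.locus!r}, enzyme {enz!r}"
            )
        by_key[key] = a

    calls = {}
    for locus in scheme.rflp_loci():
        primary = scheme.primary_enzyme(locus)
        if locus in null_loci:
            calls[locus] = LocusCall(specimen_id, locus, NULL)
            continue
        amp = by_key.get((locus, primary))
        if amp is None:
            calls[locus] = LocusCall(specimen_id, locus, MISSING)
            continue
        call = call_allele(
            digest(amp, scheme.enzyme(primary)),
            locus,
            primary,
            scheme,
            tolerance,
            specimen_id=specimen_id,
        )
        reflex = scheme.reflex_enzyme(locus)
        if call.status == AMBIGUOUS and reflex and (locus, reflex) in by_key:
            resolved = call_allele(
                digest(by_key[(locus, reflex)], scheme.enzyme(reflex)),
                locus,
                reflex,
                scheme,
                tolerance,
                specimen_id=specimen_id,
            )
            if resolved.status == CALLED and resolved.letters <= call.letters:
                call = LocusCall(
                    specimen_id,
                    locus,
                    CALLED,
                    resolved.letters,
                    (primary, reflex),
                    dict(resolved.match_details),
                )
            elif resolved.status == NOCALL:
                call = LocusCall(specimen_id, locus, NOCALL, enzymes=(primary, reflex))
        calls[locus] = call

    sequenced_calls = sequenced_calls or {}
    for locus in scheme.sequenced_loci():
        if locus in null_loci or sequenced_calls.get(locus) == "-":
            calls[locus] = LocusCall(specimen_id, locus, NULL)
        elif locus in sequenced_calls and sequenced_calls[locus] not in (".", "ND", ""):
            calls[locus] = LocusCall(
                specimen_id, locus, CALLED, frozenset([sequenced_calls[locus]])
            )
        else:
            calls[locus] = LocusCall(specimen_id, locus, MISSING)

    return MultilocusProfile(specimen_id, calls)


def profile_from_letters(
    specimen_id: str, letters: Mapping[str, str | None], scheme: TypingScheme
) -> MultilocusProfile:
    """Build a profile from plain state tokens (letter, '-', '.'/'ND'/None).

    Convenience path for pre-called data (TSV input, catalog rows, cohorts).
    A comma-joined token like ``"a,e"`` becomes an AMBIGUOUS call.
    """
    calls = {}
    for locus in scheme.wolbachia_loci():
        tok = letters.get(locus)
        if tok is None or tok in (".", "ND", ""):
            calls[locus] = LocusCall(specimen_id, locus, MISSING)
        elif tok == "-":
            calls[locus] = LocusCall(specimen_id, locus, NULL)
        elif tok == "NOCALL":
            calls[locus] = LocusCall(specimen_id, locus, NOCALL)
        elif "," in tok:
            calls[locus] = LocusCall(
                specimen_id, locus, AMBIGUOUS, frozenset(tok.split(","))
            )
        else:
            calls[locus] = LocusCall(specimen_id, locus, CALLED, frozenset([tok]))
    return MultilocusProfile(specimen_id, calls)
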