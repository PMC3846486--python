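"""Allele calling: pattern matching, tolerance behavior, the pk1 a/e reflex."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wpiptyper.caller import (
    AMBIGUOUS,
    CALLED,
    NOCALL,
    call_allele,
    call_specimen,
    profile_from_letters,
    resolve_pk1_ae,
)
from wpiptyper.digest import FragmentPattern, digest
from wpiptyper.fixtures import make_amplicon
from wpiptyper.scheme import MISSING, NULL, SchemeError


@pytest.mark.parametrize(
    "fragments,locus,enzyme,expected_status,expected_letters",
    [
        ((217, 195, 98), "ank2", "HinfI", CALLED, {"b"}),
        ((313,), "ank2", "HinfI", CALLED, {"a"}),
        ((903, 430), "pk1", "TaqI", AMBIGUOUS, {"a", "e"}),
        ((669, 665), "pk1", "TaqI", CALLED, {"b"}),
        ((500,), "ank2", "HinfI", NOCALL, set()),
        ((903, 303, 141), "pk1", "PstI", CALLED, {"a"}),
    ],
)
def test_call_allele_examples(scheme, fragments, locus, enzyme, expected_status, expected_letters):
    call = call_allele(FragmentPattern(fragments), locus, enzyme, scheme, tolerance=0)
    assert call.status == expected_status
    assert set(call.letters) == expected_letters


def test_unknown_locus_enzyme_pair_is_a_config_error(scheme):
    with pytest.raises(SchemeError):
        call_allele(FragmentPattern((100,)), "ank2", "TaqI", scheme)


@pytest.mark.parametrize(
    "fragments,expected",
    [((903, 303, 141), "a"), ((903, 430), "e"), ((600, 600), "NOCALL")],
)
def test_resolve_pk1_ae(scheme, fragments, expected):
    call = resolve_pk1_ae(FragmentPattern(fragments), scheme)
    assert call.state_token() == expected


def test_round_trip_every_allele(scheme):
    """digest(fixture(letter)) -> call recovers letter, except TaqI a/e."""
    for defn in scheme.alleles:
        amp = make_amplicon(defn.locus, defn.enzyme, defn.label, scheme, seed=11)
        call = call_allele(
            digest(amp, scheme.enzyme(defn.enzyme)), defn.locus, defn.enzyme, scheme, 0
        )
        if (defn.locus, defn.enzyme) == ("pk1", "TaqI") and defn.label in "ae":
            assert call.status == AMBIGUOUS and call.letters == frozenset("ae")
        else:
            assert call.status == CALLED and call.letter == defn.label


def test_determinism(scheme):
    pattern = FragmentPattern((851, 498))
    calls = [call_allele(pattern, "pk1", "TaqI", scheme, 0) for _ in range(5)]
    assert all(c == calls[0] for c in calls)


@settings(max_examples=60, derandomize=True)
@given(st.integers(min_value=0, max_value=30), st.integers(min_value=0, max_value=30))
def test_tolerance_monotonicity(scheme, tol_lo, tol_hi):
    """The candidate set is non-decreasing in tolerance."""
    tol_lo, tol_hi = sorted((tol_lo, tol_hi))
    pattern = FragmentPattern((300, 210))  # near ank2-c (293, 217)
    lo = call_allele(pattern, "ank2", "HinfI", scheme, tol_lo)
    hi = call_allele(pattern, "ank2", "HinfI", scheme, tol_hi)
    assert set(lo.letters) <= set(hi.letters)


def test_within_tolerance_match(scheme):
    call = call_allele(FragmentPattern((215, 196, 99)), "ank2", "HinfI", scheme, 5)
    assert call.status == CALLED and call.letter == "b"
    assert call.match_details["b"] == 2  # worst per-fragment deviation


def test_call_specimen_full_reflex_chain(scheme):
    amps = [
        make_amplicon("ank2", "HinfI", "a", scheme, 7, specimen_id="sp"),
        make_amplicon("pk1", "TaqI", "a", scheme, 7, specimen_id="sp"),
        make_amplicon("pk1", "PstI", "a", scheme, 7, specimen_id="sp"),
    ]
    prof = call_specimen(amps, scheme)
    assert prof.call("ank2").letter == "a"
    assert prof.call("pk1").letter == "a"
    assert prof.call("pk1").enzymes == ("TaqI", "PstI")


def test_call_specimen_ambiguous_without_reflex(scheme):
    amps = [make_amplicon("pk1", "TaqI", "e", scheme, 7, specimen_id="sp")]
    prof = call_specimen(amps, scheme)
    assert prof.call("pk1").status == AMBIGUOUS
    assert prof.call("ank2").status == MISSING


def test_call_specimen_missing_and_null_states(scheme):
    amps = [make_amplicon("ank2", "HinfI", "c", scheme, 7, specimen_id="sp")]
    prof = call_specimen(amps, scheme, null_loci=("MutL",), sequenced_calls={"GP15": "d"})
    assert prof.call("pk1").status == MISSING
    assert prof.call("MutL").status == NULL
    assert prof.call("GP15").letter == "d"
    assert prof.call("RepA").status == MISSING


def test_duplicate_amplicon_rejected(scheme):
    a = make_amplicon("ank2", "HinfI", "a", scheme, 7, specimen_id="sp")
    with pytest.raises(ValueError, match="duplicate"):
        call_specimen([a, a], scheme)


def test_profile_from_letters_states(scheme):
    prof = profile_from_letters(
        "sp", {"ank2": "a", "pk1": "a,e", "GP15": "-", "MutL": None, "RepA": "ND"}, scheme
    )
    assert prof.call("ank2").status == CALLED
    assert prof.call("pk1").status == AMBIGUOUS
    assert prof.call("GP15").status == NULL
    assert prof.call("MutL").status == MISSING
    assert prof.call("RepA").status == MISSING
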