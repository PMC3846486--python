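"""Virtual digestion: site finding, fragment computation, conservation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wpiptyper.digest import (
    Amplicon,
    FragmentPattern,
    digest,
    double_digest_report,
    find_sites,
    is_palindromic,
)
from wpiptyper.scheme import RestrictionEnzyme

HINFI = RestrictionEnzyme("HinfI", "GANTC", 1)
TAQI = RestrictionEnzyme("TaqI", "TCGA", 1)
PSTI = RestrictionEnzyme("PstI", "CTGCAG", 5)

dna = st.text(alphabet="ACGT", min_size=1, max_size=2000)


def naive_find_sites(sequence, enzyme):
    """Independent O(n*m) sliding-window IUPAC matcher."""
    from wpiptyper.digest import IUPAC_EXPANSION

    pat = enzyme.recognition
    hits = []
    for p in range(len(sequence) - len(pat) + 1):
        if all(sequence[p + k] in IUPAC_EXPANSION[pat[k]] for k in range(len(pat))):
            hits.append(p)
    return hits


@pytest.mark.parametrize(
    "sequence,enzyme,expected",
    [
        ("AAGACTCAA", HINFI, [2]),
        ("AAAAAA", TAQI, []),
        ("TCGATCGA", TAQI, [0, 4]),
        ("CTGCAGG", PSTI, [0]),
        ("GACTC", HINFI, [0]),
    ],
)
def test_find_sites_examples(sequence, enzyme, expected):
    assert find_sites(sequence, enzyme) == expected


def test_template_ambiguity_codes_never_match():
    # GANTC would match were the template N treated as a wildcard
    assert find_sites("GANTC", HINFI) == []


def test_invalid_character_names_position():
    with pytest.raises(ValueError, match="position 3"):
        find_sites("ACGXT", TAQI)


@settings(max_examples=200, derandomize=True)
@given(dna, st.sampled_from([HINFI, TAQI, PSTI]))
def test_sites_match_naive_oracle(sequence, enzyme):
    assert find_sites(sequence, enzyme) == naive_find_sites(sequence, enzyme)


@settings(max_examples=200, derandomize=True)
@given(dna, st.sampled_from([HINFI, TAQI, PSTI]))
def test_fragment_conservation(sequence, enzyme):
    pattern = digest(sequence, enzyme)
    assert pattern.total == len(sequence)
    assert all(f > 0 for f in pattern.fragments)


@settings(max_examples=100, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=8, max_size=500))
def test_adding_a_site_never_decreases_fragment_count(sequence):
    before = len(digest(sequence, TAQI).fragments)
    # splice a concrete TCGA site into the middle
    mid = len(sequence) // 2
    spliced = sequence[:mid] + "TCGA" + sequence[mid:]
    after = len(digest(spliced, TAQI).fragments)
    assert after >= before


@settings(max_examples=100, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=6, max_size=800))
def test_fragments_agree_with_biopython_catalyse(sequence):
    """Independent oracle: Biopython's restriction machinery."""
    from Bio import Restriction
    from Bio.Seq import Seq

    for mine, ref in (
        (HINFI, Restriction.HinfI),
        (TAQI, Restriction.TaqI),
        (PSTI, Restriction.PstI),
    ):
        got = sorted(digest(sequence, mine).fragments)
        expected = sorted(len(f) for f in ref.catalyse(Seq(sequence))) or [len(sequence)]
        assert got == expected


def test_one_internal_cut_gives_two_fragments():
    seq = "A" * 50 + "TCGA" + "G" * 50
    pattern = digest(seq, TAQI)
    assert len(pattern.fragments) == 2
    assert pattern.total == len(seq)


def test_no_site_gives_full_length_single_fragment():
    assert tuple(digest("ACGT" * 25, HINFI)) == (100,)


def test_double_digest_is_independent_not_combined(scheme):
    from wpiptyper.fixtures import make_amplicon

    amp = make_amplicon("pk1", "PstI", "e", scheme, seed=1)
    report = double_digest_report(amp, [TAQI, PSTI])
    assert tuple(report["PstI"]) == (903, 430)
    # single enzyme behaves exactly like digest
    assert double_digest_report(amp, [PSTI])["PstI"] == digest(amp, PSTI)


def test_double_digest_requires_an_enzyme(scheme):
    amp = Amplicon("s", "pk1", "ACGT")
    with pytest.raises(ValueError):
        double_digest_report(amp, [])


def test_nonpalindromic_enzyme_warns():
    odd = RestrictionEnzyme("odd", "GACGC", 1)
    assert not is_palindromic(odd.recognition)
    with pytest.warns(UserWarning, match="palindromic"):
        find_sites("AAAA", odd)


def test_fragment_pattern_invariants():
    p = FragmentPattern((98, 217, 195))
    assert p.fragments == (217, 195, 98)  # stored sorted descending
    assert p.total == 510
    with pytest.raises(ValueError):
        FragmentPattern(())
    with pytest.raises(ValueError):
        FragmentPattern((10, 0))


def test_amplicon_rejects_empty_and_bad_alphabet():
    with pytest.raises(ValueError):
        Amplicon("s", "ank2", "")
    with pytest.raises(ValueError):
        Amplicon("s", "ank2", "ACGU")
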