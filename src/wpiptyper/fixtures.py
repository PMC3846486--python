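"""Synthetic-data generation: amplicons that digest to the published fragment
tables, and specimen cohorts reproducing the published count structure.

Amplicons are built by inverting a fragment table: recognition-site instances
are placed so that the cut coordinates fall exactly at the cumulative fragment
boundaries (fragments taken in the order printed in the scheme), degenerate
pattern positions and the background are filled with seeded random bases, and
any background window that accidentally matches the digesting enzyme's pattern
is resampled away.  Fixtures are generated per (allele, enzyme) pair, not per
allele: the pk1 allele-a TaqI and PstI fragment sums disagree (1333 vs 1347 bp)
so no single sequence can satisfy both tables.

Cohorts replicate, specimen by specimen, the per-haplotype counts of the
multilocus typing survey (1935 specimens), the wPip x mtDNA partition (184),
the wPip x host-taxon partition (409) and the cytb x host-taxon partition
(166).  They are exact reconstructions of published contingency structure,
not resamples: regenerating with any seed changes specimen ids' random
suffixes only, never a count.
"""

from __future__ import annotations

import zlib

import numpy as np

from .caller import MultilocusProfile, profile_from_letters
from .digest import IUPAC_EXPANSION, Amplicon, digest
from .scheme import MISSING, NULL, TypingScheme, format_state

__all__ = [
    "make_amplicon",
    "make_cohort",
    "make_mtdna_cohort",
    "cohort_profiles",
    "TABLE2_COUNTS",
    "TABLE3_COUNTS",
    "TABLE4_COUNTS",
]

_BASES = np.array(list("ACGT"))


class FixtureError(ValueError):
    """Raised when a fixture cannot be constructed from the requested spec."""


# ---------------------------------------------------------------------------
# amplicon synthesis

def _fill_pattern(recognition: str, rng) -> str:
    return "".join(
        c if c in "ACGT" else rng.choice(list(IUPAC_EXPANSION[c])) for c in recognition
    )


def make_amplicon(
    locus: str,
    enzyme_name: str,
    allele: str,
    scheme: TypingScheme,
    seed: int,
    specimen_id: str | None = None,
) -> Amplicon:
    """Synthesize an amplicon whose digestion reproduces the allele's fragments.

    Deterministic in *seed*.  Raises :class:`FixtureError` when a fragment is
    too short to accommodate the recognition-site placement.
    """
    defs = scheme.alleles_for(locus, enzyme_name)
    table = next((a for a in defs if a.label == allele), None)
    if table is None:
        raise FixtureError(
            f"no fragment table for ({locus}, {enzyme_name}, {allele})"
        )
    enzyme = scheme.enzyme(enzyme_name)
    # Stable per-target stream: crc32 is process-independent, unlike hash().
    target_key = zlib.crc32(f"{locus}|{enzyme_name}|{allele}".encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([seed, target_key]))
    # Canonical order: as stored in the scheme (descending — the printed order
    # for every bundled table).
    frags = table.expected_fragments
    length = sum(frags)
    cuts = list(np.cumsum(frags)[:-1])
    m = len(enzyme.recognition)
    for cut in cuts:
        if cut - enzyme.cut_offset < 0 or cut - enzyme.cut_offset + m > length:
            raise FixtureError(
                f"fragment boundary {cut} cannot host the {enzyme.name} site"
            )

    for _attempt in range(200):
        seq = rng.choice(_BASES, size=length)
        intended_starts = []
        for cut in cuts:
            start = cut - enzyme.cut_offset
            inst = _fill_pattern(enzyme.recognition, rng)
            seq[start : start + m] = list(inst)
            intended_starts.append(start)
        protected = np.zeros(length, dtype=bool)
        for s in intended_starts:
            protected[s : s + m] = True

        ok = _scrub_accidental_sites(seq, enzyme, set(intended_starts), protected, rng)
        if not ok:
            continue
        sequence = "".join(seq)
        amp = Amplicon(
            specimen_id=specimen_id or f"fixture-{locus}-{allele}-{enzyme_name}",
            locus=locus,
            sequence=sequence,
            enzyme=enzyme_name,
        )
        if tuple(digest(amp, enzyme)) == frags:
            return amp
    raise FixtureError(
        f"could not synthesize ({locus}, {enzyme_name}, {allele}) without "
        "spurious sites"
    )


def _scrub_accidental_sites(seq, enzyme, intended, protected, rng, max_rounds=50):
    from .digest import find_sites  # local import to avoid cycle at module load

    m = len(enzyme.recognition)
    for _ in range(max_rounds):
        sites = [p for p in find_sites("".join(seq), enzyme) if p not in intended]
        if not sites:
            return True
        for p in sites:
            free = [q for q in range(p, p + m) if not protected[q]]
            if not free:
                return False  # accidental site inside protected span: resample
            q = int(rng.choice(free))
            current = seq[q]
            choices = [b for b in "ACGT" if b != current]
            seq[q] = rng.choice(choices)
    return False


# ---------------------------------------------------------------------------
# published count structure

# wPip x mtDNA partition: rows cytb haplotypes #1..#11, columns wPip groups.
TABLE2_COUNTS = {
    "#1":  {"I": 1,  "II": 0,  "III": 0,  "IV": 0,  "V": 0, "undetermined": 0},
    "#2":  {"I": 43, "II": 0,  "III": 0,  "IV": 0,  "V": 7, "undetermined": 0},
    "#3":  {"I": 3,  "II": 0,  "III": 0,  "IV": 0,  "V": 0, "undetermined": 0},
    "#4":  {"I": 18, "II": 0,  "III": 0,  "IV": 0,  "V": 0, "undetermined": 0},
    "#5":  {"I": 0,  "II": 39, "III": 3,  "IV": 0,  "V": 0, "undetermined": 1},
    "#6":  {"I": 0,  "II": 1,  "III": 41, "IV": 0,  "V": 0, "undetermined": 1},
    "#7":  {"I": 0,  "II": 0,  "III": 3,  "IV": 0,  "V": 0, "undetermined": 0},
    "#8":  {"I": 1,  "II": 0,  "III": 0,  "IV": 4,  "V": 0, "undetermined": 0},
    "#9":  {"I": 0,  "II": 0,  "III": 0,  "IV": 16, "V": 0, "undetermined": 0},
    "#10": {"I": 0,  "II": 0,  "III": 0,  "IV": 0,  "V": 1, "undetermined": 0},
    "#11": {"I": 0,  "II": 0,  "III": 0,  "IV": 0,  "V": 1, "undetermined": 0},
}

# wPip x host-taxon partition (409 specimens).
TABLE3_COUNTS = {
    "I":   {"quinquefasciatus": 133, "pipiens": 16, "molestus": 20, "pallens": 0,  "hybrid": 2},
    "II":  {"quinquefasciatus": 0,   "pipiens": 55, "molestus": 7,  "pallens": 0,  "hybrid": 0},
    "III": {"quinquefasciatus": 46,  "pipiens": 30, "molestus": 20, "pallens": 0,  "hybrid": 0},
    "IV":  {"quinquefasciatus": 0,   "pipiens": 15, "molestus": 15, "pallens": 1,  "hybrid": 0},
    "V":   {"quinquefasciatus": 21,  "pipiens": 2,  "molestus": 1,  "pallens": 19, "hybrid": 4},
    "undetermined": {"quinquefasciatus": 0, "pipiens": 1, "molestus": 1, "pallens": 0, "hybrid": 0},
}

# cytb haplotype x host-taxon partition (166 specimens, hybrids excluded).
TABLE4_COUNTS = {
    "#1":  {"quinquefasciatus": 1,  "pipiens": 0,  "molestus": 0, "pallens": 0},
    "#2":  {"quinquefasciatus": 43, "pipiens": 4,  "molestus": 0, "pallens": 1},
    "#3":  {"quinquefasciatus": 10, "pipiens": 3,  "molestus": 5, "pallens": 0},
    "#4":  {"quinquefasciatus": 5,  "pipiens": 0,  "molestus": 0, "pallens": 0},
    "#5":  {"quinquefasciatus": 0,  "pipiens": 35, "molestus": 3, "pallens": 0},
    "#6":  {"quinquefasciatus": 10, "pipiens": 19, "molestus": 6, "pallens": 0},
    "#7":  {"quinquefasciatus": 1,  "pipiens": 1,  "molestus": 0, "pallens": 0},
    "#8":  {"quinquefasciatus": 0,  "pipiens": 1,  "molestus": 4, "pallens": 0},
    "#9":  {"quinquefasciatus": 0,  "pipiens": 4,  "molestus": 7, "pallens": 1},
    "#10": {"quinquefasciatus": 1,  "pipiens": 0,  "molestus": 0, "pallens": 0},
    "#11": {"quinquefasciatus": 1,  "pipiens": 0,  "molestus": 0, "pallens": 0},
}

_HAP_TO_MTDNA = {
    "#1": "mtDNA-1", "#2": "mtDNA-1", "#3": "mtDNA-1", "#4": "mtDNA-1",
    "#5": "mtDNA-2", "#6": "mtDNA-3", "#7": "mtDNA-3",
    "#8": "mtDNA-4", "#9": "mtDNA-4", "#10": "mtDNA-5", "#11": "mtDNA-5",
}


def _state_token(state) -> str | None:
    """Catalog state -> concrete specimen token (first letter of a set)."""
    if state == NULL:
        return "-"
    if state == MISSING:
        return None
    return sorted(state)[0]


def make_cohort(name: str, scheme: TypingScheme, seed: int) -> list:
    """Reconstruct a published cohort as a list of specimen records.

    ``table1`` gives 1935 specimens carrying multilocus profile letters (one
    record per catalog haplotype occurrence, multi-letter catalog states
    collapsed to their first letter); ``table2``/``table3``/``table4`` give
    annotation-only records replicating those tables' cells exactly.  Specimen
    ids are deterministic in *seed*.
    """
    from .association import SpecimenRecord  # late import: association is downstream

    rng = np.random.default_rng(seed)
    tag = rng.integers(0, 10**6)
    records = []

    def sid(prefix, k):
        return f"{prefix}-{tag:06d}-{k:05d}"

    if name == "table1":
        k = 0
        for rec in scheme.catalog:
            for _ in range(rec.n):
                k += 1
                records.append(
                    SpecimenRecord(
                        specimen_id=sid("t1", k),
                        population_id=f"pop{rng.integers(1, 183):03d}",
                        ank2=_state_token(rec.state("ank2")),
                        pk1=_state_token(rec.state("pk1")),
                        gp15=_state_token(rec.state("GP15")),
                        mutl=_state_token(rec.state("MutL")),
                        repa=_state_token(rec.state("RepA")),
                        wpip_haplotype=rec.haplotype_id,  # ground-truth label
                    )
                )
        return records
    if name == "table2":
        k = 0
        for hap, row in TABLE2_COUNTS.items():
            for group, n in row.items():
                for _ in range(n):
                    k += 1
                    records.append(
                        SpecimenRecord(
                            specimen_id=sid("t2", k),
                            mtdna_haplotype=hap,
                            mtdna_group=_HAP_TO_MTDNA[hap],
                            wpip_group=group,
                        )
                    )
        return records
    if name == "table3":
        k = 0
        for group, row in TABLE3_COUNTS.items():
            for taxon, n in row.items():
                for _ in range(n):
                    k += 1
                    records.append(
                        SpecimenRecord(
                            specimen_id=sid("t3", k), wpip_group=group, taxon=taxon
                        )
                    )
        return records
    if name == "table4":
        k = 0
        for hap, row in TABLE4_COUNTS.items():
            for taxon, n in row.items():
                for _ in range(n):
                    k += 1
                    records.append(
                        SpecimenRecord(
                            specimen_id=sid("t4", k),
                            mtdna_haplotype=hap,
                            mtdna_group=_HAP_TO_MTDNA[hap],
                            taxon=taxon,
                        )
                    )
        return records
    raise FixtureError(f"unknown cohort {name!r}")


def cohort_profiles(records, scheme: TypingScheme) -> list:
    """Multilocus profiles for table1-style records (letters -> LocusCalls)."""
    out = []
    for rec in records:
        out.append(
            profile_from_letters(
                rec.specimen_id,
                {
                    "ank2": rec.ank2,
                    "pk1": rec.pk1,
                    "GP15": rec.gp15,
                    "MutL": rec.mutl,
                    "RepA": rec.repa,
                },
                scheme,
            )
        )
    return out


# ---------------------------------------------------------------------------
# mtDNA cohort

def make_mtdna_cohort(
    n_haplotypes: int,
    n_variable_sites: int,
    length: int,
    counts,
    seed: int,
) -> list:
    """Aligned sequences collapsing to exactly the requested haplotype structure.

    A random reference is drawn; haplotypes 2..k each differ from it at one
    dedicated variable column, and any further variable columns are assigned
    round-robin as extra private mutations, so exactly ``n_variable_sites``
    columns vary and exactly ``n_haplotypes`` distinct sequences exist.
    Returns ``[(name, sequence), ...]`` with ``counts[i]`` copies of
    haplotype i.  Deterministic in *seed*.
    """
    counts = list(counts)
    if len(counts) != n_haplotypes:
        raise FixtureError("counts length must equal n_haplotypes")
    if any(c < 1 for c in counts):
        raise FixtureError("every haplotype needs a positive count")
    if n_haplotypes > 1 and n_variable_sites < n_haplotypes - 1:
        raise FixtureError("need at least n_haplotypes - 1 variable sites")
    if n_haplotypes == 1 and n_variable_sites != 0:
        raise FixtureError("a single haplotype cannot produce variable sites")
    if n_variable_sites > length:
        raise FixtureError("more variable sites than positions")

    rng = np.random.default_rng(seed)
    ref = rng.choice(_BASES, size=length)
    var_cols = rng.choice(length, size=n_variable_sites, replace=False)

    haps = [ref.copy() for _ in range(n_haplotypes)]

    def mutate(hap, col):
        current = hap[col]
        hap[col] = rng.choice([b for b in "ACGT" if b != current])

    for i in range(1, n_haplotypes):
        mutate(haps[i], var_cols[i - 1])
    for extra_idx in range(n_haplotypes - 1, n_variable_sites):
        target = 1 + (extra_idx - (n_haplotypes - 1)) % max(1, n_haplotypes - 1)
        mutate(haps[target], var_cols[extra_idx])

    out = []
    for i, (hap, c) in enumerate(zip(haps, counts), start=1):
        s = "".join(hap)
        for j in range(c):
            out.append((f"hap{i:02d}_seq{j + 1:03d}", s))
    return out
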