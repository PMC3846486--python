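"""Typing-scheme model: enzymes, loci, allele fragment tables and the haplotype catalog.

A :class:`TypingScheme` is pure data.  The bundled default scheme encodes the
five-group wPip PCR-RFLP assay used across the *Culex pipiens* complex:
HinfI digestion of *ank2* (alleles a-e), TaqI digestion of *pk1* (a/e, b, c, d,
with a PstI reflex digest separating a from e), sequence-defined allele labels
for *GP15*, *MutL* and *RepA*, and the catalog mapping multilocus profiles to
wPip groups I-V.  Catalog states distinguish a null allele (``-``, no
amplification: informative) from a not-determined locus (``ND``: never
compared).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "NULL",
    "MISSING",
    "IUPAC_CODES",
    "WPIP_GROUPS",
    "RestrictionEnzyme",
    "Locus",
    "AlleleDefinition",
    "HaplotypeRecord",
    "TypingScheme",
    "SchemeError",
    "SchemeViolation",
    "parse_state",
    "format_state",
    "load_scheme",
    "dump_scheme",
    "validate_scheme",
    "derive_congruent_pairs",
]

#: Sentinel for a null allele: locus failed to amplify (primer-site mutation or
#: deletion).  Informative — it matches a catalog "-" and mismatches a letter.
NULL = "NULL"
#: Sentinel for a not-determined locus.  Never matches nor mismatches.
MISSING = "MISSING"

#: Allele state as stored in a catalog profile: a set of acceptable letters,
#: or one of the sentinels above.
AlleleState = Union[frozenset, str]

IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

WPIP_GROUPS = ("I", "II", "III", "IV", "V")

MARKER_CLASSES = ("wolbachia_rflp", "wolbachia_sequenced", "mitochondrial")


class SchemeError(ValueError):
    """Raised when a scheme config cannot be parsed or is structurally invalid."""


@dataclass(frozen=True)
class SchemeViolation:
    """One invariant violation found by :func:`validate_scheme`."""

    record: str
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.record}] {self.rule}: {self.message}"


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction endonuclease, defined by its IUPAC recognition pattern.

    ``cut_offset`` is the number of bases from the pattern start to the cut on
    the given strand, e.g. HinfI G^ANTC has offset 1.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.name:
            raise SchemeError("enzyme name must be non-empty")
        if not self.recognition or any(c not in IUPAC_CODES for c in self.recognition):
            raise SchemeError(
                f"enzyme {self.name!r}: recognition {self.recognition!r} "
                "must be a non-empty IUPAC nucleotide pattern"
            )
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise SchemeError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside "
                f"0..{len(self.recognition)}"
            )


@dataclass(frozen=True)
class Locus:
    name: str
    marker_class: str
    copy_number: int = 1

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise SchemeError(
                f"locus {self.name!r}: unknown marker_class {self.marker_class!r}"
            )
        if self.copy_number < 1:
            raise SchemeError(f"locus {self.name!r}: copy_number must be positive")


@dataclass(frozen=True)
class AlleleDefinition:
    """Expected fragment sizes (bp) for one allele under one enzyme."""

    locus: str
    enzyme: str
    label: str
    expected_fragments: tuple

    def __post_init__(self) -> None:
        frags = tuple(sorted((int(f) for f in self.expected_fragments), reverse=True))
        object.__setattr__(self, "expected_fragments", frags)
        if not frags or any(f <= 0 for f in frags):
            raise SchemeError(
                f"allele ({self.locus},{self.enzyme},{self.label}): "
                "fragments must be a non-empty list of positive integers"
            )


@dataclass(frozen=True)
class HaplotypeRecord:
    """One catalog row: a multilocus allelic profile and its wPip group."""

    haplotype_id: str
    group: str
    profile: Mapping[str, AlleleState]
    n: int = 0
    populations: str = ""
    synthetic_profile: bool = False

    def state(self, locus: str) -> AlleleState:
        return self.profile.get(locus, MISSING)


@dataclass(frozen=True)
class TypingScheme:
    name: str
    enzymes: tuple
    loci: tuple
    alleles: tuple
    catalog: tuple
    congruent_pairs: Mapping[tuple, str]
    assays: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    description: str = ""

    # -- lookups -------------------------------------------------------------
    def enzyme(self, name: str) -> RestrictionEnzyme:
        for e in self.enzymes:
            if e.name == name:
                return e
        raise SchemeError(f"unknown enzyme {name!r}")

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise SchemeError(f"unknown locus {name!r}")

    def alleles_for(self, locus: str, enzyme: str) -> tuple:
        return tuple(
            a for a in self.alleles if a.locus == locus and a.enzyme == enzyme
        )

    def rflp_loci(self) -> tuple:
        return tuple(l.name for l in self.loci if l.marker_class == "wolbachia_rflp")

    def sequenced_loci(self) -> tuple:
        return tuple(
            l.name for l in self.loci if l.marker_class == "wolbachia_sequenced"
        )

    def wolbachia_loci(self) -> tuple:
        return self.rflp_loci() + self.sequenced_loci()

    def primary_enzyme(self, locus: str) -> str:
        try:
            return self.assays[locus]["enzyme"]
        except KeyError as exc:
            raise SchemeError(f"no assay enzyme configured for locus {locus!r}") from exc

    def reflex_enzyme(self, locus: str):
        return self.assays.get(locus, {}).get("reflex_enzyme")


# ---------------------------------------------------------------------------
# state parsing

def parse_state(token: str) -> AlleleState:
    """Parse a catalog/profile state token.

    ``"-"`` -> NULL, ``"ND"``/``"."``/empty -> MISSING, otherwise a
    comma-separated set of allele labels (``"a,b"`` matches either letter).
    """
    token = token.strip()
    if token == "-":
        return NULL
    if token in ("ND", ".", ""):
        return MISSING
    letters = frozenset(t.strip() for t in token.split(",") if t.strip())
    if not letters:
        raise SchemeError(f"unparseable allele state {token!r}")
    return letters


def format_state(state: AlleleState) -> str:
    if state == NULL:
        return "-"
    if state == MISSING:
        return "ND"
    return ",".join(sorted(state))


# ---------------------------------------------------------------------------
# load / dump

def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise SchemeError(f"{where}: missing required field {key!r}")
    return mapping[key]


def load_scheme(path=None) -> "TypingScheme":
    """Load a typing scheme from a JSON config; ``None`` loads the bundled default.

    Raises :class:`SchemeError` naming the offending record on malformed input,
    and re-checks all structural invariants via :func:`validate_scheme`.
    """
    if path is None:
        text = (
            resources.files("wpiptyper").joinpath("data/default_scheme.json").read_text()
        )
    else:
        text = Path(path).read_text()
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SchemeError(f"scheme config is not valid JSON: {exc}") from exc

    enzymes = tuple(
        RestrictionEnzyme(
            name=_require(e, "name", "enzyme"),
            recognition=_require(e, "recognition", f"enzyme {e.get('name')!r}"),
            cut_offset=int(_require(e, "cut_offset", f"enzyme {e.get('name')!r}")),
        )
        for e in _require(raw, "enzymes", "scheme")
    )
    loci = tuple(
        Locus(
            name=_require(l, "name", "locus"),
            marker_class=_require(l, "marker_class", f"locus {l.get('name')!r}"),
            copy_number=int(l.get("copy_number", 1)),
        )
        for l in _require(raw, "loci", "scheme")
    )
    alleles = tuple(
        AlleleDefinition(
            locus=_require(a, "locus", "allele"),
            enzyme=_require(a, "enzyme", "allele"),
            label=_require(a, "label", "allele"),
            expected_fragments=tuple(
                _require(a, "expected_fragments", f"allele {a.get('label')!r}")
            ),
        )
        for a in _require(raw, "alleles", "scheme")
    )
    catalog = tuple(
        HaplotypeRecord(
            haplotype_id=_require(h, "haplotype_id", "catalog row"),
            group=_require(h, "group", f"haplotype {h.get('haplotype_id')!r}"),
            profile={
                locus: parse_state(tok)
                for locus, tok in _require(
                    h, "profile", f"haplotype {h.get('haplotype_id')!r}"
                ).items()
            },
            n=int(h.get("n", 0)),
            populations=h.get("populations", ""),
            synthetic_profile=bool(h.get("synthetic_profile", False)),
        )
        for h in _require(raw, "catalog", "scheme")
    )
    congruent_pairs = {}
    for key, group in _require(raw, "congruent_pairs", "scheme").items():
        parts = tuple(p.strip() for p in key.split(","))
        if len(parts) != 2:
            raise SchemeError(f"congruent_pairs key {key!r} is not 'ank2,pk1'")
        congruent_pairs[parts] = group

    scheme = TypingScheme(
        name=raw.get("name", "unnamed"),
        enzymes=enzymes,
        loci=loci,
        alleles=alleles,
        catalog=catalog,
        congruent_pairs=congruent_pairs,
        assays=raw.get("assays", {}),
        description=raw.get("description", ""),
    )
    violations = validate_scheme(scheme)
    if violations:
        raise SchemeError(
            "invalid scheme: " + "; ".join(str(v) for v in violations[:10])
        )
    return scheme


def dump_scheme(scheme: TypingScheme, path) -> None:
    """Write a scheme back to JSON (inverse of :func:`load_scheme`)."""
    raw = {
        "format_version": 1,
        "name": scheme.name,
        "description": scheme.description,
        "enzymes": [
            {"name": e.name, "recognition": e.recognition, "cut_offset": e.cut_offset}
            for e in scheme.enzymes
        ],
        "loci": [
            {"name": l.name, "marker_class": l.marker_class, "copy_number": l.copy_number}
            for l in scheme.loci
        ],
        "assays": {k: dict(v) for k, v in scheme.assays.items()},
        "alleles": [
            {
                "locus": a.locus,
                "enzyme": a.enzyme,
                "label": a.label,
                "expected_fragments": list(a.expected_fragments),
            }
            for a in scheme.alleles
        ],
        "catalog": [
            {
                "haplotype_id": h.haplotype_id,
                "group": h.group,
                "n": h.n,
                "profile": {loc: format_state(s) for loc, s in h.profile.items()},
                "populations": h.populations,
                **({"synthetic_profile": True} if h.synthetic_profile else {}),
            }
            for h in scheme.catalog
        ],
        "congruent_pairs": {
            f"{a},{p}": g for (a, p), g in scheme.congruent_pairs.items()
        },
    }
    Path(path).write_text(json.dumps(raw, indent=2) + "\n")


# ---------------------------------------------------------------------------
# validation

def derive_congruent_pairs(catalog: Iterable[HaplotypeRecord]) -> dict:
    """Re-derive the congruent (ank2, pk1) -> group map from known-haplotype rows.

    Known rows are the catalog entries whose id starts with ``known``; their
    ank2/pk1 states are single letters by construction.
    """
    pairs = {}
    for rec in catalog:
        if not rec.haplotype_id.startswith("known"):
            continue
        a, p = rec.state("ank2"), rec.state("pk1")
        if isinstance(a, frozenset) and isinstance(p, frozenset) and len(a) == len(p) == 1:
            pairs[(next(iter(a)), next(iter(p)))] = rec.group
    return pairs


def validate_scheme(scheme: TypingScheme) -> list:
    """Check every structural invariant; violations are data, not exceptions."""
    out = []

    def bad(record, rule, message):
        out.append(SchemeViolation(record, rule, message))

    enzyme_names = {e.name for e in scheme.enzymes}
    locus_names = {l.name for l in scheme.loci}

    seen = set()
    for a in scheme.alleles:
        key = (a.locus, a.enzyme, a.label)
        if key in seen:
            bad(f"allele {key}", "unique-allele", "duplicate (locus, enzyme, label)")
        seen.add(key)
        if a.locus not in locus_names:
            bad(f"allele {key}", "known-locus", f"locus {a.locus!r} not declared")
        if a.enzyme not in enzyme_names:
            bad(f"allele {key}", "known-enzyme", f"enzyme {a.enzyme!r} not declared")

    for l in scheme.loci:
        if l.name in ("ank2", "pk1") and l.marker_class != "wolbachia_rflp":
            bad(f"locus {l.name}", "marker-class", "ank2/pk1 must be wolbachia_rflp")
        if l.name in ("MutL", "GP15", "RepA") and l.marker_class != "wolbachia_sequenced":
            bad(f"locus {l.name}", "marker-class", "must be wolbachia_sequenced")
        if l.name == "pk1" and l.copy_number != 3:
            bad("locus pk1", "copy-number", "pk1 is present in three identical copies")
        if (
            l.marker_class in ("wolbachia_rflp", "wolbachia_sequenced")
            and l.name != "pk1"
            and l.copy_number != 1
        ):
            bad(f"locus {l.name}", "copy-number", "single-copy locus")

    seen_h = set()
    for h in scheme.catalog:
        if h.haplotype_id in seen_h:
            bad(f"haplotype {h.haplotype_id}", "unique-haplotype", "duplicate id")
        seen_h.add(h.haplotype_id)
        if h.group not in WPIP_GROUPS + ("undetermined",):
            bad(f"haplotype {h.haplotype_id}", "group", f"unknown group {h.group!r}")
        if h.haplotype_id in ("#29", "#30") and h.group != "undetermined":
            bad(f"haplotype {h.haplotype_id}", "group", "must be undetermined")
        for locus in ("ank2", "pk1"):
            s = h.state(locus)
            if not (isinstance(s, frozenset) and len(s) == 1):
                bad(
                    f"haplotype {h.haplotype_id}",
                    "rflp-single-letter",
                    f"{locus} state must be a single letter, got {format_state(s)!r}",
                )
        for locus in h.profile:
            if locus not in locus_names:
                bad(
                    f"haplotype {h.haplotype_id}",
                    "known-locus",
                    f"profile locus {locus!r} not declared",
                )

    derived = derive_congruent_pairs(scheme.catalog)
    if derived and dict(scheme.congruent_pairs) != derived:
        bad(
            "congruent_pairs",
            "catalog-consistency",
            f"declared {dict(scheme.congruent_pairs)!r} != derived-from-catalog {derived!r}",
        )

    for locus, assay in scheme.assays.items():
        for enz in assay.values():
            if enz not in enzyme_names:
                bad(f"assay {locus}", "known-enzyme", f"enzyme {enz!r} not declared")

    return out


def with_catalog(scheme: TypingScheme, catalog) -> TypingScheme:
    """Return a copy of *scheme* with a replaced catalog (testing helper)."""
    return replace(scheme, catalog=tuple(catalog))
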