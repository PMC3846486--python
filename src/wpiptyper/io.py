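"""Readers and writers for the pipeline's text formats.

FASTA record ids use the dialect ``specimenID|locus`` with an optional third
field naming the destination digest (``specimenID|pk1|PstI`` for the reflex
product).  All tabular files are UTF-8, tab-separated, with a header row and
``.`` for missing values.
"""

from __future__ import annotations

import csv
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .association import SpecimenRecord
from .caller import LocusCall, MultilocusProfile, profile_from_letters
from .digest import Amplicon, FragmentPattern

__all__ = [
    "read_amplicon_fasta",
    "write_fasta",
    "read_fragment_tsv",
    "write_fragment_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "read_specimen_tsv",
    "write_specimen_tsv",
    "write_assignments_tsv",
]

MISSING_TOKEN = "."


class InputError(ValueError):
    """Malformed user input (bad record id, bad column, bad value)."""


def read_amplicon_fasta(path) -> list:
    """Parse amplicons from FASTA; ids must be ``specimen|locus[|enzyme]``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise InputError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        parts = rec.id.split("|")
        if len(parts) not in (2, 3) or not all(parts):
            raise InputError(
                f"{path}: record id {rec.id!r} is not 'specimenID|locus' "
                "or 'specimenID|locus|enzyme'"
            )
        specimen, locus = parts[0], parts[1]
        enzyme = parts[2] if len(parts) == 3 else None
        try:
            out.append(Amplicon(specimen, locus, str(rec.seq), enzyme))
        except ValueError as exc:
            raise InputError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def write_fasta(amplicons_or_pairs, path) -> None:
    """Write amplicons (or (name, sequence) pairs) to FASTA."""
    records = []
    for item in amplicons_or_pairs:
        if isinstance(item, Amplicon):
            rid = f"{item.specimen_id}|{item.locus}"
            if item.enzyme:
                rid += f"|{item.enzyme}"
            records.append(SeqRecord(Seq(item.sequence), id=rid, description=""))
        else:
            name, seq = item
            records.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(records, str(path), "fasta")


def _read_tsv(path) -> list:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise InputError(f"{path}: empty file")
        return [row for row in reader]


def _write_tsv(path, fieldnames, rows) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_fragment_tsv(path) -> list:
    """Pre-measured fragment patterns: specimen, locus, enzyme, fragments.

    ``fragments`` is comma-joined bp sizes.  Returns
    ``[(specimen, locus, enzyme, FragmentPattern), ...]``.
    """
    out = []
    for i, row in enumerate(_read_tsv(path), start=2):
        try:
            frags = tuple(int(x) for x in row["fragments"].split(","))
            out.append(
                (
                    row["specimen"],
                    row["locus"],
                    row["enzyme"],
                    FragmentPattern(frags),
                )
            )
        except (KeyError, ValueError) as exc:
            raise InputError(f"{path}:{i}: {exc}") from exc
    if not out:
        raise InputError(f"{path}: no fragment rows")
    return out


def write_fragment_tsv(rows, path) -> None:
    """Write (specimen, locus, enzyme, FragmentPattern) rows."""
    _write_tsv(
        path,
        ["specimen", "locus", "enzyme", "fragments", "total"],
        [
            {
                "specimen": s,
                "locus": l,
                "enzyme": e,
                "fragments": ",".join(str(f) for f in p.fragments),
                "total": p.total,
            }
            for s, l, e, p in rows
        ],
    )


def write_calls_tsv(profiles, path) -> None:
    rows = []
    for prof in profiles:
        for locus in sorted(prof.calls):
            call = prof.calls[locus]
            rows.append(
                {
                    "specimen": prof.specimen_id,
                    "locus": locus,
                    "enzymes": ",".join(call.enzymes) or MISSING_TOKEN,
                    "state": call.state_token(),
                }
            )
    _write_tsv(path, ["specimen", "locus", "enzymes", "state"], rows)


def read_calls_tsv(path, scheme) -> list:
    """Rebuild MultilocusProfiles from a calls TSV (specimen, locus, state)."""
    by_specimen: dict = {}
    order = []
    for i, row in enumerate(_read_tsv(path), start=2):
        try:
            sid, locus, state = row["specimen"], row["locus"], row["state"]
        except KeyError as exc:
            raise InputError(f"{path}:{i}: missing column {exc}") from exc
        if sid not in by_specimen:
            by_specimen[sid] = {}
            order.append(sid)
        by_specimen[sid][locus] = state
    return [
        profile_from_letters(sid, by_specimen[sid], scheme) for sid in order
    ]


_SPECIMEN_FIELDS = [
    "specimen_id", "population_id", "taxon", "wpip_group", "wpip_haplotype",
    "mtdna_group", "mtdna_haplotype", "ank2", "pk1", "gp15", "mutl", "repa",
]


def read_specimen_tsv(path) -> list:
    out = []
    for i, row in enumerate(_read_tsv(path), start=2):
        if "specimen_id" not in row:
            raise InputError(f"{path}:{i}: missing specimen_id column")
        kwargs = {
            k: (None if row.get(k) in (None, "", MISSING_TOKEN) else row[k])
            for k in _SPECIMEN_FIELDS
            if k in row
        }
        kwargs["specimen_id"] = row["specimen_id"]
        try:
            out.append(SpecimenRecord(**kwargs))
        except ValueError as exc:
            raise InputError(f"{path}:{i}: {exc}") from exc
    if not out:
        raise InputError(f"{path}: no specimen rows")
    return out


def write_specimen_tsv(records, path) -> None:
    _write_tsv(
        path,
        _SPECIMEN_FIELDS,
        [
            {
                k: (getattr(r, k) if getattr(r, k) is not None else MISSING_TOKEN)
                for k in _SPECIMEN_FIELDS
            }
            for r in records
        ],
    )


def write_assignments_tsv(profiles, assignments, path) -> None:
    by_id = {p.specimen_id: p for p in profiles}
    rows = []
    for a in assignments:
        prof = by_id.get(a.specimen_id)
        row = {"specimen": a.specimen_id}
        for locus in ("ank2", "pk1", "GP15", "MutL", "RepA"):
            call = prof.calls.get(locus) if prof else None
            row[locus] = call.state_token() if call else MISSING_TOKEN
        row.update(
            group=a.group,
            route=a.route,
            haplotype_id=a.haplotype_id or MISSING_TOKEN,
        )
        rows.append(row)
    _write_tsv(
        path,
        ["specimen", "ank2", "pk1", "GP15", "MutL", "RepA", "group", "route", "haplotype_id"],
        rows,
    )
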