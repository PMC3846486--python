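"""Mitochondrial haplotype collapsing and mtDNA-group mapping.

Aligned equal-length mtDNA fragments (the assay uses an 852 bp *cytb* region)
are collapsed into haplotypes by exact string equality.  Variable sites are
alignment columns with more than one distinct concrete base (A/C/G/T) —
ambiguity codes compare literally for haplotype identity but do not create
variable sites.  Gap characters are rejected: the typed fragments are
indel-free coding mtDNA.

Pairwise identity is averaged over all unordered *specimen* pairs by default
(frequency-weighted); ``weighted=False`` averages over unique haplotypes
instead.  *cytb* haplotypes are mapped to mtDNA groups 1-5 by their observed
association with wPip groups I-V; the default map encodes that published
partition (#1-#4 -> mtDNA-1, #5 -> mtDNA-2, #6-#7 -> mtDNA-3, #8-#9 ->
mtDNA-4, #10-#11 -> mtDNA-5).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np

from .scheme import IUPAC_CODES

__all__ = [
    "DEFAULT_MTDNA_GROUP_MAP",
    "MtdnaHaplotypeTable",
    "collapse_haplotypes",
    "map_mtdna_groups",
]

#: cytb haplotype id -> mtDNA group, as defined by the wPip association.
DEFAULT_MTDNA_GROUP_MAP = {
    "#1": "mtDNA-1", "#2": "mtDNA-1", "#3": "mtDNA-1", "#4": "mtDNA-1",
    "#5": "mtDNA-2",
    "#6": "mtDNA-3", "#7": "mtDNA-3",
    "#8": "mtDNA-4", "#9": "mtDNA-4",
    "#10": "mtDNA-5", "#11": "mtDNA-5",
}

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class MtdnaHaplotypeTable:
    """Collapsed haplotypes: (id, representative sequence, count) triples plus
    summary statistics and an optional haplotype -> mtDNA-group map."""

    haplotypes: tuple  # of (haplotype_id, sequence, count)
    n_sequences: int
    length: int
    n_variable_sites: int
    mean_pairwise_identity: float
    group_map: dict

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def group_of(self, haplotype_id: str) -> str:
        return self.group_map.get(haplotype_id, UNASSIGNED)


def _validate(seqs) -> list:
    if not seqs:
        raise ValueError("at least one sequence required")
    seqs = [s.upper() for s in seqs]
    length = len(seqs[0])
    for i, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(
                f"sequence {i} has length {len(s)} != {length}; "
                "input must be a gapless alignment of equal lengths"
            )
        for j, c in enumerate(s):
            if c in "-.":
                raise ValueError(f"sequence {i}: gap character at position {j}")
            if c not in IUPAC_CODES:
                raise ValueError(f"sequence {i}: invalid nucleotide {c!r} at {j}")
    return seqs


def collapse_haplotypes(sequences, weighted: bool = True) -> MtdnaHaplotypeTable:
    """Collapse aligned sequences into haplotypes and summarize their diversity.

    Haplotype ids ``#1, #2, ...`` are assigned by descending count, ties broken
    by first occurrence, so relabeling is stable under input permutation up to
    count ties.  ``mean_pairwise_identity`` is the average fraction of matching
    positions over all unordered pairs (specimen-weighted, or over unique
    haplotypes with ``weighted=False``); a single sequence has identity 1.0.
    """
    seqs = _validate(list(sequences))
    length = len(seqs[0])

    counts: dict = {}
    first_seen: dict = {}
    for i, s in enumerate(seqs):
        counts[s] = counts.get(s, 0) + 1
        first_seen.setdefault(s, i)
    reps = sorted(counts, key=lambda s: (-counts[s], first_seen[s]))
    haplotypes = tuple(
        (f"#{k + 1}", rep, counts[rep]) for k, rep in enumerate(reps)
    )

    arr = np.frombuffer("".join(reps).encode(), dtype="S1").reshape(len(reps), length)
    acgt = np.isin(arr, [b"A", b"C", b"G", b"T"])
    n_variable = 0
    for col in range(length):
        bases = {arr[r, col] for r in range(len(reps)) if acgt[r, col]}
        if len(bases) > 1:
            n_variable += 1

    # Pairwise identity via the haplotype-level difference matrix.
    k = len(reps)
    diff = np.zeros((k, k), dtype=float)
    for i, j in combinations(range(k), 2):
        d = np.count_nonzero(arr[i] != arr[j])
        diff[i, j] = diff[j, i] = d
    ident = 1.0 - diff / length
    c = np.array([counts[r] for r in reps], dtype=float)
    if weighted:
        n = c.sum()
        total_pairs = n * (n - 1) / 2.0
        if total_pairs == 0:
            mean_ident = 1.0
        else:
            within = (c * (c - 1) / 2.0).sum()  # identical pairs
            between = sum(
                c[i] * c[j] * ident[i, j] for i, j in combinations(range(k), 2)
            )
            mean_ident = (within + between) / total_pairs
    else:
        if k == 1:
            mean_ident = 1.0
        else:
            mean_ident = float(
                np.mean([ident[i, j] for i, j in combinations(range(k), 2)])
            )

    return MtdnaHaplotypeTable(
        haplotypes=haplotypes,
        n_sequences=len(seqs),
        length=length,
        n_variable_sites=n_variable,
        mean_pairwise_identity=float(mean_ident),
        group_map={},
    )


def map_mtdna_groups(
    table: MtdnaHaplotypeTable, group_definition: dict | None = None
) -> MtdnaHaplotypeTable:
    """Attach a haplotype -> mtDNA-group map; unmapped ids stay unassigned.

    ``group_definition`` defaults to the published cytb partition
    (:data:`DEFAULT_MTDNA_GROUP_MAP`).
    """
    definition = dict(
        DEFAULT_MTDNA_GROUP_MAP if group_definition is None else group_definition
    )
    if not definition:
        raise ValueError("group definition must cover at least one haplotype")
    group_map = {
        hap_id: definition.get(hap_id, UNASSIGNED)
        for hap_id, _seq, _n in table.haplotypes
    }
    return replace(table, group_map=group_map)
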