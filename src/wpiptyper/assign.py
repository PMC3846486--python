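"""wPip group assignment from multilocus profiles.

Assignment runs three routes in order:

1. **congruent** — the (ank2, pk1) letter pair is one of the five group-defining
   pairs (a,a)→I, (e,c)→II, (b,b)→III, (c,d)→IV, (d,e)→V.  Any other letter
   pair marks the profile as recombinant between the two ankyrin loci.
2. **catalog** — exact match of the profile against the haplotype catalog on
   every locus where both sides are informative (a null allele matches a
   catalog "-"; a not-determined side is skipped).  Among consistent rows the
   best match is the one agreeing at the most loci, breaking ties by the fewest
   catalog-informative loci left unverified by the profile.
3. **majority_vote** — each informative locus votes for every group whose
   catalog states include its letter (or a "-", for a null allele); a strict
   plurality with at least two informative loci wins.  This is a deterministic
   stand-in for phylogenetic placement of novel recombinant profiles and is
   flagged as such in the output route.

Anything else is undetermined (vote tie / catalog says so) or unassignable
(fewer than two informative loci).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .caller import CALLED, MultilocusProfile
from .scheme import MISSING, NULL, TypingScheme

__all__ = [
    "RECOMBINANT",
    "NOT_EVALUABLE",
    "WPipAssignment",
    "AssignmentSummary",
    "check_congruence",
    "assign_group",
    "summarize_assignments",
]

RECOMBINANT = "RECOMBINANT"
NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class WPipAssignment:
    """Group call for one specimen with its evidence trail."""

    specimen_id: str
    group: str  # I..V, undetermined, unassignable
    route: str  # congruent, catalog, majority_vote, none
    haplotype_id: str | None = None
    evidence: tuple = ()

    def __post_init__(self) -> None:
        if self.route == "catalog" and self.haplotype_id is None:
            raise ValueError("route=catalog requires a haplotype_id")


def _single_letter(call) -> str | None:
    return call.letter if call.status == CALLED else None


def check_congruence(profile: MultilocusProfile, scheme: TypingScheme) -> str:
    """Group for a congruent (ank2, pk1) pair, RECOMBINANT for any other pair,
    NOT_EVALUABLE when either locus lacks a single-letter call."""
    a = _single_letter(profile.call("ank2"))
    p = _single_letter(profile.call("pk1"))
    if a is None or p is None:
        return NOT_EVALUABLE
    return scheme.congruent_pairs.get((a, p), RECOMBINANT)


def _profile_state(call):
    """Collapse a LocusCall to a catalog-comparable state or None (skip)."""
    if call.status == CALLED:
        return call.letter
    if call.status == NULL:
        return NULL
    return None  # MISSING, NOCALL, AMBIGUOUS: not comparable


def _match_catalog(profile: MultilocusProfile, scheme: TypingScheme):
    """Consistent catalog rows ranked by (agreements desc, unverified asc)."""
    ranked = []
    for rec in scheme.catalog:
        agreements = 0
        unverified = 0
        ok = True
        for locus in scheme.wolbachia_loci():
            cat = rec.state(locus)
            obs = _profile_state(profile.calls.get(locus)) if locus in profile.calls else None
            if cat == MISSING:
                continue  # catalog side not determined: never matches nor mismatches
            if obs is None:
                unverified += 1
                continue
            if cat == NULL:
                if obs == NULL:
                    agreements += 1
                else:
                    ok = False
                    break
            else:  # letter set
                if obs != NULL and obs in cat:
                    agreements += 1
                else:
                    ok = False
                    break
        if ok:
            ranked.append((agreements, -unverified, rec))
    ranked.sort(key=lambda t: (t[0], t[1]), reverse=True)
    return ranked


def _majority_vote(profile: MultilocusProfile, scheme: TypingScheme):
    """Per-locus votes over catalog allele-group associations."""
    votes = Counter()
    informative = 0
    for locus in scheme.wolbachia_loci():
        call = profile.calls.get(locus)
        obs = _profile_state(call) if call is not None else None
        if obs is None:
            continue
        informative += 1
        groups = set()
        for rec in scheme.catalog:
            cat = rec.state(locus)
            if cat == MISSING:
                continue
            if (obs == NULL and cat == NULL) or (obs != NULL and cat != NULL and obs in cat):
                groups.add(rec.group)
        for g in groups:
            votes[g] += 1
    return votes, informative


def assign_group(profile: MultilocusProfile, scheme: TypingScheme) -> WPipAssignment:
    """Assign a wPip group to one specimen profile; never raises."""
    sid = profile.specimen_id
    congruence = check_congruence(profile, scheme)
    if congruence not in (RECOMBINANT, NOT_EVALUABLE):
        return WPipAssignment(
            sid,
            congruence,
            "congruent",
            evidence=(f"ank2/pk1 pair maps to wPip-{congruence}",),
        )

    ranked = _match_catalog(profile, scheme)
    # Require the ank2/pk1 backbone itself to be verified for a catalog match.
    ranked = [r for r in ranked if r[0] >= 2]
    if ranked:
        best_score = (ranked[0][0], ranked[0][1])
        best = [rec for a, u, rec in ranked if (a, u) == best_score]
        groups = {rec.group for rec in best}
        if len(groups) == 1:
            rec = best[0]
            ev = (
                f"profile matches catalog haplotype {rec.haplotype_id} "
                f"({ranked[0][0]} loci verified)",
            )
            if len(best) > 1:
                ev += (
                    "equally consistent with "
                    + ", ".join(r.haplotype_id for r in best[1:]),
                )
            return WPipAssignment(sid, rec.group, "catalog", rec.haplotype_id, ev)

    votes, informative = _majority_vote(profile, scheme)
    if informative >= 2 and votes:
        top = votes.most_common()
        if len(top) == 1 or top[0][1] > top[1][1]:
            return WPipAssignment(
                sid,
                top[0][0],
                "majority_vote",
                evidence=(
                    f"strict plurality {top[0][1]}/{informative} informative loci "
                    f"for wPip-{top[0][0]} (votes: {dict(votes)})",
                ),
            )
        return WPipAssignment(
            sid, "undetermined", "none", evidence=(f"vote tie: {dict(votes)}",)
        )
    return WPipAssignment(
        sid,
        "unassignable",
        "none",
        evidence=(f"only {informative} informative locus/loci",),
    )


@dataclass(frozen=True)
class AssignmentSummary:
    total: int
    counts: dict
    percentages: dict = field(default_factory=dict)  # 1-decimal % of total
    congruent: int = 0
    congruent_pct: float = 0.0
    recombinant: int = 0

    def to_rows(self):
        return [
            {"group": g, "n": n, "pct": self.percentages[g]}
            for g, n in self.counts.items()
        ]


def summarize_assignments(assignments) -> AssignmentSummary:
    """Per-group counts/percentages and the congruent-vs-recombinant tally.

    Percentages are reported to one decimal; the congruent tally counts
    specimens assigned via the ank2/pk1 pair alone.
    """
    assignments = list(assignments)
    if not assignments:
        raise ValueError("no assignments to summarize")
    total = len(assignments)
    order = ["I", "II", "III", "IV", "V", "undetermined", "unassignable"]
    counts = {g: 0 for g in order}
    congruent = 0
    for a in assignments:
        counts[a.group] = counts.get(a.group, 0) + 1
        if a.route == "congruent":
            congruent += 1
    counts = {g: n for g, n in counts.items() if n or g in order[:5]}
    pct = {g: round(100.0 * n / total, 1) for g, n in counts.items()}
    return AssignmentSummary(
        total=total,
        counts=counts,
        percentages=pct,
        congruent=congruent,
        congruent_pct=round(100.0 * congruent / total, 1),
        recombinant=total - congruent,
    )
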