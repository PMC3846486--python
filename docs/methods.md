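# Methods

## The typing scheme as data

The five-group wPip assay is shipped as a JSON config
(`src/wpiptyper/data/default_scheme.json`) rather than hard-coded biology:
restriction enzymes (name, IUPAC recognition pattern, cut offset), loci with
marker class and copy number, per-(locus, enzyme) allele fragment tables in
integer base pairs, the haplotype catalog, and the congruent
(ank2, pk1) → group map. Users can supply their own scheme file with the same
schema to `--scheme`.

The recognition chemistries are the standard definitions — HinfI G^ANTC
(offset 1), TaqI T^CGA (offset 1), PstI CTGCA^G (offset 5). The fragment
tables and catalog follow the published assay. Catalog profile states
distinguish three things:

* a **letter set** — one or more acceptable allele labels (within-group
  variation such as RepA "a,b" for wPip-I; any member letter matches);
* a **null allele** `-` — the locus failed to amplify because of a primer-site
  mutation or deletion; this is informative and must match a catalog `-`;
* **not determined** `ND` — no data; never matches and never mismatches.

GP15 labels carrying an asterisk in the source survey (h\*, i\*, j\*, k\*,
l\*) are kept verbatim as distinct labels; `k` and `k*` are different alleles.
One catalog row (the singleton haplotype #30) has no published profile; it is
recorded with a placeholder recombinant (ank2, pk1) pair unused by any other
row, flagged `"synthetic_profile": true`, so that catalog matching stays
well-defined and the undetermined tally (3 specimens) is preserved. It is
excluded from catalog-fidelity testing.

`validate_scheme` re-derives the congruent-pair map from the catalog's
known-haplotype rows and reports any divergence from the declared map, along
with every other structural invariant, as data (violation records), not
exceptions.

## Virtual digestion

Coordinates are 0-based and half-open; a cut is the index of the first base of
the downstream fragment. Site search expands each pattern position to its
IUPAC base class and scans with an overlapping-match regular expression;
ambiguity codes in the *template* never match (conservative: an N in a read
is not evidence of a site). Only the given strand is scanned — all three
scheme enzymes are reverse-complement palindromic so no site can be missed; a
non-palindromic user enzyme triggers a warning. Digestion is complete
(no partial digests, no star activity, no methylation sensitivity), matching
the assay's assumption, and fragment lengths always sum to the amplicon
length. Tests cross-check fragments against Biopython's restriction machinery
and a naive sliding-window matcher as independent oracles.

## Allele calling

A candidate allele matches iff the fragment counts agree and each observed
fragment pairs with an expected fragment within ±tolerance bp, both lists
sorted descending and paired greedily (optimal for one-to-one interval
matching at equal counts). One match → the call; several → AMBIGUOUS (the
designed pk1 TaqI a/e collision); none → NOCALL. The per-candidate worst
deviation is recorded in the call for audit.

Default tolerance for user gel measurements is ±5 bp per fragment — typical
agarose sizing accuracy in this fragment range; the assay itself publishes no
tolerance. In-silico patterns are exact and all bundled tests run at 0.

pk1's three identical chromosomal copies are modeled as a single amplicon:
the assay observes one clean allele per gene per specimen. The pk1 reflex is
applied when the TaqI call is AMBIGUOUS{a,e} and a PstI product is available;
the PstI fragment table (a: 903/303/141, e: 903/430) then decides.

## Group assignment

Routes, in order:

1. **congruent** — (ank2, pk1) ∈ {(a,a)→I, (e,c)→II, (b,b)→III, (c,d)→IV,
   (d,e)→V}. This is the primary published rule and needs no other marker;
   the assignment is invariant to GP15/MutL/RepA by construction. Any other
   single-letter pair is a recombinant profile.
2. **catalog** — exact match against the haplotype catalog on every locus
   where both profile and catalog are informative (letters must be members of
   the catalog letter set; a null allele matches `-`). Because catalog rows
   differ in how many loci they determine, several rows can be consistent
   with one profile; the best match maximizes the number of agreeing
   informative loci and, among those, minimizes the catalog-informative loci
   the profile leaves unverified. This deterministic ranking reproduces every
   published row assignment — including the case of a (b, a, ND, ND, ND)
   profile, which prefers the row determined exactly at those two loci over a
   fully-determined undetermined-group row. A catalog match requires at least
   the two-locus ank2/pk1 backbone to be verified. Rows tied across different
   groups fall through to the vote.
3. **majority_vote** — each informative locus votes for every group whose
   catalog states (across all rows of that group) contain its letter (or a
   `-`, for a null allele); a strict plurality with ≥ 2 informative loci
   wins. The published survey placed recombinant haplotypes by
   maximum-likelihood/parsimony phylogenies of concatenated sequences, which
   are not reproducible from fragment data; the vote is this package's
   deterministic approximation and is flagged `route=majority_vote` in output
   so users can distinguish it from the published routes. Ties →
   undetermined; < 2 informative loci → unassignable.

Summaries report per-group counts, percentages to one decimal of the total,
and the congruent-vs-recombinant tally.

## mtDNA haplotypes

Input is a gapless alignment of equal-length sequences (the assay's 852-bp
*cytb* fragment is indel-free coding sequence; gap characters are rejected
rather than given an ad-hoc policy). Haplotypes are exact-equality classes;
ids `#1, #2, …` are assigned by descending count then first occurrence, so
labeling is deterministic without the original supplementary sequences, and a
user-supplied two-column file can impose the published labels. A variable
site is a column with > 1 distinct concrete base (A/C/G/T) among the unique
haplotypes; ambiguity codes separate haplotypes but do not create variable
sites. Mean pairwise identity is computed over all unordered specimen pairs
by default (frequency-weighted); `weighted=False` averages over unique
haplotypes instead — the published "ca. 99.5 %" figure does not state which
convention it used, so both are available and neither is asserted as the
published one. The identity always respects the bound
1 − (variable sites)/length. The default haplotype → mtDNA-group map encodes
the published partition (#1–#4 → mtDNA-1, #5 → mtDNA-2, #6–#7 → mtDNA-3,
#8–#9 → mtDNA-4, #10–#11 → mtDNA-5).

## Exact contingency tests

Null model: all r×c tables with the observed margins, weighted by the
multivariate hypergeometric probability
P(T) = (∏ᵢ rᵢ! ∏ⱼ cⱼ!)/(N! ∏ᵢⱼ nᵢⱼ!). The two-sided p-value is
Σ P(T) over tables with P(T) ≤ P(observed), ties included — the
probability-mass ordering of the Fisher–Freeman–Halton generalization.
Probabilities are computed via log-gamma and compared on the log scale with a
relative tie tolerance of 1e-7 (the convention used by standard exact-test
implementations, guarding against spurious tie splits from floating-point
noise).

Small tables are enumerated exhaustively (row-major cell filling with margin
bounds pruning; default cap 10⁶ tables — desk-scale latency well under a
minute). Past the cap the test switches to Monte Carlo: independent
margin-fixed tables sampled by Patefield's algorithm
(`scipy.stats.random_table`) under a mandatory seed, reporting
p̂ = (k+1)/(m+1) with binomial standard error √(p̂(1−p̂)/m). The published
analyses used a Markov-chain exact test (GENEPOP); enumeration/independent
sampling targets the same null and is verified against the enumeration oracle
in tests (p-mass sums to 1 within 1e-9; 2×2 agrees with the closed-form
hypergeometric two-sided test to 1e-12; MC tracks enumeration within 3·SE).
Published p-values of the form P < 10⁻⁵ are threshold reports and are not
floored here — the computed p (or its MC estimate) is reported as is.

The haploid LD test builds the allele×allele table (one allele per locus per
specimen — appropriate for co-transmitted cytoplasmic markers) and applies
the same test. Its type-I error on independent biallelic simulations
(frequency 0.5, n = 200, 500 replicates) sits near 0.04 — slightly
conservative, as expected for a discrete exact test.

Incongruence counting on a wPip × mtDNA table reports, per mtDNA group, the
row total minus the modal cell plus the identity of the off-modal cells; ties
for the mode are flagged and every modal candidate listed.

## Synthetic data

`make_amplicon` inverts a fragment table: recognition-site instances are
placed so cuts land exactly at the cumulative boundaries of the fragments in
their stored (printed) order, degenerate pattern positions and the background
are filled from a seeded generator, and accidental pattern matches are
mutated away (bounded resampling, verified by a final digest). Amplicons are
generated per (allele, enzyme) pair because the published pk1-a TaqI and PstI
fragment sums disagree (1333 vs 1347 bp) — no single sequence satisfies both
tables, so the two digests of "the same PCR product" are represented by two
sequences, distinguished by the FASTA id's optional third field
(`specimen|pk1|PstI`).

Cohort generators replicate published count structure exactly, specimen by
specimen: the 1935-profile multilocus survey (one record per catalog
haplotype occurrence, multi-letter states collapsed to their first letter),
and the 184 / 409 / 166-specimen association cohorts. Seeds randomize only
sequence backgrounds, specimen-id suffixes and pseudo-population labels —
never a count. Consequently, passing cohort tests demonstrates that the
pipeline recovers the published partitions from faithfully reconstructed
inputs; it says nothing about gel sizing error, partial digestion,
multi-infection or sampling noise in real specimens, none of which the
generator emulates. The mtDNA generator builds a reference plus k−1 singleton
mutations (extra variable sites assigned round-robin), guaranteeing exact
haplotype and variable-site counts.

Two published marginals do not reconcile internally and are reproduced as
computed from the cells: the wPip-II share of 1935 specimens is 16.8 % at one
decimal (326/1935), and the wPip × taxon table's column sums give
*quinquefasciatus* 200 / *pipiens* 119 against printed totals of 201 / 118.

## Known limitations

* Phylogenetic placement of recombinant haplotypes and of incongruent
  mtDNA specimens is out of scope; the majority vote is a flagged heuristic.
* No in-silico PCR: amplicons are taken as given (primer annealing, amplicon
  extraction from genomes, and PCR failure rates are not modeled).
* No gel-migration simulation; tolerance is a flat ± bp per fragment.
* Multi-infection detection (double peaks) is not modeled; one allele per
  locus per specimen is assumed throughout.
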