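# wpiptyper

In-silico PCR-RFLP typing of *Wolbachia* wPip strains in the *Culex pipiens*
mosquito complex, with exact tests of cytoplasmic association.

## The problem

Mosquitoes of the *Culex pipiens* complex (*Cx. quinquefasciatus*, *Cx. p.
pipiens* forms *pipiens* and *molestus*, *Cx. p. pallens*) are essentially
fixed for infection by wPip, a monophyletic clade of the endosymbiont
*Wolbachia* that manipulates host reproduction through cytoplasmic
incompatibility. wPip strains fall into five groups, wPip-I to wPip-V,
distinguishable by two fast-evolving ankyrin-motif genes, *ank2* and *pk1*.
Because *Wolbachia* and mitochondria are co-transmitted in the egg cytoplasm,
wPip groups travel with mitochondrial (*cytb*) haplotypes, and the pattern of
wPip/mtDNA/host-taxon association carries the signature of cytoplasmic
introgression across the complex.

`wpiptyper` implements the complete typing workflow for anyone applying the
five-group assay or re-analysing published group frequencies:

1. **Virtual digestion** (`wpiptyper.digest`) — IUPAC-degenerate recognition
   site search and complete-digest fragment patterns. The scheme's assays:
   HinfI (G^ANTC) digestion of *ank2* discriminates alleles a (313 bp),
   b (217/195/98), c (293/217), d (217/195) and e (415); TaqI (T^CGA)
   digestion of *pk1* gives a/e (903/430, identical), b (669/665), c (851/498)
   and d (497/251/107); a PstI (CTGCA^G) reflex digest separates pk1 a
   (903/303/141) from e (903/430).
2. **Allele calling** (`wpiptyper.caller`) — fragment-pattern matching with a
   per-fragment size tolerance and the pk1 a/e reflex resolution.
3. **Group assignment** (`wpiptyper.assign`) — the five congruent (ank2, pk1)
   pairs (a,a)→I, (e,c)→II, (b,b)→III, (c,d)→IV, (d,e)→V; any other pair is a
   recombinant profile, resolved against the bundled 35-row haplotype catalog
   over the additional sequenced markers *GP15*, *MutL* and *RepA* (null
   alleles included), with a majority-vote fallback for novel profiles.
4. **mtDNA haplotypes** (`wpiptyper.mtdna`) — collapsing aligned *cytb*
   fragments into haplotypes, variable-site and pairwise-identity summaries,
   and the haplotype → mtDNA-group (1–5) partition.
5. **Exact association tests** (`wpiptyper.association`) — the
   Fisher–Freeman–Halton exact test on r×c contingency tables. The null
   conditions on both margins; table T has probability
   P(T) = (∏ᵢ rᵢ! ∏ⱼ cⱼ!)/(N! ∏ᵢⱼ nᵢⱼ!), and the two-sided p-value sums P(T)
   over tables no more probable than the observed one — by exhaustive
   enumeration for small problems, by seeded Patefield Monte Carlo sampling
   otherwise. Used for ank2/pk1 linkage disequilibrium and the wPip × mtDNA ×
   host-taxon partitions.
6. **Synthetic data** (`wpiptyper.fixtures`) — amplicons whose digestion
   reproduces any scheme fragment table exactly, plus specimen cohorts
   replicating the published survey's count structure (1935 typed specimens;
   184 wPip×mtDNA; 409 wPip×taxon; 166 cytb×taxon).

## Worked example

Generate a fixture bundle, type it and test an association (every stochastic
path takes an explicit seed):

```sh
wpiptyper simulate --seed 5 --outdir fx        # allele amplicon FASTA + cohort TSVs
wpiptyper type amps.fasta --out calls.tsv      # your amplicons; ids specimenID|locus[|enzyme]
wpiptyper assign calls.tsv --out assignments.tsv
```

For an `amps.fasta` holding two specimens — one with ank2-a plus pk1 TaqI 903/430 resolved to pk1-a by
the PstI reflex, one with ank2-e/pk1-c — `assign` prints:

```
total specimens	2
wPip-I	1	50.0%
wPip-II	1	50.0%
...
congruent ank2/pk1	2	100.0%
```

i.e. both (a,a) and (e,c) are congruent pairs, assigned to wPip-I and wPip-II
without needing the sequenced markers. Testing the wPip × host-taxon
partition of the 409-specimen cohort:

```sh
wpiptyper assoc fx/cohort_table3.tsv --row wpip_group --col taxon --seed 1
```

```
exact test: p = 9.9999e-06 (monte_carlo, n = 100000, SE = 1e-05, seed = 1)
```

The enumeration cap was exceeded (the 6×5 table admits far more than 10⁶
margin-fixed tables), so the p-value is the (k+1)/(m+1) Monte Carlo estimate:
none of 100 000 sampled tables was as improbable as the observed one — wPip
groups and host taxa are strongly associated, though not exclusively (each
taxon carries two to five wPip groups).

The same analyses are available as a library:

```python
import wpiptyper as w

scheme = w.load_scheme()                    # bundled five-group scheme
amp = w.make_amplicon("pk1", "TaqI", "d", scheme, seed=1)
w.digest(amp, scheme.enzyme("TaqI")).fragments   # (497, 251, 107)
```

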