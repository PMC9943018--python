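# Methods

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
and Infernal tblout (1-based inclusive, seq-from > seq-to on the minus
strand) are converted at the boundary. In tblout input the strand is
derived from coordinate order and cross-checked against the strand column
when present; a contradiction rejects the record with a warning rather
than guessing. Both dialects occur in the wild and silent disagreement is
worse than a dropped row. GFF3 `gene` and `pseudogene` features are
consumed directly; `CDS` features without a parent gene are promoted to
genes, since many bacterial annotations carry CDS only. Features without
a strand are rejected with a warning — orientation is the object of study,
so a strandless gene cannot be used.

## Hit resolution

Related covariance models (six c-di-GMP models, three cobalamin models,
…) recognize overlapping sequence sets, so raw search output stacks
several hits on one locus. Hits sharing contig and strand are
single-linkage clustered on interval overlap (one shared base suffices;
abutting intervals do not merge) and each cluster keeps its highest
bit-score member. Single-linkage transitive merging is the simplest rule
that collapses a chain of mutually overlapping model hits into one locus.
Ties break by lower E-value, then lexicographically smaller class name,
making resolution a pure function of the hit set: permuting input order
cannot change the result, and resolving resolved loci is the identity.
Hits on opposite strands never merge.

## Orientation rule

Let the scan direction be the riboswitch's own transcription direction.
The candidate target is the nearest gene whose body overlaps the
riboswitch or lies downstream of it in the scan direction, with a gap of
at most `max_distance` (default 500 nt, configurable). Same strand ⇒
`SENSE_5P`; opposite strand ⇒ `ANTISENSE_3P`; no candidate ⇒
`UNASSIGNED`. This single geometric criterion unifies the two verbal
definitions — 5′ sense leader and 3′ antisense element — because
convergent geometry always meets an opposite-strand gene at its 3′ end.
Distance is the non-negative gap (0 when overlapping). Two deliberate
edge rules:

* a riboswitch wholly contained in a same-strand gene is internal, not a
  leader, and stays `UNASSIGNED`; contained in an opposite-strand gene it
  is an antisense call at distance 0 (antisense elements may overlap 3′
  ends);
* when two genes are equidistant (a shared boundary coordinate), the one
  giving a sense call wins, then the smaller gene id — conservative for
  antisense calls and deterministic.

The rule is translation-invariant and symmetric under mirroring all
coordinates with a global strand flip; both properties are asserted on
randomized layouts in the test suite.

## Enrichment statistic

The null is a pooled one-margin-fixed hypergeometric over the family
rows: N assigned riboswitches in total, K antisense overall; a family
with n members and k antisense is scored by the inclusive upper tail
P(X ≥ k), X ~ Hypergeom(N, K, n). The tail is summed in log space from k
upward using a lazily extended log-factorial table, with early
termination once terms have passed the distribution mode and fallen 30
orders of magnitude below the running sum; family tables span 1e-62 to
1.0 and the deep tail must survive. The implementation is checked two
ways: exhaustive exact rational enumeration for every parameter tuple
with N ≤ 60 (relative error < 1e-10; observed worst case ≈ 7e-14) and
scipy's `hypergeom.sf` on larger tuples. Raw p-values are the primary
output; a Benjamini–Hochberg column is available but off by default,
since the screen's headline numbers are uncorrected and 27 parallel
tests at p ≈ 1e-62 do not change rank.

Inclusivity at k matters: the mid-range rows (Glycine 0.74, glnA 0.30,
sul1 0.64) reproduce only with P(X ≥ k), not P(X > k).

## Gene categories

The ten-way classification replaces a manual curation step with an
ordered rule file (YAML, shipped default in `riboscreen/data/`). First
match wins; structural classes (pseudogene by feature kind, transposase
by keyword/COG) precede functional keyword classes (transcription
factor, signaling, transporter, cofactor-dependence, interconversion),
which precede the annotation-artifact classes; `other` is the
unconditional fallback, so the classifier is total. Cofactor-dependence
is tested before generic enzyme keywords because a
"cobalamin-dependent … synthase" is a cofactor case first. The
`hypothetical` class requires **both** length < 300 nt **and** no known
ortholog; `uncharacterized` requires length ≥ 300 nt **and** a bona fide
ortholog. A gene of exactly 300 nt falls on the uncharacterized side.
The five categories counted as biologically consistent regulation are
interconversion, cofactor, transporter, signaling and tf.

## Synteny context

For antisense calls on suspect categories (transposase, pseudogene,
hypothetical, uncharacterized), the would-be canonical target is the
next gene beyond the suspect in the riboswitch's scan direction — the
gene the riboswitch would lead in 5′-sense geometry were the suspect
absent. Its ortholog group (user-supplied table; orthology is never
computed here) is looked up, and each other genome carrying a member
votes: consistent iff that member is the `SENSE_5P` target of a
riboswitch of the same family. Consistency is the consistent fraction
over compared genomes (0 when none are comparable) and a call is flagged
`reassigned` when consistency reaches the threshold (default 0.5).
Consistency is invariant under permutation of the compared genomes, a
genome without an ortholog contributes nothing, and the flag is monotone
in the threshold. Per-category summaries report both the reassigned
fraction and the mean consistency; the mean is the direct estimator of a
per-genome planting rate, while the reassigned fraction concentrates
toward 0 or 1 as the number of compared genomes grows.

## Synthetic data

The generator emulates the screen's input at desk scale: by default 10
genomes × 2 contigs × 100 genes (lognormal lengths, median ≈ 900 nt,
minimum 100 nt; geometric-like intergenic gaps, mean 150 nt, minimum
25 nt), ~300 riboswitches over seven families at the observed antisense
rates (base rate ≈ 1.2%, the most enriched family at ≈ 5.6%), decoy
overlapping hits at probability 0.3 with strictly lower scores, 7 tandem
pairs, a ten-category plan for antisense targets, and ortholog
scaffolding for suspect cases with per-related-genome consistency 0.72
across 5 related genomes. Planted riboswitch–gene gaps are at most
400 nt, safely inside the 500 nt assignment rule, and tandem members are
separated by 25–50 nt so a ±20 nt decoy can never bridge two loci.
Category slots interleave round-robin across categories so even a
handful of antisense cases spans the plan. One seed sequence drives the
planning stream and per-genome layout substreams spawned by counter;
identical seed and config give byte-identical bundles.

It plants geometry, not sequence: no downstream stage reads nucleotides,
covariance-model search being consumed only through its tabular output.
What passing recovery tests show is therefore that the *geometric and
statistical* machinery is exact on unambiguous input; they do not
exercise sequence-level failure modes (truncated models, misannotated
gene boundaries, overlapping real genes) or the search step itself.
Real annotations also carry messier label vocabularies than the
generator's category keywords, so category recovery on real genomes
depends on tuning the rule file, not on the classifier mechanics.

## Problem sizes and numerical choices

The default test-suite simulation is 10 genomes / ~2,000 genes / ~330
riboswitches; the synteny-rate study plants ≥ 200 suspect cases across 8
genomes; the enrichment power study runs 100 replicates of a 10,500-
riboswitch plan through the same relation sampler the generator uses,
without genome layout — contingency-level replication is exact for a
statistic that only sees counts. The exhaustive hypergeometric oracle
sweep covers ~1.3 million tuples. BED scores clip bit scores to
[0, 1000] per the BED convention. Empty inputs produce empty,
well-formed outputs (an empty contingency, a zero category table with
percentages reported as 0), never errors.

## Known limitations

* The 50 → 27 class-to-family map beyond the hard-required memberships
  (the six c-di-GMP models; Cobalamin/AdoCbl/AdoCbl-variant) groups
  classes by ligand identity and is meant to be edited; it is a
  configuration file, not an assertion.
* Operons are invisible: a riboswitch leading a multi-gene operon is
  assigned to the first gene only.
* Whether a co-oriented riboswitch downstream of a gene belongs to that
  gene's 3′ UTR or to the next gene's leader cannot be decided from
  annotation alone; under the scan rule it is the next co-oriented
  gene's leader or `UNASSIGNED`.
* Ortholog tables are consumed, never inferred; synteny conclusions are
  only as good as the supplied orthology.
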