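# Methods

## Scientific setting

Two rounds of whole-genome duplication at the base of the vertebrates left
many developmental gene families with "a"/"b" paralogue pairs.  For four
Wnt ligand subfamilies (Wnt2, Wnt5, Wnt7, Wnt8) the mouse and the chick
each retain both paralogues, while amphioxus — a chordate that diverged
before the duplications — retains a single gene per subfamily and proxies
the ancestral state.  `wntdiverge` quantifies how the duplicates have
diverged along two axes: the protein-coding sequence (conservation
profiling of a five-sequence alignment per subfamily) and embryonic
deployment (ordinal grading of spatial expression-pattern similarity, and
the subset structure of a gene × territory presence matrix).

## Column classification

The unit is a five-row alignment: outgroup, species-1 a/b, species-2 a/b.
Each column receives exactly one category, decided in priority order:

1. outgroup gapped → `OUTGROUP_GAP` (no ancestral state to compare with;
   the column is excluded from every conservation count);
2. all five residues cysteine → `CONSERVED_CYS` (the ~24 structural
   cysteines of Wnt ligands are tabulated separately);
3. otherwise, let *M* be the set of vertebrate roles whose residue
   *matches* the outgroup residue under the active policy (a gap matches
   nothing): |M| = 4 → `FULLY_CONSERVED`; |M| = 3 →
   `SINGLE_GENE_DIVERGENT` with the odd gene recorded; M = both "a"
   genes → `PARALOGUE_A_CONSERVED`; M = both "b" genes →
   `PARALOGUE_B_CONSERVED`; |M| = 0 with all four vertebrates non-gap and
   mutually equal → `VERTEBRATE_ONLY`; anything else → `UNCLASSIFIED`.

Species-specific two-gene conservation (both genes of one species
matching the outgroup) deliberately falls into `UNCLASSIFIED`: it is not
one of the counted biological signals, and counting it would change the
summary semantics.

### Matching policy

"Conserved" defaults to residue identity — unambiguous and directly
testable.  A `SIMILARITY_GROUPS` mode additionally accepts two residues
from the same physicochemical group, which is the mode relevant when
percent *similarity* rather than identity is quoted.  Because the policy
requires each residue to belong to at most one group, the default
partition is disjoint: aliphatic {A,V,L,I,M}, aromatic {F,W,Y}, basic
{K,R,H}, acidic {D,E}, amide {N,Q}, hydroxyl {S,T}, and singletons C, G,
P.  (The overlapping Clustal "strong groups" cannot serve here.)  The
groups are a constructor argument, so any disjoint partition can be
substituted.

### Percent similarity

For each vertebrate sequence, similarity to the outgroup is
100 × matches / (mutually ungapped columns).  Restricting the denominator
to columns where both sequences carry a residue is the standard pairwise
convention and makes the value a substitution measure, independent of
indel history.  A pair with no mutually ungapped column raises an error
rather than returning a conventional value.

### Gap handling

A vertebrate gap counts as a mismatch (it cannot carry the ancestral
residue); an outgroup gap removes the column from analysis.  Validation
rejects ragged rows and all-gap columns, reporting the first offending
column index.

## Expression model

An annotation is (gene, stage, territory, domain set, optional level).
Territories come from a controlled vocabulary shared across species
(optionally with parent links for grouping, e.g. the CNS subdivisions);
domains are free labels within a territory.  Stages are paired across
species at matched limb morphology: TS15↔HH20, TS17↔HH23, TS19↔HH26.

Two genes' patterns in a territory are graded from their domain sets D1,
D2: both empty → not applicable; exactly one empty → `***` (3, exclusive);
disjoint non-empty → `**` (2, different domains); overlapping but unequal
→ `*` (1, minor difference); equal → `=` (0).  "Minor difference" is
operationalized as overlap-without-equality — the only reading computable
from set-valued annotations.  The rule is symmetric by construction, and
qualitative staining level is stored but never graded: the scale is purely
spatial.

Stage aggregation defaults to grading the union of each gene's domains
across its stages (the summary view); per-stage-worst and per-stage-best
modes grade each matched stage pair separately and keep the most divergent
or most similar applicable grade.  No ordering between the union grade and
the per-stage grades holds in general (a union can merge two disjoint
per-stage sets into an overlapping pair), so none is asserted; what is
guaranteed — and tested — is that identical per-stage sets yield `=` under
all three modes.

The four-way grid for a subfamily compares paralogues within each species
and orthologues across species for each tag, over every territory where
any of the four genes is expressed.  The divergence index of a comparison
is the mean ordinal grade over its applicable territories, in [0, 3]; it
is reported as missing when no cell is applicable.  The index is a
package-level numeric summary that makes "subfamily X is more divergent
than Y" statements concrete and lets the simulator's divergence parameter
be recovered quantitatively.

## Territory sharing

From a binary presence matrix (1 iff expression at any stage), territory
t shares with t′ when S(t) ⊆ S(t′) for expressing-gene sets S.  A row is
reciprocal when every listed partner has exactly S(t); an empty list is
vacuously reciprocal (no one-way sharing exists).  Pair-level equality
partners are additionally emitted in JSON, since a row flag alone cannot
express statements like "arches 1 and 2 are mutually reciprocal" when a
territory's set is also contained in some larger set.  Territories with no
expressing gene are excluded from rows (they would vacuously share with
everything) and listed separately.

## Synthetic data

The alignment generator draws a category per column from a configurable
mixture and constructs residues realizing exactly that category under
identity matching.  Cysteine is reserved for planted `CONSERVED_CYS`
columns so a planted `FULLY_CONSERVED` column can never reclassify as the
cysteine category.  The default mixture (55% fully conserved, 7% cysteine,
12% single-gene divergent, 6% + 6% paralogue-specific, 6% vertebrate-only,
8% outgroup gap, over 350 columns) echoes the overall look of a real Wnt
subfamily alignment: conservation dominating, ~24 cysteines, modest
divergence classes.  `UNCLASSIFIED` has no canonical construction and is
not plantable.

The expression generator mirrors the biology it tests: per subfamily and
territory, with probability `p_express` (default 0.6 — most territories
express more than one subfamily) an ancestral domain set of
`n_domains_per_territory` labels (default 2) is drawn; all four genes
inherit it; each gene then mutates independently with probability `theta`,
choosing uniformly among silencing (drop all domains), relocation (replace
with a disjoint set) and a minor edit (add or remove one domain, never
emptying the set).  The three moves map one-to-one onto the grade outcomes
***, ** and * against an unmutated partner, but the planted truth is
always the grade implied by the *final* sets, so compound events (both
genes mutating) stay unambiguous.  Each gene carries the same domain set at
every stage of its species; divergence is modelled per gene × territory,
not per stage, which makes the planted grade identical under all three
stage aggregations.  One seeded pseudo-random stream drives each artifact;
identical configs give byte-identical files.

What the simulator does not emulate: realistic protein evolution (no
substitution matrices or indel process), temporal dynamics of expression,
territory-specific domain vocabularies, annotation noise or observer
disagreement.  Passing planted-recovery tests therefore demonstrates the
correctness of the classification and grading machinery, not robustness to
the ambiguities of real annotation data.

## Numerical and ordering choices

Grades are compared by their integer ordinals; 'worst' is the maximum,
'best' the minimum, ties are impossible by construction.  Grid rows follow
the territory vocabulary file order; sharing-report rows follow matrix
column order — all outputs are deterministic and diffable.  The divergence
index uses the arithmetic mean of ordinals, treating the scale as
equally spaced; this is a convention, adequate for ranking comparisons,
and no interval interpretation is claimed.  CLI exit codes separate
validation failures (3) from I/O failures (4).

## Reproduction on real alignments, and its limits

The `profile` stage reproduces published per-subfamily counts only when
run on the actual Wnt protein sequences, which are referenced by accession
and are not redistributed with the package (see `data/real/README.md` for
the expected layout).  Column-level counts are sensitive to the upstream
aligner and its parameters; the pipeline therefore treats the aligner as
pinned external configuration, records it in the run manifest, and the
real-data test reports disagreement rather than tolerating it silently.
Whether published counts used identity or a similarity grouping, and
whether cysteine conservation was assessed over all five sequences or the
vertebrates only, are not decidable from the source material; the package
defaults to identity and to all five sequences, and exposes both
alternatives.

## Problem sizes

The test-suite and acceptance-script workloads — 10,000 planted columns,
1,000 random columns and 1,000 random matrices against brute-force
oracles, a 10-point theta grid with 5 replicate seeds over 50 territories
— were chosen as the smallest sizes at which the checked properties are
exercised across all category mixtures and matrix shapes; the whole suite
runs in well under a minute on one CPU.
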