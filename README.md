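# wntdiverge

Tools for asking how a pair of duplicated developmental genes has diverged
— in protein sequence and in embryonic deployment — built around the
vertebrate Wnt "a"/"b" paralogue pairs (Wnt2, Wnt5, Wnt7, Wnt8) of mouse
and chick, with the single amphioxus orthologue as a proxy for the
pre-duplication ancestral state.

It is aimed at evo-devo and molecular-evolution researchers comparing
paralogue/orthologue pairs across model species, and it answers three
questions:

1. **Which residues has each duplicate kept?**  Every column of a
   five-sequence subfamily alignment (outgroup + 2 species × 2 paralogues)
   is classified by which vertebrate genes match the outgroup residue:
   fully conserved, conserved cysteine, single-gene divergent (with the
   divergent gene named), "a"- or "b"-paralogue-specifically conserved,
   vertebrate-only, or outgroup-gap/unclassified.  Summaries include the
   per-gene single-gene-divergence counts and percent identity/similarity
   to the outgroup.
2. **How similar are two genes' expression patterns?**  Stage- and
   territory-resolved annotations are graded per territory on the ordinal
   scale `=` (0, equivalent domains) < `*` (1, overlapping but distinct) <
   `**` (2, same territory, different domains) < `***` (3, only one gene
   expressed).  A four-way grid compares paralogues within each species and
   orthologues across species; the mean ordinal over applicable
   territories is the comparison's divergence index in [0, 3].
3. **Which territories share their full expressing-gene set?**  From the
   binary gene × territory presence matrix, each territory's containment
   partners (S(t) ⊆ S(t′)) and a reciprocal/non-reciprocal flag are
   computed — non-reciprocal sharing dominating is evidence for
   territory-by-territory regulation.

A synthetic-data module generates alignments with planted column classes
and expression datasets with planted grades under a tunable divergence
parameter θ, so the whole pipeline is testable with exact ground truth.

## Worked example

Run the full synthetic pipeline (simulate → profile → compare → share):

```sh
wntdiverge run --seed 3 --out demo
```

`demo/summary.tsv` profiles the simulated 350-column alignment:

```
conserved_cysteines	20
paralogue_a_specific_sites	19
paralogue_b_specific_sites	20
single_gene_divergence[S1_A]	14
single_gene_divergence[S1_B]	17
single_gene_divergence[S2_A]	13
single_gene_divergence[S2_B]	8
similarity_vs_outgroup[S2_B]	85.3
```

i.e. 20 columns are all-cysteine, 19 sites are conserved with the outgroup
only in the two "a" paralogues (and 20 only in the "b" paralogues), the
species-1 "a" gene is the lone divergent gene at 14 otherwise-conserved
sites, and the species-2 "b" gene matches the outgroup at 85.3% of their
mutually ungapped columns.

`demo/grid_Wnt2.tsv` is the four-way comparison grid for one simulated
subfamily (columns: paralogues in species 1, paralogues in species 2,
"a" orthologues, "b" orthologues):

```
territory	PARALOGUES_SPECIES1	PARALOGUES_SPECIES2	ORTHOLOGUES_A	ORTHOLOGUES_B
diencephalon	=	***	=	***
otic_vesicle	=	**	=	**
branchial_arch_2	*	*	*	=
branchial_arch_3	***	=	***	=
```

Read the first row as: in the diencephalon the species-1 paralogues
occupy equivalent domains (`=`), while in species 2 only one paralogue is
expressed there at all (`***`); the "a" orthologues agree across species
and the "b" orthologues do not.  `demo/sharing.tsv` lists, per territory,
the territories containing its full expressing-gene set and whether the
sharing is reciprocal:

```
territory	shared_with	reciprocal
telencephalon	diencephalon,rhombencephalon,neural_tube,...	NR
diencephalon	.	R
```

Individual stages are available as `wntdiverge profile`, `compare`,
`share` (plus `share check --group ... --target ...`) and
`wntdiverge simulate alignment|expression`; see `--help` on each.

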