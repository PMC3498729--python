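# Real subfamily alignments (not distributed)

The Wnt protein sequences themselves are not redistributed with this
package; obtain them from NCBI/Ensembl by accession (the amphioxus
orthologue plus the chick and mouse "a"/"b" paralogues for each of Wnt2,
Wnt5, Wnt7 and Wnt8), align each five-sequence set with a progressive
aligner (e.g. `clustalw` or `mafft --auto`, recording the version), and
place per subfamily:

    data/real/Wnt2.fasta   aligned FASTA (gap '-')
    data/real/Wnt2.roles.tsv  label<TAB>role (OUTGROUP, S1_A=chick a,
                              S1_B=chick b, S2_A=mouse a, S2_B=mouse b)

and likewise for `Wnt5`, `Wnt7`, `Wnt8`.  With these files present,
`tests/test_acceptance.py::test_real_alignment_conservation_counts` runs
the `profile` stage on each subfamily and compares its counts with the
published values.  Counts are sensitive to the aligner and its parameters;
differences under a different guide tree are expected and should be
reported alongside the numbers.
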