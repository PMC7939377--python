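# Deposited genotype data (not redistributed)

The test
`tests/test_acceptance.py::TestDepositedGenotypeRecomputation` recomputes
per-marker PIC and the informativeness class tally from the study's
deposited per-accession genotype table. That table is third-party data
and is not shipped with this package.

To run the recomputation, export the deposited table to
`data/deposited/marker_genotypes.tsv` with columns:

    marker    sample    allele1_len    allele2_len

one row per sequenced accession per marker, allele lengths in bp, missing
calls left blank. Without the file the test fails with a missing-input
error.
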