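# Reference sequences (user-supplied)

Database sequences are not redistributed with this package. To run the
cross-species reference comparisons in the test suite, place the following
plain FASTA files here (one record each, any header):

| file                      | sequence                                          |
|---------------------------|---------------------------------------------------|
| `heparanase_human.fasta`  | human heparanase (e.g. extracted from PDB 5E9C chains, or UniProt Q9Y251) |
| `heparanase_mouse.fasta`  | mouse heparanase, UniProt Q6YGZ1                  |
| `pf4_human.fasta`         | human platelet factor 4 (CXCL4), UniProt P02776   |
| `pf4_rabbit.fasta`        | rabbit platelet factor 4                          |

For example:

    wget -O heparanase_mouse.fasta \
        https://rest.uniprot.org/uniprotkb/Q6YGZ1.fasta

Without these files the two tests that compare the corresponding
percent-identity/similarity values report a failure explaining what is
missing; everything else in the package is self-contained.
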