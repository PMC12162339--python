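# External reference sequences (not redistributed)

One check compares the bichir (*Erpetoichthys calabaricus*) p40 homolog
against human p40 under BLAST-compatible scoring. The two public sequences
are not bundled; to run it, fetch them once into this directory:

- `P29460.fa` — UniProt https://rest.uniprot.org/uniprotkb/P29460.fasta
- `ENSECRT00000020045.fa` — the protein translation of Ensembl transcript
  ENSECRT00000020045 (Erpetoichthys calabaricus), e.g. via Ensembl REST:
  https://rest.ensembl.org/sequence/id/ENSECRT00000020045?type=protein;content-type=text/x-fasta

Without these files the corresponding test fails with a pointer here.
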