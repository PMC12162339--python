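"""Align a group, trim it, and profile per-column conservation.

The trimmer keeps columns with >=85% occupancy (with a 30% conserved-columns
floor); information content is log2(20) minus the column entropy, the height
scale of a sequence logo.  Key residues are mapped from ungapped reference
numbering onto alignment columns with a conservation fraction.
"""

import tempfile
from pathlib import Path

from cytofam import (SyntheticSpec, column_profiles, generate_species_set,
                     map_key_residues, progressive_align, read_fasta,
                     trim_alignment)

workdir = Path(tempfile.mkdtemp(prefix="cytofam_example_"))
bundle = generate_species_set(SyntheticSpec(seed=1), workdir / "corpus")

truth = bundle.truth
members = []
for _, row in truth[truth.template_id == "lig_EBI3"].iterrows():
    recs = {r.id: r for r in read_fasta(bundle.protein_paths[row.species_id])}
    members.append(recs[row.protein_id])

aln = progressive_align(members)
trimmed, kept = trim_alignment(aln)
print(f"{len(members)} Group II ligands: {aln.ncols} columns, "
      f"{trimmed.ncols} after trimming")

profiles = column_profiles(trimmed)
strong = [(i, p) for i, p in enumerate(profiles) if p.information_bits > 4.0]
print(f"{len(strong)} columns with >4 bits (near-invariant); first five:")
for i, p in strong[:5]:
    print(f"  column {i:3d} (source {kept[i]:3d}): consensus {p.consensus}, "
          f"{p.information_bits:.2f} bits")

ref = members[0].id
reports = map_key_residues(aln, ref, [(members[0].seq[9], 10)])
r = reports[0]
print(f"\nresidue {r.residue}{r.position} of {ref}: column {r.column}, "
      f"conserved in {r.conservation:.0%} of rows")
# High-information columns concentrate in the planted signature anchors,
# which the generator shields from mutation.
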