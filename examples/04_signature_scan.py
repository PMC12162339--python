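"""Scan for the three gapped fn3 signatures and the WSXWS hallmark.

The beta-subunit signatures F-I-KPDPP, W-P-W-P-F-L-K/F and V-A-S-WS are
ordered anchors separated by one or more residues; WSXWS is the contiguous
pentapeptide hallmark of class-I cytokine receptor ectodomains.
"""

import tempfile
from pathlib import Path

from cytofam import (SyntheticSpec, detect_wsxws, generate_species_set,
                     load_builtin_signatures, read_fasta, scan_signature)

workdir = Path(tempfile.mkdtemp(prefix="cytofam_example_"))
bundle = generate_species_set(
    SyntheticSpec(seed=1, classes={"Mammalia": 1}, point_mutation_rate=0.0),
    workdir / "corpus")

sigs, _ = load_builtin_signatures()
truth = bundle.truth
proteins = {r.id: r for r in read_fasta(bundle.protein_paths["mam1"])}

ebi3 = proteins[truth[truth.template_id == "lig_EBI3"].protein_id.iloc[0]]
print(f"beta-subunit {ebi3.id} ({len(ebi3)} aa):")
for sig in sigs:
    for m in scan_signature(ebi3, sig):
        print(f"  {sig.motif_id:16s} at {m.start:3d}-{m.end:3d}  {m.matched}")

rb1 = proteins[truth[truth.template_id == "rec_IL12RB1"].protein_id.iloc[0]]
print(f"\nreceptor {rb1.id} ({len(rb1)} aa):")
for m in detect_wsxws(rb1):
    print(f"  WSXWS at {m.start}-{m.end}  {m.matched}")
# All three signature classes sit in the fn3 region, in order, exactly where
# the generator planted them.
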