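"""Classify domain architectures into ligand and receptor Groups I-V.

The groups are equivalence classes of architectures: e.g. an IL12p40_C
domain marks a Group I ligand (p40-like), Lep_receptor_Ig followed by
exactly two fn3 marks a Group V receptor (IL-12Rbeta2-like).
"""

from cytofam import DomainArchitecture
from cytofam.family_grouping import classify_ligand, classify_receptor


def arch(*labels):
    pos, doms = 1, []
    for lab in labels:
        doms.append((lab, pos, pos + 89))
        pos += 100
    return DomainArchitecture("example", tuple(doms))


print("ligands:")
for labels, query in [(("Ig-like", "IL12p40_C"), None), (("fn3",), None),
                      (("IL12",), None), (("IL23",), None), ((), "IL27")]:
    a = classify_ligand(arch(*labels), query)
    shown = "+".join(labels) if labels else f"(no domain, best query {query})"
    print(f"  {shown:35s} -> Group {a.group:2s} [{a.rule_id}]")

print("receptors:")
for labels in [("fn3",), ("Ig-like", "fn3", "fn3"),
               ("Lep_receptor_Ig", "IL6Ra-bind", "fn3"),
               ("IL6Ra-bind",), ("Lep_receptor_Ig", "fn3", "fn3")]:
    a = classify_receptor(arch(*labels))
    print(f"  {'+'.join(labels):35s} -> Group {a.group:2s} [{a.rule_id}]")
# Each rule_id names the clause that fired, so every assignment is auditable.
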