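"""Run the whole pipeline end to end on a synthetic corpus and check the
stage report against the planted truth."""

import json
import tempfile
from pathlib import Path

import pandas as pd

from cytofam import (RunConfig, SyntheticSpec, emit_domain_calls,
                     generate_species_set, run_pipeline)

workdir = Path(tempfile.mkdtemp(prefix="cytofam_example_"))
bundle = generate_species_set(SyntheticSpec(seed=1), workdir / "corpus")
domtbl = emit_domain_calls(bundle)

cfg = RunConfig(meta=str(bundle.meta_path),
                fasta_dir=str(bundle.root / "fasta"),
                gff_dir=str(bundle.root / "gff"),
                busco_dir=str(bundle.root / "busco"),
                queries_fasta=str(bundle.queries_path),
                domtbl=[str(domtbl)],
                out_dir=str(workdir / "out"), seed=17)
report = run_pipeline(cfg)

print(json.dumps(report.stages, indent=2))

groups = pd.read_csv(workdir / "out" / "groups.tsv", sep="\t")
truth = bundle.truth[~bundle.truth.is_decoy]
merged = truth.merge(groups, on="protein_id", how="left")
recovery = (merged.group == merged.truth_group).mean()
print(f"\ngroup recovery vs planted truth: {recovery:.1%} "
      f"({len(merged)} planted proteins)")
# All stage outputs are plain TSV under out/; rerunning with the same seed
# and inputs reproduces them byte for byte.
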