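import pytest

from cytofam.pipeline import RunConfig, run_pipeline
from cytofam.synthetic_data import (SyntheticSpec, emit_domain_calls,
                                    generate_species_set)


@pytest.fixture(scope="session")
def bundle0(tmp_path_factory):
    """Synthetic corpus at mutation rate 0: species copies equal the masters."""
    root = tmp_path_factory.mktemp("bundle0")
    b = generate_species_set(SyntheticSpec(seed=11, point_mutation_rate=0.0), root)
    emit_domain_calls(b)
    return b


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Synthetic corpus at the default 10% point-mutation rate."""
    root = tmp_path_factory.mktemp("bundle10")
    b = generate_species_set(SyntheticSpec(seed=11), root)
    emit_domain_calls(b)
    return b


def make_config(b, out_dir, seed=17):
    return RunConfig(
        meta=str(b.meta_path),
        fasta_dir=str(b.root / "fasta"),
        gff_dir=str(b.root / "gff"),
        busco_dir=str(b.root / "busco"),
        queries_fasta=str(b.queries_path),
        domtbl=[str(b.domtbl_path)],
        out_dir=str(out_dir),
        seed=seed,
    )


@pytest.fixture(scope="session")
def pipeline_run(bundle, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe_out")
    cfg = make_config(bundle, out)
    report = run_pipeline(cfg)
    return bundle, cfg, report, out


@pytest.fixture(scope="session")
def pipeline_run0(bundle0, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe_out0")
    cfg = make_config(bundle0, out)
    report = run_pipeline(cfg)
    return bundle0, cfg, report, out
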