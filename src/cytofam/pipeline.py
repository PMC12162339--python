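"""End-to-end orchestration: preprocess → identify → classify → cluster →
conserve → distribute/synteny, driven by a single validated config.

All stage outputs are plain TSV under the configured output directory; the
run report (JSON) echoes parameters and per-stage counts.  Every source of
randomness flows from the single config seed, so output files are
bit-identical across reruns (the report's wall-clock fields are the one
deliberate exception and are excluded from the determinism contract).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import conservation_signatures as cons
from . import distribution_synteny as dist
from . import family_grouping as grouping
from . import genome_preprocess as prep
from . import formats_io as fio
from . import homolog_search as hs

__all__ = ["RunConfig", "RunReport", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised for unknown keys, missing paths or malformed config values."""


@dataclass
class RunConfig:
    """Validated pipeline configuration; defaults are the published
    parameters (E ≤ 1e-5, trim -gt 0.85 -cons 30, k range 6..11, BUSCO gate
    2.4/0.60/0.10/0.50/97.00)."""

    meta: str = ""
    fasta_dir: str = ""
    gff_dir: str = ""
    busco_dir: str = ""
    query_table: str | None = None
    queries_fasta: str = ""
    domtbl: list[str] = field(default_factory=list)
    blast_tab: list[str] = field(default_factory=list)
    newick: str | None = None
    out_dir: str = "cytofam_out"
    seed: int = 17
    e_max: float = 1e-5
    gap_open: int = 11
    gap_extend: int = 1
    gt: float = 0.85
    cons: float = 30.0
    min_clust: int = 6
    max_clust: int = 11
    gap_max: int = 20
    window: int = 5
    qc_complete_gt: float = 2.4
    qc_single_ge: float = 0.60
    qc_duplicated_ge: float = 0.10
    qc_fragmented_ge: float = 0.50
    qc_missing_le: float = 97.00
    focal_symbols: list[str] = field(default_factory=lambda: ["IL12RB2"])

    def thresholds(self) -> prep.QcThresholds:
        return prep.QcThresholds(self.qc_complete_gt, self.qc_single_ge,
                                 self.qc_duplicated_ge, self.qc_fragmented_ge,
                                 self.qc_missing_le)


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected by name, missing
    optional keys fall back to the published defaults, and required input
    paths must exist."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    cfg = RunConfig(**doc)
    for key in ("meta", "fasta_dir", "gff_dir", "busco_dir", "queries_fasta"):
        p = getattr(cfg, key)
        if not p:
            raise ConfigError(f"{path}: required key {key!r} missing")
        if not Path(p).exists():
            raise ConfigError(f"{path}: {key}={p!r} does not exist")
    for lst in (cfg.domtbl, cfg.blast_tab):
        for p in lst:
            if not Path(p).exists():
                raise ConfigError(f"{path}: input {p!r} does not exist")
    return cfg


@dataclass
class RunReport:
    parameters: dict
    stages: dict[str, dict] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add_stage(self, name: str, t0: float, **counts) -> None:
        self.stages[name] = {"wall_clock_s": round(time.perf_counter() - t0, 3),
                             **counts}

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(
            {"parameters": self.parameters, "stages": self.stages,
             "warnings": self.warnings}, indent=2) + "\n")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def _read_genome_fasta(path: Path) -> dict[str, str]:
    regions: dict[str, str] = {}
    name, parts = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    regions[name] = "".join(parts)
                name, parts = line[1:].split()[0], []
            elif line:
                parts.append(line)
    if name is not None:
        regions[name] = "".join(parts)
    return regions


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage; outputs under ``config.out_dir``:

    qc.tsv, proteins.faa, calls.tsv, groups.tsv, clusters.tsv,
    profiles.tsv, matches.tsv, dist_groups.tsv, dist_symbols.tsv,
    species_counts.tsv, synteny.tsv, report.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = asdict(config)
    report = RunReport(parameters=params)

    # -- preprocess ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        metas = fio.read_species_meta(config.meta)
        summaries = {}
        for m in metas:
            p = Path(config.busco_dir) / f"short_summary.{m.species_id}.txt"
            if not p.exists():
                raise StageError("preprocess", f"missing BUSCO summary for {m.species_id}")
            summaries[m.species_id] = fio.parse_busco_summary(p)
        retained, rejected = prep.filter_species_by_busco(summaries, config.thresholds())
        with open(out / "qc.tsv", "w") as fh:
            fh.write("species_id\tretained\tfailed_clauses\n")
            for m in metas:
                ok = m.species_id in retained
                clauses = "" if ok else "; ".join(rejected[m.species_id])
                fh.write(f"{m.species_id}\t{ok}\t{clauses}\n")
        genome_store, models = {}, {}
        orphan_total = 0
        for sid in sorted(retained):
            genome_store[sid] = _read_genome_fasta(Path(config.fasta_dir) / f"{sid}.genome.fa")
            models[sid], orphans = fio.read_gff3(Path(config.gff_dir) / f"{sid}.gff3")
            orphan_total += orphans
        proteins, stats = prep.extract_proteins(genome_store, models, retained)
        fio.write_fasta(proteins, out / "proteins.faa")
    except (fio.FormatError, OSError, KeyError) as exc:
        raise StageError("preprocess", str(exc)) from exc
    if orphan_total:
        report.warnings.append(f"{orphan_total} GFF3 features with unresolvable parents dropped")
    if not retained:
        report.warnings.append("no species retained after BUSCO QC; downstream tables empty")
    report.add_stage("preprocess", t0, species_in=len(metas),
                     species_retained=len(retained), proteins=len(proteins),
                     internal_stop_excluded=stats.internal_stop)

    # -- identify -----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        queries = (fio.read_query_table(config.query_table) if config.query_table
                   else fio.load_builtin_queries())
        query_seqs = {r.id: r for r in fio.read_fasta(config.queries_fasta)}
        domain_hits = [h for p in config.domtbl for h in fio.parse_domtblout(p)]
        if config.blast_tab:
            sim_hits = [h for p in config.blast_tab for h in fio.parse_blast_tab(p)]
        else:
            q_records = [query_seqs[q.uniprot_acc] for q in queries
                         if q.uniprot_acc in query_seqs]
            sim_hits = hs.similarity_search(q_records, proteins, config.e_max,
                                            config.gap_open, config.gap_extend)
        calls = hs.call_homologs(proteins, domain_hits, sim_hits, queries)
    except (fio.FormatError, OSError, KeyError) as exc:
        raise StageError("identify", str(exc)) from exc
    with open(out / "calls.tsv", "w") as fh:
        fh.write("protein_id\tspecies_id\tfamily_side\tbest_query_symbol\t"
                 "pct_identity\tevidence\taccepted\n")
        for c in calls:
            fh.write(f"{c.protein_id}\t{c.species_id or ''}\t{c.family_side}\t"
                     f"{c.best_query_symbol}\t{c.pct_identity:.2f}\t{c.evidence}\t"
                     f"{c.accepted}\n")
    accepted = [c for c in calls if c.accepted]
    report.add_stage("identify", t0, proteins=len(proteins), calls=len(calls),
                     accepted=len(accepted), similarity_hits=len(sim_hits),
                     domain_hits=len(domain_hits))

    # -- classify -----------------------------------------------------------
    t0 = time.perf_counter()
    dom_by_protein: dict[str, list[fio.DomainHit]] = {}
    for h in domain_hits:
        dom_by_protein.setdefault(h.protein_id, []).append(h)
    assignments: list[grouping.GroupAssignment] = []
    for c in accepted:
        arch = grouping.build_architecture(dom_by_protein.get(c.protein_id, []))
        arch = grouping.DomainArchitecture(c.protein_id, arch.ordered_domains)
        if c.family_side == "ligand":
            assignments.append(grouping.classify_ligand(arch, c.best_query_symbol))
        else:
            assignments.append(grouping.classify_receptor(arch))
    with open(out / "groups.tsv", "w") as fh:
        fh.write("protein_id\tfamily_side\tgroup\trule_id\n")
        for a in assignments:
            fh.write(f"{a.protein_id}\t{a.family_side}\t{a.group}\t{a.rule_id}\n")
    n_unassigned = sum(a.group == "unassigned" for a in assignments)
    if n_unassigned:
        report.warnings.append(f"{n_unassigned} accepted homologs left unassigned")
    report.add_stage("classify", t0, accepted=len(accepted),
                     assigned=len(assignments) - n_unassigned,
                     unassigned=n_unassigned)

    # -- cluster ------------------------------------------------------------
    t0 = time.perf_counter()
    prot_by_id = {p.id: p for p in proteins}
    cluster_rows = []
    k_by_side = {}
    for side in ("ligand", "receptor"):
        members = [prot_by_id[c.protein_id] for c in accepted
                   if c.family_side == side and c.protein_id in prot_by_id]
        if len(members) < 2:
            report.warnings.append(f"too few accepted {side}s to cluster")
            continue
        rep = grouping.cluster_sequences(members, config.min_clust,
                                         config.max_clust, config.seed)
        report.warnings.extend(f"cluster[{side}]: {w}" for w in rep.warnings)
        k_by_side[side] = rep.k_selected
        for pid, cl in sorted(rep.assignments.items()):
            x, y = rep.coordinates[pid]
            mean_id, med_id = rep.cluster_stats[cl]
            cluster_rows.append((side, pid, cl, f"{x:.4f}", f"{y:.4f}",
                                 f"{mean_id:.2f}", f"{med_id:.2f}"))
    with open(out / "clusters.tsv", "w") as fh:
        fh.write("family_side\tprotein_id\tcluster\tpc1\tpc2\t"
                 "cluster_mean_identity\tcluster_median_identity\n")
        for row in cluster_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    report.add_stage("cluster", t0, clustered=len(cluster_rows), **{
        f"k_{side}": k for side, k in k_by_side.items()})

    # -- conserve -----------------------------------------------------------
    t0 = time.perf_counter()
    sigs, wsxws = cons.load_builtin_signatures()
    group_of = {a.protein_id: a.group for a in assignments}
    side_of = {a.protein_id: a.family_side for a in assignments}
    profile_rows, match_rows = [], []
    group_members: dict[tuple[str, str], list[fio.ProteinRecord]] = {}
    for pid, grp in group_of.items():
        if grp != "unassigned" and pid in prot_by_id:
            group_members.setdefault((side_of[pid], grp), []).append(prot_by_id[pid])
    for (side, grp) in sorted(group_members):
        members = sorted(group_members[(side, grp)], key=lambda r: r.id)
        if len(members) < 2:
            continue
        aln = cons.progressive_align(members, config.gap_open, config.gap_extend)
        trimmed, kept = cons.trim_alignment(aln, config.gt, config.cons)
        for col, prof in enumerate(cons.column_profiles(trimmed)):
            top3 = sorted(zip(cons._AA20, prof.frequencies),
                          key=lambda t: -t[1])[:3]
            profile_rows.append((side, grp, col, kept[col], prof.consensus,
                                 f"{prof.information_bits:.3f}",
                                 f"{prof.gap_fraction:.3f}",
                                 ",".join(a for a, f in top3 if f > 0)))
        for rec in members:
            for sig in sigs:
                for m in cons.scan_signature(rec, sig, config.gap_max):
                    match_rows.append((side, grp, rec.id, m.motif_id,
                                       m.start, m.end, m.matched))
            for m in cons.detect_wsxws(rec):
                match_rows.append((side, grp, rec.id, m.motif_id,
                                   m.start, m.end, m.matched))
    with open(out / "profiles.tsv", "w") as fh:
        fh.write("family_side\tgroup\tcolumn\tsource_column\tconsensus\t"
                 "ic_bits\tgap_fraction\ttop_residues\n")
        for row in profile_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out / "matches.tsv", "w") as fh:
        fh.write("family_side\tgroup\tprotein_id\tmotif_id\tstart\tend\tmatch\n")
        for row in match_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    report.add_stage("conserve", t0, groups_profiled=len(group_members),
                     profile_columns=len(profile_rows),
                     motif_matches=len(match_rows))

    # -- distribute / synteny ----------------------------------------------
    t0 = time.perf_counter()
    if accepted:
        by_group = dist.count_table(calls, metas, groups=group_of)
        by_symbol = dist.count_table(calls, metas)
        by_group.to_csv(out / "dist_groups.tsv", sep="\t")
        by_symbol.to_csv(out / "dist_symbols.tsv", sep="\t")
    else:
        pd.DataFrame().to_csv(out / "dist_groups.tsv", sep="\t")
        pd.DataFrame().to_csv(out / "dist_symbols.tsv", sep="\t")
    counts = dist.per_species_counts(calls, sorted(retained))
    counts.to_csv(out / "species_counts.tsv", sep="\t")
    synteny_frames = []
    for focal in config.focal_symbols:
        hoods = []
        for sid in sorted(retained):
            try:
                hoods.append(dist.neighborhood(models[sid], focal, sid,
                                               config.window))
            except KeyError:
                continue
        if len(hoods) >= 2:
            synteny_frames.append(dist.neighborhood_conservation(hoods))
        else:
            report.warnings.append(f"synteny: focal {focal!r} found in "
                                   f"{len(hoods)} species; skipped")
    syn = (pd.concat(synteny_frames, ignore_index=True) if synteny_frames
           else pd.DataFrame(columns=["species_a", "species_b", "focal",
                                      "shared_score", "adjacency_conserved"]))
    syn.to_csv(out / "synteny.tsv", sep="\t", index=False)
    report.add_stage("distribute", t0, species_rows=len(counts),
                     synteny_pairs=len(syn))

    report.write(out / "report.json")
    return report
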