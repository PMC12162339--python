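"""Self-consistent synthetic study inputs with planted ground truth.

Generates everything the pipeline reads — per-species genome FASTA, GFF3
annotation with multi-isoform gene models, protein FASTA, BUSCO short
summaries, species metadata, a query FASTA — plus a truth table recording,
for every planted protein, its template, group, best-matching query and the
exact coordinates of planted domains and signature motifs.

Each of the ten family templates mirrors one query subunit's architecture
(e.g. the Group V receptor template is Lep_receptor_Ig followed by two fn3).
A species' copy of a template is its master sequence with seeded point
mutations; masters double as the query sequences, so similarity evidence
behaves like a BLASTp search against human queries.  Backgrounds inside
motif-bearing segments avoid the residues that start or terminate a
signature (F, W, V, I, K), which makes every planted signature occurrence
unique by construction and its coordinates exactly recoverable.

One global integer seed determines all output bytes; per-file substreams are
derived by hashing (seed, tags) so file content does not depend on emission
order.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (DomainHit, GeneModel, ProteinRecord, SpeciesMeta,
                         Transcript, write_domtblout, write_fasta, write_gff3,
                         write_species_meta)

__all__ = [
    "SyntheticSpec",
    "GroupTemplate",
    "SyntheticBundle",
    "LIGAND_TEMPLATES",
    "RECEPTOR_TEMPLATES",
    "TEMPLATE_ORDER",
    "generate_species_set",
    "emit_domain_calls",
    "mutate_sequences",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
#: background alphabet inside motif-bearing segments: no residue that can
#: start a signature (F, W, V) or shift a match end (I, K)
_SAFE_AA = "ACDEGHLMNPQRSTY"

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"


def _rng(seed: int, *tags) -> np.random.Generator:
    h = hashlib.sha256(("|".join([str(seed), *map(str, tags)])).encode()).digest()
    return np.random.default_rng(int.from_bytes(h[:4], "big") % (2 ** 31))


def _rand_aa(rng: np.random.Generator, n: int, alphabet: str = _AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=n))


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Segment:
    label: str                 # architecture label or linker name
    pfam_acc: str | None       # emitted as a domain call when set
    length: tuple[int, int]
    signatures: bool = False   # plant the three fn3 signatures
    wsxws: bool = False        # plant one WSXWS pentapeptide


@dataclass(frozen=True)
class GroupTemplate:
    """Planted architecture for one family subunit.

    ``domain_layout`` is the ordered segment plan; segments with a Pfam
    accession become domain calls, linker/undetected segments do not (the
    Group I ligand's C-terminal fn3-like region deliberately has none: its
    signatures are present but no fn3 model detects it).
    """

    template_id: str
    query_symbol: str
    uniprot_acc: str
    family_side: str
    truth_group: str
    domain_layout: tuple[_Segment, ...]

    def __post_init__(self) -> None:
        self._check_consistency()

    def _check_consistency(self) -> None:
        """Self-check: the layout must classify to ``truth_group``."""
        from .family_grouping import (DomainArchitecture, classify_ligand,
                                      classify_receptor)
        from .family_grouping import PFAM_LABELS
        from .formats_io import strip_version
        pos, doms = 1, []
        for seg in self.domain_layout:
            end = pos + seg.length[0] - 1
            if seg.pfam_acc:
                doms.append((PFAM_LABELS.get(strip_version(seg.pfam_acc), "other"),
                             pos, end))
            pos = end + 1
        arch = DomainArchitecture("self_check", tuple(doms))
        if self.family_side == "ligand":
            got = classify_ligand(arch, self.query_symbol).group
        else:
            got = classify_receptor(arch).group
        if got != self.truth_group:
            raise ValueError(
                f"template {self.template_id}: layout classifies to {got}, "
                f"declared {self.truth_group}")


LIGAND_TEMPLATES = (
    GroupTemplate("lig_p40", "IL12B", "P29460", "ligand", "I", (
        _Segment("leader", None, (18, 24)),
        _Segment("IL12p40_C", "PF10420.14", (95, 110)),
        _Segment("fn3_like", None, (95, 105), signatures=True),
    )),
    GroupTemplate("lig_EBI3", "EBI3", "Q14213", "ligand", "II", (
        _Segment("leader", None, (18, 24)),
        _Segment("Ig-like", "PF07679.16", (80, 90)),
        _Segment("fn3", "PF00041.26", (95, 105), signatures=True),
    )),
    GroupTemplate("lig_p35", "IL12A", "P29459", "ligand", "III", (
        _Segment("leader", None, (18, 24)),
        _Segment("IL12", "PF03039.19", (170, 190)),
    )),
    GroupTemplate("lig_p19", "IL23A", "Q9NPF7", "ligand", "IV", (
        _Segment("leader", None, (18, 24)),
        _Segment("IL23", "PF16649.10", (150, 170)),
    )),
    GroupTemplate("lig_p28", "IL27", "Q8NEV9", "ligand", "V", (
        _Segment("leader", None, (18, 24)),
        _Segment("helix_bundle", None, (190, 220)),
    )),
)

RECEPTOR_TEMPLATES = (
    GroupTemplate("rec_IL12RB1", "IL12RB1", "P42701", "receptor", "I", (
        _Segment("leader", None, (18, 24)),
        _Segment("fn3", "PF00041.26", (95, 105), wsxws=True),
    )),
    GroupTemplate("rec_WSX1", "IL27RA", "Q6UWB1", "receptor", "II", (
        _Segment("leader", None, (18, 24)),
        _Segment("Ig-like", "PF07679.16", (80, 90)),
        _Segment("fn3", "PF00041.26", (95, 105)),
        _Segment("fn3", "PF00041.26", (95, 105), wsxws=True),
    )),
    GroupTemplate("rec_gp130", "IL6ST", "P40189", "receptor", "III", (
        _Segment("leader", None, (18, 24)),
        _Segment("Lep_receptor_Ig", "PF06328.16", (95, 110)),
        _Segment("IL6Ra-bind", "PF09240.15", (85, 100)),
        _Segment("fn3", "PF00041.26", (95, 105), wsxws=True),
    )),
    GroupTemplate("rec_IL12RB2", "IL12RB2", "Q99665", "receptor", "V", (
        _Segment("leader", None, (18, 24)),
        _Segment("Lep_receptor_Ig", "PF06328.16", (95, 110)),
        _Segment("fn3", "PF00041.26", (95, 105)),
        _Segment("fn3", "PF00041.26", (95, 105), wsxws=True),
    )),
    GroupTemplate("rec_IL23R", "IL23R", "Q5VWK5", "receptor", "IV", (
        _Segment("leader", None, (18, 24)),
        _Segment("IL6Ra-bind", "PF09240.15", (85, 100)),
        _Segment("stalk", None, (25, 35), wsxws=True),
    )),
)

#: gene order on each synthetic contig; IL12RB2 immediately precedes IL23R so
#: the published receptor adjacency is planted for the synteny stage
TEMPLATE_ORDER = LIGAND_TEMPLATES + RECEPTOR_TEMPLATES
_TEMPLATES_BY_ID = {t.template_id: t for t in TEMPLATE_ORDER}

_DEFAULT_CLASSES = {"Mammalia": 3, "Aves": 2, "Actinopteri": 2,
                    "Lepidosauria": 1, "Reptilia": 1}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic corpus.

    Defaults: 9 species over 5 taxonomic Classes, 12 genes per species (one
    copy of each of the ten family templates plus two decoys), 10% point
    mutations relative to the query masters, and up to two isoforms per gene.
    """

    classes: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_CLASSES))
    genes_per_species: int = 12
    architecture_mix: Mapping[str, float] | None = None
    decoy_fraction: float = 1.0 / 6.0
    point_mutation_rate: float = 0.1
    isoforms_per_gene: tuple[int, int] = (1, 2)
    seed: int = 0
    failing_species: int = 0  # extra species built to fail the BUSCO gate

    def __post_init__(self) -> None:
        mix = self.mix
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("architecture_mix proportions must sum to 1")
        for name in ("decoy_fraction", "point_mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        unknown = set(mix) - set(_TEMPLATES_BY_ID)
        if unknown:
            raise ValueError(f"unknown templates in mix: {sorted(unknown)}")

    @property
    def mix(self) -> dict[str, float]:
        if self.architecture_mix is not None:
            return dict(self.architecture_mix)
        n = len(TEMPLATE_ORDER)
        return {t.template_id: 1.0 / n for t in TEMPLATE_ORDER}


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------

@dataclass
class _Master:
    template: GroupTemplate
    seq: str
    domains: list[tuple[str, str, int, int]]      # (label, acc, start, end) 1-based
    motifs: list[tuple[str, int, int]]            # (motif_id, start, end) 1-based
    mask: set[int]                                # 0-based anchor positions


def _plant_signatures(rng: np.random.Generator, length: int
                      ) -> tuple[str, list[tuple[str, int, int]], set[int]]:
    """A motif segment: safe background with the three signatures embedded."""
    from .conservation_signatures import load_builtin_signatures  # cycle-free
    seg = list(_rand_aa(rng, length, _SAFE_AA))
    motifs, mask = [], set()
    sigs, _ = load_builtin_signatures()
    pos = 2
    for sig in sigs:
        start = pos
        p = pos
        for i, anchor in enumerate(sig.anchors):
            alt = anchor[0]  # plant the first alternative (K for K/F)
            if p + len(alt) > length:
                raise ValueError(f"segment length {length} too short for signatures")
            for k, ch in enumerate(alt):
                seg[p + k] = ch
                mask.add(p + k)
            p += len(alt)
            if i < len(sig.anchors) - 1:
                p += int(rng.integers(2, 6))  # gap of 2..5 residues
        motifs.append((sig.motif_id, start + 1, p))
        pos = p + int(rng.integers(3, 6))
    return "".join(seg), motifs, mask


def _plant_wsxws(rng: np.random.Generator, length: int
                 ) -> tuple[str, list[tuple[str, int, int]], set[int]]:
    seg = list(_rand_aa(rng, length, _SAFE_AA))
    start = length - 12  # keep the hallmark near the segment's C-terminus
    block = "WS" + str(rng.choice(list(_SAFE_AA))) + "WS"
    for k, ch in enumerate(block):
        seg[start + k] = ch
    mask = {start + k for k in range(5)}
    return "".join(seg), [("WSXWS", start + 1, start + 5)], mask


def _build_master(template: GroupTemplate, seed: int) -> _Master:
    rng = _rng(seed, "master", template.template_id)
    parts: list[str] = []
    domains, motifs, mask = [], [], set()
    offset = 0
    # motif-bearing templates use the safe alphabet everywhere, so residues
    # that can start or end a signature occur only at planted positions
    plants_motifs = any(s.signatures or s.wsxws for s in template.domain_layout)
    background = _SAFE_AA if plants_motifs else _AA20
    for seg in template.domain_layout:
        length = int(rng.integers(seg.length[0], seg.length[1] + 1))
        if seg.signatures:
            text, segmotifs, segmask = _plant_signatures(rng, length)
        elif seg.wsxws:
            text, segmotifs, segmask = _plant_wsxws(rng, length)
        else:
            text, segmotifs, segmask = _rand_aa(rng, length, background), [], set()
        parts.append(text)
        if seg.pfam_acc:
            domains.append((seg.label, seg.pfam_acc, offset + 1, offset + length))
        motifs.extend((mid, offset + s, offset + e) for mid, s, e in segmotifs)
        mask.update(offset + i for i in segmask)
        offset += length
    return _Master(template, "".join(parts), domains, motifs, mask)


@dataclass
class _PlannedGene:
    gene_id: str
    symbol: str
    template_id: str | None       # None for decoys
    family_side: str
    truth_group: str
    query_symbol: str
    protein: str
    mask: set[int]
    domains: list[tuple[str, str, int, int]]
    motifs: list[tuple[str, int, int]]
    strand: str
    n_isoforms: int


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            mask: set[int] | None = None, corrupt_motifs: bool = False) -> str:
    if rate <= 0.0:
        return seq
    out = list(seq)
    hits = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hits):
        if not corrupt_motifs and mask and int(i) in mask:
            continue
        choices = [a for a in _AA20 if a != out[i]]
        out[i] = choices[int(rng.integers(0, len(choices)))]
    return "".join(out)


def _template_counts(mix: Mapping[str, float], n_planted: int) -> dict[str, int]:
    """Largest-remainder apportionment in template order."""
    order = [t.template_id for t in TEMPLATE_ORDER if mix.get(t.template_id, 0) > 0]
    base = {tid: int(math.floor(mix[tid] * n_planted)) for tid in order}
    short = n_planted - sum(base.values())
    frac = sorted(order, key=lambda tid: (-(mix[tid] * n_planted
                                            - base[tid]), order.index(tid)))
    for tid in frac[:short]:
        base[tid] += 1
    return base


def _plan_species(spec: SyntheticSpec, species_id: str,
                  masters: Mapping[str, _Master]) -> list[_PlannedGene]:
    rng = _rng(spec.seed, "species", species_id)
    n_decoys = int(math.floor(spec.genes_per_species * spec.decoy_fraction + 0.5))
    n_planted = spec.genes_per_species - n_decoys
    counts = _template_counts(spec.mix, n_planted)
    genes: list[_PlannedGene] = []
    idx = 0
    for template in TEMPLATE_ORDER:
        for copy in range(counts.get(template.template_id, 0)):
            master = masters[template.template_id]
            seq = _mutate(master.seq, spec.point_mutation_rate,
                          _rng(spec.seed, "mut", species_id, template.template_id, copy),
                          master.mask)
            lo, hi = spec.isoforms_per_gene
            n_iso = int(rng.integers(lo, hi + 1)) if hi > lo else lo
            suffix = f"_{copy + 1}" if counts[template.template_id] > 1 else ""
            genes.append(_PlannedGene(
                f"{species_id}_g{idx:03d}", template.query_symbol + suffix,
                template.template_id, template.family_side,
                template.truth_group, template.query_symbol,
                seq, set(master.mask), list(master.domains),
                list(master.motifs), "+" if idx % 2 == 0 else "-", n_iso))
            idx += 1
    for d in range(n_decoys):
        drng = _rng(spec.seed, "decoy", species_id, d)
        seq = _rand_aa(drng, int(drng.integers(150, 301)))
        genes.append(_PlannedGene(
            f"{species_id}_g{idx:03d}", f"DEC{d + 1}_{species_id}",
            None, "", "none", "", seq, set(), [], [],
            "+" if idx % 2 == 0 else "-", 1))
        idx += 1
    return genes


# ---------------------------------------------------------------------------
# Realization: contigs, gene models, files
# ---------------------------------------------------------------------------

def _backtranslate(protein: str) -> str:
    return "".join(_CODON[a] for a in protein) + _STOP


def _revcomp(nt: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[c] for c in reversed(nt))


def _realize_species(spec: SyntheticSpec, species_id: str,
                     genes: Sequence[_PlannedGene]
                     ) -> tuple[dict[str, str], list[GeneModel],
                                list[ProteinRecord]]:
    """Lay the planned genes on one contig; derive models and proteins."""
    rng = _rng(spec.seed, "layout", species_id)
    contig_parts: list[str] = []
    pos = 0  # 0-based length so far
    models: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    region = "chr1"
    for gi, g in enumerate(genes):
        spacer = "".join(rng.choice(list("ACGT"), size=int(rng.integers(80, 121))))
        contig_parts.append(spacer)
        pos += len(spacer)
        cds = _backtranslate(g.protein)
        nexons = 2 + (gi % 2)
        cut_points = sorted({int(round(len(cds) * (k + 1) / nexons))
                             for k in range(nexons - 1)})
        bounds = [0, *cut_points, len(cds)]
        exons = [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
                 if bounds[i + 1] > bounds[i]]
        intron_len = 47  # deliberately not a codon multiple
        # transcribed block: exon,intron,exon,...
        block_parts, exon_offsets = [], []
        boff = 0
        for k, (a, b) in enumerate(exons):
            if k:
                intr = "".join(rng.choice(list("ACGT"), size=intron_len))
                block_parts.append(intr)
                boff += intron_len
            block_parts.append(cds[a:b])
            exon_offsets.append((boff, boff + (b - a)))
            boff += b - a
        block = "".join(block_parts)
        B = len(block)
        if g.strand == "+":
            segs = [(pos + a + 1, pos + b) for a, b in exon_offsets]
            contig_parts.append(block)
        else:
            segs = [(pos + B - b + 1, pos + B - a) for a, b in exon_offsets]
            contig_parts.append(_revcomp(block))
        # phases in transcription order
        phases, cum = [], 0
        for a, b in exon_offsets:
            phases.append((3 - cum % 3) % 3 if cum % 3 else 0)
            cum += b - a
        transcripts = [Transcript(f"{g.gene_id}.t1", tuple(segs), tuple(phases))]
        if g.n_isoforms > 1:
            l2 = 3 * max(1, int(0.6 * len(g.protein)))  # shorter, codon-aligned
            segs2, ph2, need = [], [], l2
            for (s, e), ph, (a, b) in zip(segs, phases, exon_offsets):
                take = min(need, b - a)
                if take <= 0:
                    break
                if g.strand == "+":
                    segs2.append((s, s + take - 1))
                else:
                    segs2.append((e - take + 1, e))
                ph2.append(ph)
                need -= take
            transcripts.append(Transcript(f"{g.gene_id}.t2", tuple(segs2), tuple(ph2)))
        models.append(GeneModel(g.gene_id, region, g.strand,
                                tuple(transcripts), g.symbol))
        proteins.append(ProteinRecord(f"{g.gene_id}.t1", g.protein,
                                      f"species={species_id} gene={g.gene_id}",
                                      species_id))
        if g.n_isoforms > 1:
            proteins.append(ProteinRecord(
                f"{g.gene_id}.t2", g.protein[:l2 // 3],
                f"species={species_id} gene={g.gene_id} isoform=secondary",
                species_id))
        pos += B
    tail = "".join(rng.choice(list("ACGT"), size=100))
    contig_parts.append(tail)
    return {region: "".join(contig_parts)}, models, proteins


def _busco_summary_text(rng: np.random.Generator, species_id: str,
                        fail: bool) -> str:
    if fail:
        c, s, d, f, m = 1.8, 1.5, 0.3, 0.2, 98.0
    else:
        c = round(float(rng.uniform(88.0, 96.5)), 1)  # leaves room for F + M ≥ 0
        d = round(float(rng.uniform(1.0, 6.0)), 1)
        s = round(c - d, 1)
        f = round(float(rng.uniform(0.6, 2.0)), 1)
        m = round(100.0 - c - f, 1)
    return (
        f"# BUSCO version is: 5.4.7\n"
        f"# Summarized benchmarking in BUSCO notation for species {species_id}\n"
        f"\t***** Results: *****\n\n"
        f"\tC:{c}%[S:{s}%,D:{d}%],F:{f}%,M:{m}%,n:9226\n"
    )


@dataclass
class SyntheticBundle:
    """All paths and in-memory ground truth of one generated corpus."""

    root: Path
    spec: SyntheticSpec
    metas: list[SpeciesMeta]
    truth: pd.DataFrame
    queries: list[ProteinRecord]
    genome_paths: dict[str, Path]
    gff_paths: dict[str, Path]
    protein_paths: dict[str, Path]
    busco_paths: dict[str, Path]
    meta_path: Path
    truth_path: Path
    queries_path: Path
    domtbl_path: Path | None = None
    planned: dict[str, list[_PlannedGene]] = field(default_factory=dict, repr=False)

    @property
    def species_ids(self) -> list[str]:
        return [m.species_id for m in self.metas]


_CLASS_ABBR = {"Mammalia": "mam", "Aves": "ave", "Actinopteri": "act",
               "Lepidosauria": "lep", "Reptilia": "rep",
               "Chondrichthyes": "cho", "Cladistia": "cla",
               "Leptocardii": "lpc", "Other": "oth"}


def generate_species_set(spec: SyntheticSpec, out_dir: str | Path) -> SyntheticBundle:
    """Write a complete synthetic corpus under ``out_dir``.

    Identical specs produce byte-identical bundles.  The truth table has one
    row per gene with the planted group, query symbol and domain/motif
    coordinates on the primary (longest) isoform; decoys carry
    ``truth_group=none``.
    """
    root = Path(out_dir)
    for sub in ("fasta", "gff", "proteins", "busco"):
        (root / sub).mkdir(parents=True, exist_ok=True)

    masters = {t.template_id: _build_master(t, spec.seed) for t in TEMPLATE_ORDER}
    queries = [ProteinRecord(t.uniprot_acc, masters[t.template_id].seq,
                             f"{t.query_symbol} synthetic query master")
               for t in TEMPLATE_ORDER]
    queries_path = root / "queries.faa"
    write_fasta(queries, queries_path)

    metas: list[SpeciesMeta] = []
    for cls in sorted(spec.classes):
        for i in range(spec.classes[cls]):
            sid = f"{_CLASS_ABBR.get(cls, 'oth')}{i + 1}"
            metas.append(SpeciesMeta(sid, f"Synthia {cls.lower()} {i + 1}", cls,
                                     "synthetic"))
    for i in range(spec.failing_species):
        metas.append(SpeciesMeta(f"bad{i + 1}", f"Synthia degraded {i + 1}",
                                 "Other", "synthetic"))
    fail_ids = {f"bad{i + 1}" for i in range(spec.failing_species)}

    genome_paths, gff_paths, protein_paths, busco_paths = {}, {}, {}, {}
    planned: dict[str, list[_PlannedGene]] = {}
    truth_rows = []
    for meta in metas:
        sid = meta.species_id
        genes = _plan_species(spec, sid, masters)
        planned[sid] = genes
        genomes, models, proteins = _realize_species(spec, sid, genes)
        genome_paths[sid] = root / "fasta" / f"{sid}.genome.fa"
        with open(genome_paths[sid], "w") as fh:
            for region, seq in genomes.items():
                fh.write(f">{region}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k:k + 60] + "\n")
        gff_paths[sid] = root / "gff" / f"{sid}.gff3"
        write_gff3(models, gff_paths[sid])
        protein_paths[sid] = root / "proteins" / f"{sid}.faa"
        write_fasta(proteins, protein_paths[sid])
        busco_paths[sid] = root / "busco" / f"short_summary.{sid}.txt"
        busco_paths[sid].write_text(
            _busco_summary_text(_rng(spec.seed, "busco", sid), sid,
                                sid in fail_ids))
        for g in genes:
            truth_rows.append({
                "species_id": sid,
                "taxon_class": meta.taxon_class,
                "gene_id": g.gene_id,
                "transcript_id": f"{g.gene_id}.t1",
                "protein_id": f"{g.gene_id}.t1",
                "symbol": g.symbol,
                "template_id": g.template_id or "",
                "family_side": g.family_side,
                "truth_group": g.truth_group,
                "truth_query_symbol": g.query_symbol,
                "is_decoy": g.template_id is None,
                "protein_length": len(g.protein),
                "n_isoforms": g.n_isoforms,
                "domains": ";".join(f"{lab}:{acc}:{s}-{e}"
                                    for lab, acc, s, e in g.domains),
                "motifs": ";".join(f"{mid}:{s}-{e}" for mid, s, e in g.motifs),
            })

    columns = ["species_id", "taxon_class", "gene_id", "transcript_id",
               "protein_id", "symbol", "template_id", "family_side",
               "truth_group", "truth_query_symbol", "is_decoy",
               "protein_length", "n_isoforms", "domains", "motifs"]
    truth = pd.DataFrame(truth_rows, columns=columns)
    meta_path = root / "meta.tsv"
    write_species_meta(metas, meta_path)
    truth_path = root / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return SyntheticBundle(root, spec, metas, truth, queries, genome_paths,
                           gff_paths, protein_paths, busco_paths, meta_path,
                           truth_path, queries_path, None, planned)


def emit_domain_calls(bundle: SyntheticBundle, path: str | Path | None = None) -> Path:
    """Write a domtblout file reflecting the planted domain layouts.

    Rows mirror the truth table exactly (coordinates on the primary isoform),
    so the pipeline can run end-to-end without an external hmmscan.  Decoys
    get no rows.
    """
    path = Path(path) if path else bundle.root / "domains.domtblout"
    hits: list[DomainHit] = []
    lengths: dict[str, int] = {}
    for sid in bundle.species_ids:
        for g in bundle.planned.get(sid, []):
            pid = f"{g.gene_id}.t1"
            lengths[pid] = len(g.protein)
            for lab, acc, s, e in g.domains:
                hits.append(DomainHit(pid, acc, s, e, score=150.0,
                                      evalue=1e-30, domain_name=lab))
    write_domtblout(hits, path, lengths)
    bundle.domtbl_path = path
    return path


def mutate_sequences(bundle: SyntheticBundle, rate: float, seed: int,
                     out_dir: str | Path | None = None,
                     corrupt_motifs: bool = False) -> SyntheticBundle:
    """Apply additional residue-wise substitutions to every planted protein.

    Substitutions hit each residue independently with probability ``rate``
    but never land on planted motif anchors unless ``corrupt_motifs`` is set.
    The corpus is re-realized (genomes, GFF3, proteins) in ``out_dir`` so the
    files stay self-consistent.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate outside [0, 1]")
    out = Path(out_dir) if out_dir else bundle.root.parent / (bundle.root.name + "_mut")
    new_bundle = generate_species_set(bundle.spec, out)
    for sid in new_bundle.species_ids:
        genes = []
        for g in bundle.planned[sid]:
            rng = _rng(seed, "extra-mut", sid, g.gene_id)
            genes.append(replace(g, protein=_mutate(g.protein, rate, rng,
                                                    g.mask, corrupt_motifs)))
        new_bundle.planned[sid] = genes
        genomes, models, proteins = _realize_species(bundle.spec, sid, genes)
        with open(new_bundle.genome_paths[sid], "w") as fh:
            for region, seq in genomes.items():
                fh.write(f">{region}\n")
                for k in range(0, len(seq), 60):
                    fh.write(seq[k:k + 60] + "\n")
        write_gff3(models, new_bundle.gff_paths[sid])
        write_fasta(proteins, new_bundle.protein_paths[sid])
    return new_bundle
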