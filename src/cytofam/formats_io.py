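"""Readers and writers for the external formats the pipeline touches.

Every reader validates strictly and raises :class:`FormatError` on malformed
input rather than propagating half-parsed records downstream.  Coordinates are
1-based inclusive throughout, matching GFF3 and HMMER conventions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ProteinRecord",
    "SpeciesMeta",
    "BuscoSummary",
    "QueryDef",
    "Transcript",
    "GeneModel",
    "DomainHit",
    "SimilarityHit",
    "TAXON_CLASSES",
    "strip_version",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "parse_busco_summary",
    "parse_domtblout",
    "write_domtblout",
    "parse_blast_tab",
    "write_blast_tab",
    "read_query_table",
    "load_builtin_queries",
    "read_species_meta",
    "write_species_meta",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


#: Closed set of taxonomic Classes used for distribution summaries; unknown
#: labels are coerced to "Other".
TAXON_CLASSES = (
    "Mammalia",
    "Aves",
    "Actinopteri",
    "Lepidosauria",
    "Reptilia",
    "Chondrichthyes",
    "Cladistia",
    "Leptocardii",
    "Other",
)

_AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}


def strip_version(acc: str) -> str:
    """Version-insensitive Pfam comparison key: ``PF00041.26`` → ``PF00041``."""
    return acc.split(".", 1)[0]


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identity.

    ``id`` is the first whitespace-delimited token of the FASTA header; the
    remainder is kept as ``description`` but never used as a key.
    """

    id: str
    seq: str
    description: str = ""
    species_id: str | None = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class SpeciesMeta:
    species_id: str
    species_name: str
    taxon_class: str
    source: str = ""

    def __post_init__(self) -> None:
        if self.taxon_class not in TAXON_CLASSES:
            object.__setattr__(self, "taxon_class", "Other")


@dataclass(frozen=True)
class BuscoSummary:
    """Five-number genome completeness summary (percent of BUSCO orthologs)."""

    complete_pct: float
    single_pct: float
    duplicated_pct: float
    fragmented_pct: float
    missing_pct: float

    def __post_init__(self) -> None:
        for name in ("complete_pct", "single_pct", "duplicated_pct",
                     "fragmented_pct", "missing_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise FormatError(f"BUSCO {name}={v} outside [0, 100]")


@dataclass(frozen=True)
class QueryDef:
    """One human query subunit used for family identification.

    Queries whose Pfam domain column is empty ("-" in the reference table)
    are ``blast_only``: they are assigned to subfamilies exclusively through
    similarity evidence.
    """

    uniprot_acc: str
    gene_symbol: str
    subunit_name: str
    required_domains: tuple[str, ...]
    family_side: str

    def __post_init__(self) -> None:
        if self.family_side not in ("ligand", "receptor"):
            raise FormatError(f"unknown family_side {self.family_side!r}")

    @property
    def blast_only(self) -> bool:
        return len(self.required_domains) == 0


@dataclass(frozen=True)
class Transcript:
    """Ordered CDS segments of one transcript, in transcription order.

    Segments are 1-based inclusive ``(start, end)`` genomic intervals; for a
    minus-strand gene they are sorted by descending coordinate.  ``phases``
    holds the GFF3 phase of each segment (0 when unannotated).
    """

    transcript_id: str
    cds_segments: tuple[tuple[int, int], ...]
    phases: tuple[int, ...] = ()

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    seq_region: str
    strand: str
    transcripts: tuple[Transcript, ...]
    symbol: str | None = None

    @property
    def start(self) -> int:
        return min(s for t in self.transcripts for s, _ in t.cds_segments)

    @property
    def end(self) -> int:
        return max(e for t in self.transcripts for _, e in t.cds_segments)


@dataclass(frozen=True)
class DomainHit:
    protein_id: str
    domain_acc: str
    start: int
    end: int
    score: float
    evalue: float
    domain_name: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"domain hit {self.domain_acc} on {self.protein_id}: "
                f"invalid interval [{self.start}, {self.end}]")
        if self.evalue < 0:
            raise FormatError("negative E-value")

    @property
    def acc_key(self) -> str:
        return strip_version(self.domain_acc)


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise FormatError(f"pct_identity {self.pct_identity} outside [0,100]")
        if self.evalue < 0:
            raise FormatError("negative E-value")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, species_id: str | None = None) -> list[ProteinRecord]:
    """Read a protein FASTA.

    Trailing stop codons (``*``) are stripped; duplicate identifiers and empty
    sequences are format errors, as are residues outside the 20-letter amino
    acid alphabet plus ``X`` and ``*``.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if not seq:
            raise FormatError(f"{path}: empty sequence for {rec.id!r}")
        bad = set(seq) - _AA_ALPHABET
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has residues outside the protein "
                f"alphabet: {sorted(bad)}")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(rec.id, seq, desc, species_id))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records with 60-column wrapping and uppercase sequences."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            seq = rec.seq.upper()
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_STRANDS = {"+", "-"}


def _gff_attrs(col: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in col.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3(path: str | Path) -> tuple[list[GeneModel], int]:
    """Assemble gene models from a GFF3 annotation.

    Returns ``(models, orphan_count)`` where ``orphan_count`` tallies mRNA/CDS
    features whose Parent could not be resolved; such features are dropped
    rather than fatal, since real annotations routinely need repair.
    CDS segments are ordered in transcription order (descending coordinates on
    the minus strand) and carry their GFF3 phase.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    mrna_order: list[str] = []
    cds_rows: list[tuple[str, int, int, int]] = []
    orphans = 0

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _src, ftype, start_s, end_s, _score, strand, phase_s, attr_s = cols
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if ftype in ("gene", "mRNA", "CDS") and strand not in _STRANDS:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if ftype == "CDS" and end < start:
                raise FormatError(f"{path}:{lineno}: CDS end {end} < start {start}")
            attrs = _gff_attrs(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "seq_region": seqid,
                    "strand": strand,
                    "symbol": attrs.get("Name") or attrs.get("gene_name"),
                    "mrnas": {},
                }
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid is None:
                    raise FormatError(f"{path}:{lineno}: mRNA without ID")
                if parent is None or parent not in genes:
                    orphans += 1
                    continue
                mrna_parent[mid] = parent
                mrna_order.append(mid)
            elif ftype == "CDS":
                parent = attrs.get("Parent")
                phase = int(phase_s) if phase_s in ("0", "1", "2") else 0
                if parent is None:
                    orphans += 1
                    continue
                cds_rows.append((parent, start, end, phase))

    cds_by_mrna: dict[str, list[tuple[int, int, int]]] = {}
    for parent, start, end, phase in cds_rows:
        if parent not in mrna_parent:
            orphans += 1
            continue
        cds_by_mrna.setdefault(parent, []).append((start, end, phase))

    models: list[GeneModel] = []
    for gid, info in genes.items():
        transcripts = []
        for mid in mrna_order:
            if mrna_parent.get(mid) != gid or mid not in cds_by_mrna:
                continue
            segs = sorted(cds_by_mrna[mid], reverse=(info["strand"] == "-"))
            transcripts.append(Transcript(
                mid,
                tuple((s, e) for s, e, _ in segs),
                tuple(p for _, _, p in segs),
            ))
        if transcripts:
            models.append(GeneModel(gid, info["seq_region"], info["strand"],
                                    tuple(transcripts), info["symbol"]))
    return models, orphans


def write_gff3(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in models:
            attrs = f"ID={gm.gene_id}"
            if gm.symbol:
                attrs += f";Name={gm.symbol}"
            fh.write("\t".join([gm.seq_region, "cytofam", "gene", str(gm.start),
                                str(gm.end), ".", gm.strand, ".", attrs]) + "\n")
            for tr in gm.transcripts:
                t_start = min(s for s, _ in tr.cds_segments)
                t_end = max(e for _, e in tr.cds_segments)
                fh.write("\t".join([gm.seq_region, "cytofam", "mRNA", str(t_start),
                                    str(t_end), ".", gm.strand, ".",
                                    f"ID={tr.transcript_id};Parent={gm.gene_id}"]) + "\n")
                phases = tr.phases or (0,) * len(tr.cds_segments)
                for (s, e), ph in zip(tr.cds_segments, phases):
                    fh.write("\t".join([gm.seq_region, "cytofam", "CDS", str(s),
                                        str(e), ".", gm.strand, str(ph),
                                        f"Parent={tr.transcript_id}"]) + "\n")


# ---------------------------------------------------------------------------
# BUSCO short summary
# ---------------------------------------------------------------------------

_BUSCO_RE = re.compile(
    r"C:\s*([\d.]+)%\s*\[\s*S:\s*([\d.]+)%\s*,\s*D:\s*([\d.]+)%\s*\]\s*,"
    r"\s*F:\s*([\d.]+)%\s*,\s*M:\s*([\d.]+)%")


def parse_busco_summary(path: str | Path) -> BuscoSummary:
    """Extract the five percentages from a BUSCO v5 short-summary text."""
    text = Path(path).read_text()
    m = _BUSCO_RE.search(text)
    if m is None:
        raise FormatError(f"{path}: no BUSCO summary line (C:..%[S:..%,D:..%],F:..%,M:..%)")
    c, s, d, f, miss = (float(g) for g in m.groups())
    return BuscoSummary(c, s, d, f, miss)


# ---------------------------------------------------------------------------
# HMMER3 domtblout
# ---------------------------------------------------------------------------

# column layout of a domtblout row (whitespace-delimited, 23 fixed columns
# then free-text description); envelope coordinates are columns 20-21.
_DOMTBL_NCOL = 23


def parse_domtblout(path: str | Path) -> list[DomainHit]:
    """Parse HMMER3 ``--domtblout`` output into one hit per domain row.

    Envelope coordinates (``env from``/``env to``) are used as the domain
    interval.  Comment lines are ignored; a row with fewer than the fixed 23
    columns is a format error.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < _DOMTBL_NCOL:
                raise FormatError(
                    f"{path}:{lineno}: expected ≥{_DOMTBL_NCOL} columns, got {len(cols)}")
            try:
                hits.append(DomainHit(
                    protein_id=cols[3],
                    domain_acc=cols[1],
                    start=int(cols[19]),
                    end=int(cols[20]),
                    score=float(cols[13]),
                    evalue=float(cols[12]),
                    domain_name=cols[0],
                ))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_domtblout(hits: Sequence[DomainHit], path: str | Path,
                    protein_lengths: dict[str, int] | None = None) -> None:
    """Emit hits in domtblout layout (one row per domain, envelope = ali = hmm span)."""
    protein_lengths = protein_lengths or {}
    per_protein: dict[str, list[DomainHit]] = {}
    for h in hits:
        per_protein.setdefault(h.protein_id, []).append(h)
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  acc "
                 "description of target\n#\n")
        for pid in per_protein:
            rows = per_protein[pid]
            n = len(rows)
            for i, h in enumerate(rows, 1):
                tlen = h.end - h.start + 1
                qlen = protein_lengths.get(pid, 0)
                fh.write(" ".join(str(x) for x in [
                    h.domain_name or strip_version(h.domain_acc), h.domain_acc,
                    tlen, pid, "-", qlen,
                    f"{h.evalue:.2g}", f"{h.score:.1f}", "0.0",
                    i, n, f"{h.evalue:.2g}", f"{h.evalue:.2g}",
                    f"{h.score:.1f}", "0.0",
                    1, tlen, h.start, h.end, h.start, h.end, "0.99", "-",
                ]) + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)
# ---------------------------------------------------------------------------

_BLAST_COLS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
               "qstart", "qend", "sstart", "send", "evalue", "bitscore"]


def parse_blast_tab(path: str | Path) -> list[SimilarityHit]:
    """Parse 12-column BLAST tabular output (``-outfmt 6``) in file order."""
    try:
        df = pd.read_csv(path, sep="\t", names=_BLAST_COLS, header=None,
                         comment="#", dtype={"qseqid": str, "sseqid": str})
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    if df.shape[1] != 12:
        raise FormatError(f"{path}: expected 12 tab-separated columns")
    for col in ("pident", "evalue", "bitscore"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), col].iloc[0]
            raise FormatError(f"{path}: non-numeric {col} value {bad!r}")
        df[col] = vals
    return [
        SimilarityHit(r.qseqid, r.sseqid, float(r.pident), int(r.length),
                      float(r.evalue), float(r.bitscore))
        for r in df.itertuples(index=False)
    ]


def write_blast_tab(hits: Sequence[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join([
                h.query_id, h.subject_id, f"{h.pct_identity:.2f}", str(h.aln_len),
                "0", "0", "1", str(h.aln_len), "1", str(h.aln_len),
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Query table and species metadata
# ---------------------------------------------------------------------------

def read_query_table(path: str | Path) -> list[QueryDef]:
    """Read the query-definition table (TSV with a header row).

    Columns: accession, gene_symbol, protein_name, domains (semicolon-
    separated Pfam accessions, empty or ``-`` for none), family_side.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"accession", "gene_symbol", "protein_name", "domains", "family_side"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        doms = tuple(d.strip() for d in r.domains.split(";")
                     if d.strip() and d.strip() != "-")
        out.append(QueryDef(r.accession, r.gene_symbol, r.protein_name,
                            doms, r.family_side))
    return out


def load_builtin_queries() -> list[QueryDef]:
    """The bundled ten-query human IL-12s/IL-12Rs definition table."""
    ref = resources.files("cytofam.data") / "queries.tsv"
    with resources.as_file(ref) as path:
        return read_query_table(path)


def read_species_meta(path: str | Path) -> list[SpeciesMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"species_id", "species_name", "taxon_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    metas, seen = [], set()
    for r in df.itertuples(index=False):
        if r.species_id in seen:
            raise FormatError(f"{path}: duplicate species_id {r.species_id!r}")
        seen.add(r.species_id)
        metas.append(SpeciesMeta(r.species_id, r.species_name, r.taxon_class,
                                 getattr(r, "source", "")))
    return metas


def write_species_meta(metas: Sequence[SpeciesMeta], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tspecies_name\ttaxon_class\tsource\n")
        for m in metas:
            fh.write(f"{m.species_id}\t{m.species_name}\t{m.taxon_class}\t{m.source}\n")
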