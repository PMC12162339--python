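"""Species-level quality filtering and one-protein-per-gene reduction.

A genome enters the analysis only if its BUSCO five-number summary clears the
quality gate; each retained gene is then represented by its longest isoform
(maximal total coding length), translated with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .formats_io import BuscoSummary, GeneModel, ProteinRecord, Transcript

__all__ = [
    "QcThresholds",
    "filter_species_by_busco",
    "select_longest_isoform",
    "translate_transcript",
    "extract_proteins",
    "ExtractionStats",
]


@dataclass(frozen=True)
class QcThresholds:
    """BUSCO quality gate.

    A species is retained iff complete > ``complete_gt``, single-copy ≥
    ``single_ge``, duplicated ≥ ``duplicated_ge``, fragmented ≥
    ``fragmented_ge`` and missing ≤ ``missing_le`` (all percentages).
    The defaults are deliberately permissive minimums: they exclude only
    genomes with essentially no recoverable single-copy orthologs.
    """

    complete_gt: float = 2.4
    single_ge: float = 0.60
    duplicated_ge: float = 0.10
    fragmented_ge: float = 0.50
    missing_le: float = 97.00


def filter_species_by_busco(
    summaries: Mapping[str, BuscoSummary],
    thresholds: QcThresholds = QcThresholds(),
) -> tuple[set[str], dict[str, list[str]]]:
    """Apply the quality gate; returns (retained, rejected→failed clauses).

    Every failed clause is listed so a rejection is auditable.
    """
    retained: set[str] = set()
    rejected: dict[str, list[str]] = {}
    t = thresholds
    for species, s in summaries.items():
        failed = []
        if not s.complete_pct > t.complete_gt:
            failed.append(f"complete_pct {s.complete_pct} <= {t.complete_gt}")
        if not s.single_pct >= t.single_ge:
            failed.append(f"single_pct {s.single_pct} < {t.single_ge}")
        if not s.duplicated_pct >= t.duplicated_ge:
            failed.append(f"duplicated_pct {s.duplicated_pct} < {t.duplicated_ge}")
        if not s.fragmented_pct >= t.fragmented_ge:
            failed.append(f"fragmented_pct {s.fragmented_pct} < {t.fragmented_ge}")
        if not s.missing_pct <= t.missing_le:
            failed.append(f"missing_pct {s.missing_pct} > {t.missing_le}")
        if failed:
            rejected[species] = failed
        else:
            retained.add(species)
    return retained, rejected


def select_longest_isoform(model: GeneModel) -> str:
    """Transcript with maximal total CDS length; ties break to the
    lexicographically smallest transcript_id, so the choice is invariant to
    listing order."""
    if not model.transcripts:
        raise ValueError(f"gene {model.gene_id} has no transcripts")
    return min(model.transcripts,
               key=lambda t: (-t.cds_length, t.transcript_id)).transcript_id


@dataclass
class ExtractionStats:
    internal_stop: int = 0
    partial_codon: int = 0
    flagged_partial: list[str] = field(default_factory=list)


def _transcript_nt(region_seq: str, tr: Transcript, strand: str) -> str:
    parts = []
    for s, e in tr.cds_segments:
        seg = region_seq[s - 1:e]
        if strand == "-":
            seg = str(Seq(seg).reverse_complement())
        parts.append(seg)
    return "".join(parts)


def translate_transcript(region_seq: str, tr: Transcript, strand: str,
                         stats: ExtractionStats | None = None) -> str | None:
    """Translate one transcript's CDS with the standard genetic code.

    The phase of the first CDS segment shifts the reading frame; a trailing
    stop is removed.  A premature internal stop disqualifies the protein
    (returns None); a coding length not divisible by 3 translates the floor
    and flags the transcript as partial.
    """
    nt = _transcript_nt(region_seq, tr, strand)
    phase = tr.phases[0] if tr.phases else 0
    nt = nt[phase:]
    rem = len(nt) % 3
    if rem:
        nt = nt[:len(nt) - rem]
        if stats is not None:
            stats.partial_codon += 1
            stats.flagged_partial.append(tr.transcript_id)
    if not nt:
        return None
    aa = str(Seq(nt).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        if stats is not None:
            stats.internal_stop += 1
        return None
    return aa or None


def extract_proteins(
    genome_store: Mapping[str, Mapping[str, str]],
    models: Mapping[str, Sequence[GeneModel]],
    retained_species: Iterable[str],
) -> tuple[list[ProteinRecord], ExtractionStats]:
    """One protein per gene (longest isoform) for every retained species.

    ``genome_store`` maps species_id → {seq_region → nucleotide sequence};
    ``models`` maps species_id → gene models.  Protein ids are transcript ids;
    the description records species, gene and symbol.
    """
    stats = ExtractionStats()
    out: list[ProteinRecord] = []
    for species in sorted(retained_species):
        regions = genome_store[species]
        for gm in models.get(species, ()):
            tid = select_longest_isoform(gm)
            tr = next(t for t in gm.transcripts if t.transcript_id == tid)
            if gm.seq_region not in regions:
                raise KeyError(
                    f"{species}: region {gm.seq_region!r} absent from genome store")
            aa = translate_transcript(regions[gm.seq_region], tr, gm.strand, stats)
            if aa is None:
                continue
            desc = f"species={species} gene={gm.gene_id}"
            if gm.symbol:
                desc += f" symbol={gm.symbol}"
            out.append(ProteinRecord(tid, aa, desc, species))
    return out, stats
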