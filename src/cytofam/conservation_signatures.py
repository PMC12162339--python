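"""Per-group alignment, trimming, conservation profiles and signature motifs.

This module carries the conservation analysis of the family: align the
members of a group, trim poorly occupied columns, profile per-column residue
usage (sequence-logo matrices in bits), scan for the three gapped fn3
signatures ("F-I-KPDPP", "W-P-W-P-F-L-K/F", "V-A-S-WS") and the contiguous
WSXWS hallmark, and map literature key residues (e.g. p35 Y189, p19 W156,
p40 RKKEKMK 254-260) onto alignment columns with a conservation fraction.

A signature is an ordered list of anchors separated by intervals of one or
more residues; matching is leftmost-shortest (anchors placed as early as
possible, with backtracking), non-overlapping, with a configurable upper gap
bound so a match stays within one fn3 domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .formats_io import ProteinRecord

__all__ = [
    "MultipleAlignment",
    "ColumnProfile",
    "SignatureMotif",
    "MotifMatch",
    "KeyResidueReport",
    "progressive_align",
    "trim_alignment",
    "column_profiles",
    "parse_motif",
    "load_builtin_signatures",
    "scan_signature",
    "detect_wsxws",
    "map_key_residues",
]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()


@dataclass(frozen=True)
class MultipleAlignment:
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


def progressive_align(records: Sequence[ProteinRecord],
                      gap_open: int = 11, gap_extend: int = 1) -> MultipleAlignment:
    """Multiple alignment of a group's members (progressive, BLOSUM62).

    Pairwise inputs use an optimal global alignment with free terminal gaps;
    larger inputs use a guide-tree progressive alignment.  A single sequence
    is returned as a one-row alignment.  Deterministic for fixed input.
    """
    if not records:
        raise ValueError("no sequences to align")
    ids = tuple(r.id for r in records)
    if len(records) == 1:
        return MultipleAlignment(ids, (records[0].seq,))
    seqs = [bseq.ProteinSequence(r.seq) for r in records]
    penalty = (-(gap_open + gap_extend), -gap_extend)
    if len(records) == 2:
        aln = balign.align_optimal(seqs[0], seqs[1], _MATRIX, gap_penalty=penalty,
                                   local=False, terminal_penalty=False,
                                   max_number=1)[0]
    else:
        aln = balign.align_multiple(seqs, _MATRIX, gap_penalty=penalty)[0]
    symbols = balign.get_symbols(aln)
    rows = tuple("".join(s if s is not None else "-" for s in row)
                 for row in symbols)
    return MultipleAlignment(ids, rows)


def trim_alignment(aln: MultipleAlignment, gap_threshold: float = 0.85,
                   cons_min: float = 30.0) -> tuple[MultipleAlignment, list[int]]:
    """Remove poorly occupied columns, with a conserved-percentage floor.

    Columns whose non-gap fraction is ≥ ``gap_threshold`` are kept.  If that
    leaves fewer than ``cons_min`` percent of the original columns, the
    ⌈cons_min% · ncols⌉ columns of highest occupancy are kept instead (ties
    resolved leftmost).  Returns the trimmed alignment and the original
    (0-based) indices of the kept columns, in order.
    """
    ncols = aln.ncols
    if ncols == 0:
        return aln, []
    arr = np.array([list(r) for r in aln.rows])
    occ = (arr != "-").mean(axis=0)
    kept = [i for i in range(ncols) if occ[i] >= gap_threshold]
    floor = math.ceil(cons_min / 100.0 * ncols)
    if len(kept) < floor:
        # stable sort on -occupancy keeps leftmost first among ties
        order = sorted(range(ncols), key=lambda i: (-occ[i], i))
        kept = sorted(order[:floor])
    rows = tuple("".join(r[i] for i in kept) for r in aln.rows)
    return MultipleAlignment(aln.ids, rows), kept


@dataclass(frozen=True)
class ColumnProfile:
    frequencies: tuple[float, ...]  # over the 20 aa, gap-excluded
    gap_fraction: float
    information_bits: float
    consensus: str


def column_profiles(aln: MultipleAlignment) -> list[ColumnProfile]:
    """Per-column residue frequencies, gap fraction, information content.

    Frequencies are over non-gap standard residues (``X`` ignored);
    information content is log2(20) minus the Shannon entropy of the column,
    the height scale of a sequence logo.  An all-gap column has zero
    frequencies and zero information.
    """
    if not aln.rows:
        raise ValueError("empty alignment")
    out = []
    nrows = len(aln.rows)
    for c in range(aln.ncols):
        col = [r[c] for r in aln.rows]
        gaps = col.count("-")
        counts = np.array([sum(1 for x in col if x == aa) for aa in _AA20], float)
        total = counts.sum()
        if total == 0:
            out.append(ColumnProfile((0.0,) * 20, gaps / nrows, 0.0, "-"))
            continue
        freqs = counts / total
        nz = freqs[freqs > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        ic = math.log2(20) - entropy
        consensus = _AA20[int(np.argmax(counts))]
        out.append(ColumnProfile(tuple(freqs), gaps / nrows, ic, consensus))
    return out


# ---------------------------------------------------------------------------
# Gapped signature motifs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignatureMotif:
    """Ordered anchors separated by intervals of ≥1 residue.

    An anchor is a literal residue string or a single-position choice set
    (e.g. K/F).  The final element is always an anchor, so a match ends on
    sequence, not on a wildcard.
    """

    motif_id: str
    anchors: tuple[tuple[str, ...], ...]  # each anchor: alternatives

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ValueError("motif needs at least one anchor")


def parse_motif(motif_id: str, anchors: Sequence[str]) -> SignatureMotif:
    """Build a motif from anchor strings; ``K/F`` denotes alternatives."""
    parsed = tuple(tuple(a.split("/")) if "/" in a else (a,) for a in anchors)
    return SignatureMotif(motif_id, parsed)


def load_builtin_signatures(path: str | Path | None = None
                            ) -> tuple[list[SignatureMotif], SignatureMotif]:
    """The three bundled fn3 signatures plus the WSXWS motif definition."""
    if path is None:
        ref = resources.files("cytofam.data") / "signatures.yaml"
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    doc = yaml.safe_load(text)
    sigs = [parse_motif(d["motif_id"], d["anchors"]) for d in doc["signatures"]]
    wsxws = SignatureMotif(doc["wsxws"]["motif_id"],
                           (("W",), ("S",), tuple(_AA20), ("W",), ("S",)))
    return sigs, wsxws


@dataclass(frozen=True)
class MotifMatch:
    motif_id: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    matched: str


def _anchor_at(seq: str, pos: int, anchor: tuple[str, ...]) -> int | None:
    """End index (exclusive) if one alternative of ``anchor`` matches at pos."""
    for alt in anchor:
        if seq.startswith(alt, pos):
            return pos + len(alt)
    return None


def _match_from(seq: str, start: int, motif: SignatureMotif,
                gap_min: int, gap_max: int) -> int | None:
    """Earliest-anchor (lazy) match of the whole motif starting exactly at
    ``start``; returns the end index (exclusive) or None.

    Gaps are tried shortest-first with backtracking, mirroring lazy-quantifier
    regular-expression semantics.
    """
    end0 = _anchor_at(seq, start, motif.anchors[0])
    if end0 is None:
        return None

    def rec(prev_end: int, idx: int) -> int | None:
        if idx == len(motif.anchors):
            return prev_end
        for g in range(gap_min, gap_max + 1):
            pos = prev_end + g
            if pos >= len(seq):
                return None
            e = _anchor_at(seq, pos, motif.anchors[idx])
            if e is not None:
                res = rec(e, idx + 1)
                if res is not None:
                    return res
        return None

    return rec(end0, 1)


def scan_signature(sequence: str | ProteinRecord, motif: SignatureMotif,
                   gap_max: int = 20, gap_min: int = 1,
                   protein_id: str | None = None) -> list[MotifMatch]:
    """All non-overlapping leftmost-shortest matches of a gapped signature.

    Intervals between anchors span ``gap_min``..``gap_max`` residues
    (defaults 1..20: "one or more amino acids", bounded to stay within one
    fn3 domain).  After a match, scanning resumes at the first position past
    its end.
    """
    if isinstance(sequence, ProteinRecord):
        protein_id = protein_id or sequence.id
        sequence = sequence.seq
    pid = protein_id or ""
    matches: list[MotifMatch] = []
    pos = 0
    n = len(sequence)
    while pos < n:
        end = _match_from(sequence, pos, motif, gap_min, gap_max)
        if end is None:
            pos += 1
            continue
        matches.append(MotifMatch(motif.motif_id, pid, pos + 1, end,
                                  sequence[pos:end]))
        pos = end
    return matches


def detect_wsxws(sequence: str | ProteinRecord,
                 protein_id: str | None = None) -> list[MotifMatch]:
    """Every non-overlapping occurrence of the W-S-x-W-S pentapeptide."""
    if isinstance(sequence, ProteinRecord):
        protein_id = protein_id or sequence.id
        sequence = sequence.seq
    pid = protein_id or ""
    matches = []
    pos = 0
    while pos + 5 <= len(sequence):
        w = sequence[pos:pos + 5]
        if w[0] == "W" and w[1] == "S" and w[3] == "W" and w[4] == "S":
            matches.append(MotifMatch("WSXWS", pid, pos + 1, pos + 5, w))
            pos += 5
        else:
            pos += 1
    return matches


# ---------------------------------------------------------------------------
# Key-residue mapping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeyResidueReport:
    residue: str
    position: int  # 1-based on the ungapped reference
    column: int    # 0-based alignment column
    reference_ok: bool
    conservation: float


def map_key_residues(aln: MultipleAlignment, reference_id: str,
                     residues: Sequence[tuple[str, int]]) -> list[KeyResidueReport]:
    """Map 1-based reference positions onto alignment columns.

    For each (residue letter, position): find the alignment column holding
    that ungapped reference position, check that the reference actually
    carries the stated letter there (``reference_ok`` is False on mismatch —
    a claimed residue never passes silently), and report the fraction of rows
    matching the reference residue at that column.
    """
    try:
        ridx = aln.ids.index(reference_id)
    except ValueError as exc:
        raise KeyError(f"reference {reference_id!r} not in alignment") from exc
    row = aln.rows[ridx]
    # ungapped position (1-based) → column
    col_of: dict[int, int] = {}
    p = 0
    for c, ch in enumerate(row):
        if ch != "-":
            p += 1
            col_of[p] = c
    reports = []
    nrows = len(aln.rows)
    for letter, pos in residues:
        if pos not in col_of:
            raise ValueError(f"position {pos} beyond reference length {p}")
        col = col_of[pos]
        ref_aa = row[col]
        ok = ref_aa == letter
        cons = sum(1 for r in aln.rows if r[col] == ref_aa) / nrows
        reports.append(KeyResidueReport(letter, pos, col, ok, cons))
    return reports
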