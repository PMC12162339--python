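"""Dual-evidence identification of IL-12 family members.

A protein is accepted as a family member when domain-content evidence
(required Pfam domains present) and similarity evidence (local alignment to a
human query at E ≤ 1e-5) intersect.  Queries defined without Pfam domains
(p28, IL-23R, WSX-1) are assigned purely by similarity — the family lacks a
seed alignment that detects them.

Pairwise alignment is Smith–Waterman with affine gaps under BLOSUM62 and
BLAST-compatible penalties (gap open 11, extend 1: a gap of length k costs
11 + k).  Bit scores use fixed gapped-BLOSUM62 Karlin–Altschul constants and
E-values use the product of the two sequence lengths as the search space, so
the internal search is a drop-in, desk-scale replacement for an external
BLASTp run; precomputed tabular output can be ingested instead with identical
downstream semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import biotite.sequence as bseq
import biotite.sequence.align as balign

from .formats_io import DomainHit, ProteinRecord, QueryDef, SimilarityHit

__all__ = [
    "AlignmentResult",
    "HomologCall",
    "KARLIN_LAMBDA",
    "KARLIN_K",
    "align_local",
    "similarity_search",
    "domain_evidence",
    "call_homologs",
]

# Karlin-Altschul constants for gapped BLOSUM62 with open 11 / extend 1.
KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041

_MATRIX = balign.SubstitutionMatrix.std_protein_matrix()  # BLOSUM62


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    subject_id: str
    aligned_query: str
    aligned_subject: str
    raw_score: int
    bitscore: float
    evalue: float
    pct_identity: float
    aln_len: int


def _bit_and_evalue(raw: int, m: int, n: int) -> tuple[float, float]:
    bits = (KARLIN_LAMBDA * raw - math.log(KARLIN_K)) / math.log(2.0)
    evalue = m * n * math.pow(2.0, -bits)
    return bits, evalue


def align_local(
    a: ProteinRecord | str,
    b: ProteinRecord | str,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    pct_identity follows the BLAST pident convention: identical columns over
    the full alignment length, gap columns included in the denominator.  When
    no cell scores positive the alignment is empty (score 0, identity 0).
    """
    qid, qseq = (a.id, a.seq) if isinstance(a, ProteinRecord) else ("query", a)
    sid, sseq = (b.id, b.seq) if isinstance(b, ProteinRecord) else ("subject", b)
    if not qseq or not sseq:
        raise ValueError("empty sequence")
    try:
        pa = bseq.ProteinSequence(qseq)
        pb = bseq.ProteinSequence(sseq)
    except Exception as exc:
        raise ValueError(f"residue outside protein alphabet: {exc}") from exc
    # biotite charges `open` on the first gap symbol, so BLAST's
    # open 11 / extend 1 cost (11 + k for a k-gap) maps to (-(11+1), -1).
    aln = balign.align_optimal(
        pa, pb, _MATRIX,
        gap_penalty=(-(gap_open + gap_extend), -gap_extend),
        local=True, max_number=1,
    )[0]
    raw = int(aln.score)
    m, n = len(qseq), len(sseq)
    if raw <= 0 or len(aln) == 0:
        bits, evalue = _bit_and_evalue(0, m, n)
        return AlignmentResult(qid, sid, "", "", 0, bits, evalue, 0.0, 0)
    symbols = balign.get_symbols(aln)
    row_q = "".join(s if s is not None else "-" for s in symbols[0])
    row_s = "".join(s if s is not None else "-" for s in symbols[1])
    ncol = len(row_q)
    ident = sum(1 for x, y in zip(row_q, row_s) if x == y and x != "-")
    bits, evalue = _bit_and_evalue(raw, m, n)
    return AlignmentResult(qid, sid, row_q, row_s, raw, bits, evalue,
                           100.0 * ident / ncol, ncol)


def similarity_search(
    queries: Sequence[ProteinRecord],
    db: Sequence[ProteinRecord],
    e_max: float = 1e-5,
    gap_open: int = 11,
    gap_extend: int = 1,
) -> list[SimilarityHit]:
    """Align every query against every database protein; keep E ≤ e_max.

    Hits are returned sorted by (subject_id, ascending E-value) so downstream
    consumption is order-independent.
    """
    hits: list[SimilarityHit] = []
    for q in queries:
        for s in db:
            res = align_local(q, s, gap_open, gap_extend)
            if res.aln_len and res.evalue <= e_max:
                hits.append(SimilarityHit(q.id, s.id, round(res.pct_identity, 2),
                                          res.aln_len, res.evalue, res.bitscore))
    hits.sort(key=lambda h: (h.subject_id, h.evalue, h.query_id))
    return hits


def domain_evidence(protein_hits: Sequence[DomainHit], query: QueryDef) -> bool:
    """True iff every required domain of ``query`` occurs among the hits.

    Comparison is version-insensitive (PF00041 matches PF00041.26).  Presence
    suffices; order and copy number are not constrained.  A query with no
    required domains yields False — domain evidence is inapplicable and the
    protein must be handled by the similarity-only path.
    """
    if not query.required_domains:
        return False
    present = {h.acc_key for h in protein_hits}
    return all(acc.split(".")[0] in present for acc in query.required_domains)


@dataclass(frozen=True)
class HomologCall:
    """Family-membership decision for one protein.

    ``evidence`` records which routes supported the call: ``both`` (domain ∩
    similarity), ``blast_only_query`` (similarity to a query defined without
    Pfam domains), or ``pfam_only`` (domain evidence without similarity —
    never accepted).
    """

    protein_id: str
    species_id: str | None
    family_side: str
    best_query_symbol: str
    pct_identity: float
    evidence: str
    accepted: bool


def call_homologs(
    proteins: Sequence[ProteinRecord],
    domain_hits: Sequence[DomainHit],
    similarity_hits: Sequence[SimilarityHit],
    queries: Sequence[QueryDef],
) -> list[HomologCall]:
    """Intersect domain and similarity evidence into final family calls.

    Per protein, the best query is the passing similarity hit with maximal
    bitscore (ties: higher identity, then query-table order).  Acceptance:

    * domain evidence for ≥1 query AND ≥1 similarity hit → ``both``;
    * best query is a blast-only query → ``blast_only_query``;
    * domain evidence without similarity → ``pfam_only``, not accepted.

    Proteins with neither route produce no call.
    """
    by_acc: Mapping[str, QueryDef] = {q.uniprot_acc: q for q in queries}
    query_order = {q.uniprot_acc: i for i, q in enumerate(queries)}
    dom_by_protein: dict[str, list[DomainHit]] = {}
    for h in domain_hits:
        dom_by_protein.setdefault(h.protein_id, []).append(h)
    sim_by_protein: dict[str, list[SimilarityHit]] = {}
    for h in similarity_hits:
        if h.query_id in by_acc:
            sim_by_protein.setdefault(h.subject_id, []).append(h)

    calls: list[HomologCall] = []
    for prot in proteins:
        phits = dom_by_protein.get(prot.id, [])
        domain_pass = any(domain_evidence(phits, q) for q in queries)
        sims = sim_by_protein.get(prot.id, [])
        if not domain_pass and not sims:
            continue
        if sims:
            best = min(sims, key=lambda h: (-h.bitscore, -h.pct_identity,
                                            query_order[h.query_id]))
            best_q = by_acc[best.query_id]
            if domain_pass:
                evidence, accepted = "both", True
            elif best_q.blast_only:
                evidence, accepted = "blast_only_query", True
            else:
                evidence, accepted = "blast_only_query", False
            calls.append(HomologCall(prot.id, prot.species_id, best_q.family_side,
                                     best_q.gene_symbol, best.pct_identity,
                                     evidence, accepted))
        else:
            satisfied = next(q for q in queries if domain_evidence(phits, q))
            calls.append(HomologCall(prot.id, prot.species_id,
                                     satisfied.family_side, satisfied.gene_symbol,
                                     0.0, "pfam_only", False))
    return calls
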