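"""Distribution tables per taxonomic Class and micro-synteny comparison.

Tabulates homolog and group counts per species and per Class (row
percentages to 2 decimals, half-even), and compares the gene neighborhood of
a focal symbol across species: how many of the windowed flanking genes are
shared, and whether the immediate neighbor is preserved (e.g. IL23R adjacent
to IL12RB2 from zebrafish to humans).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import GeneModel, SpeciesMeta, TAXON_CLASSES
from .homolog_search import HomologCall

__all__ = [
    "GeneNeighborhood",
    "count_table",
    "per_species_counts",
    "neighborhood",
    "neighborhood_conservation",
]


def count_table(
    calls: Sequence[HomologCall],
    metas: Sequence[SpeciesMeta],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts of accepted homologs per (family_side, label) × taxonomic Class.

    The row label is the best-query gene symbol, or the Group (I–V) when a
    ``protein_id → group`` mapping is supplied.  Row percentages (``..._pct``
    columns) are the share of each Class in the row total, rounded half-even
    to 2 decimals; rows with zero total have blank (NaN) percentages.
    """
    class_of = {m.species_id: m.taxon_class for m in metas}
    unknown = sorted({c.species_id for c in calls if c.accepted}
                     - set(class_of) - {None})
    if unknown:
        raise KeyError(f"species missing from metadata: {unknown}")
    counts: dict[tuple[str, str], dict[str, int]] = {}
    for c in calls:
        if not c.accepted:
            continue
        label = groups.get(c.protein_id, "unassigned") if groups is not None \
            else c.best_query_symbol
        key = (c.family_side, label)
        row = counts.setdefault(key, {cl: 0 for cl in TAXON_CLASSES})
        row[class_of[c.species_id]] += 1

    index = pd.MultiIndex.from_tuples(sorted(counts), names=["family_side", "label"])
    df = pd.DataFrame([counts[k] for k in sorted(counts)], index=index,
                      columns=list(TAXON_CLASSES), dtype=int)
    totals = df.sum(axis=1)
    for cl in TAXON_CLASSES:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * df[cl] / totals, np.nan)
        df[f"{cl}_pct"] = np.round(pct, 2)
    df["total"] = totals
    return df


def per_species_counts(
    calls: Sequence[HomologCall],
    retained_species: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Accepted ligand/receptor gene counts per species.

    Retained species without any call still get a (0, 0) row, so absence is
    visible rather than silently dropped.
    """
    species = set(retained_species or [])
    species.update(c.species_id for c in calls if c.accepted and c.species_id)
    rows = {sp: {"ligand_count": 0, "receptor_count": 0} for sp in sorted(species)}
    for c in calls:
        if c.accepted and c.species_id in rows:
            rows[c.species_id][f"{c.family_side}_count"] += 1
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("species_id")


@dataclass(frozen=True)
class GeneNeighborhood:
    species_id: str
    focal_gene: str
    upstream: tuple[str, ...]    # nearest-last, genomic order
    downstream: tuple[str, ...]  # nearest-first


def neighborhood(models: Sequence[GeneModel], focal_symbol: str,
                 species_id: str = "", window: int = 5) -> GeneNeighborhood:
    """Up to ``window`` annotated genes flanking the focal gene on its contig.

    Genes are ordered by start coordinate; the window truncates at contig
    ends.  Genes without a symbol cannot participate and are skipped.
    The result is invariant to the input order of the models.
    """
    focal = next((g for g in models if g.symbol == focal_symbol), None)
    if focal is None:
        raise KeyError(f"focal symbol {focal_symbol!r} not found"
                       f"{' in ' + species_id if species_id else ''}")
    contig = sorted((g for g in models
                     if g.seq_region == focal.seq_region and g.symbol),
                    key=lambda g: (g.start, g.gene_id))
    idx = next(i for i, g in enumerate(contig) if g.gene_id == focal.gene_id)
    up = tuple(g.symbol for g in contig[max(0, idx - window):idx])
    down = tuple(g.symbol for g in contig[idx + 1:idx + 1 + window])
    return GeneNeighborhood(species_id, focal_symbol, up, down)


def neighborhood_conservation(
    neighborhoods: Sequence[GeneNeighborhood],
) -> pd.DataFrame:
    """Pairwise shared-neighbor scores for one focal symbol across species.

    For each species pair: score = |shared flanking symbols| / window size
    (the larger of the two neighborhood sizes, so a truncated contig cannot
    inflate the score), plus a symmetric adjacency flag — True when the two
    species share an identical immediate neighbor on either side.
    """
    if len(neighborhoods) < 2:
        raise ValueError("need neighborhoods from at least 2 species")
    rows = []
    for a, b in combinations(neighborhoods, 2):
        set_a = set(a.upstream) | set(a.downstream)
        set_b = set(b.upstream) | set(b.downstream)
        denom = max(len(set_a), len(set_b))
        score = len(set_a & set_b) / denom if denom else 0.0
        imm_a = {a.upstream[-1] if a.upstream else None,
                 a.downstream[0] if a.downstream else None} - {None}
        imm_b = {b.upstream[-1] if b.upstream else None,
                 b.downstream[0] if b.downstream else None} - {None}
        rows.append({
            "species_a": a.species_id, "species_b": b.species_id,
            "focal": a.focal_gene, "shared_score": score,
            "adjacency_conserved": bool(imm_a & imm_b),
        })
    return pd.DataFrame(rows)
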