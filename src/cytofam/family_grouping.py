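"""Domain-architecture grouping of IL-12 family ligands and receptors.

The family splits into five groups per side, each an equivalence class of
domain architectures:

ligands
    I   IL12p40_C (p40-like, sometimes preceded by Ig-like domains)
    II  fn3 (EBI3-like, occasionally with Ig-like domains)
    III single IL12 domain (p35-like)
    IV  single IL23 domain (p19-like)
    V   no diagnostic domain; p28/CNTF-like by best-query similarity

receptors
    I   a single fn3 and nothing else
    II  1–2 fn3 at the C-terminus
    III Lep_receptor_Ig followed by fn3 (± IL6Ra-bind / EpoR_lig-bind)
    IV  IL6Ra-bind without Lep_receptor_Ig
    V   Lep_receptor_Ig with exactly 2 fn3

The published descriptions are prototypes, not a decision procedure; the
clauses here are ordered most-specific-first so every architecture fires
exactly one rule (recorded as ``rule_id``).

The module also reproduces the family-wide clustering: a pairwise-identity
feature matrix, PCA retaining ≥90% variance, and k-means over a k range with
silhouette-based selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .formats_io import DomainHit, ProteinRecord, strip_version
from .homolog_search import align_local

__all__ = [
    "PFAM_LABELS",
    "DomainArchitecture",
    "GroupAssignment",
    "ClusterReport",
    "build_architecture",
    "classify_ligand",
    "classify_receptor",
    "pairwise_identity_matrix",
    "pca_projection",
    "cluster_sequences",
]

#: Pfam accession → architecture label (version-insensitive keys).
PFAM_LABELS = {
    "PF00041": "fn3",
    "PF10420": "IL12p40_C",
    "PF03039": "IL12",
    "PF16649": "IL23",
    "PF06328": "Lep_receptor_Ig",
    "PF09240": "IL6Ra-bind",
    "PF09067": "EpoR_lig-bind",
    # immunoglobulin-like set domains seen alongside the family domains
    "PF07679": "Ig-like",
    "PF13927": "Ig-like",
    "PF00047": "Ig-like",
}

#: best-query gene symbols that place a domain-free ligand in Group V
P28_LIKE_SYMBOLS = {"IL27", "p28", "CNTF"}


@dataclass(frozen=True)
class DomainArchitecture:
    """Ordered domain content of one protein (sorted by start)."""

    protein_id: str
    ordered_domains: tuple[tuple[str, int, int], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _, _ in self.ordered_domains)

    def count(self, label: str) -> int:
        return sum(1 for lab in self.labels if lab == label)


@dataclass(frozen=True)
class GroupAssignment:
    protein_id: str
    family_side: str
    group: str  # I..V or "unassigned"
    rule_id: str


def _label_for(acc: str) -> str:
    return PFAM_LABELS.get(strip_version(acc), "other")


def build_architecture(hits: Sequence[DomainHit]) -> DomainArchitecture:
    """Collapse raw domain hits into an ordered architecture.

    Same-label hits overlapping by more than 50% of both intervals are merged,
    keeping the higher-scoring hit's coordinates — repeated model hits over
    one physical domain must not inflate copy counts.
    """
    if not hits:
        return DomainArchitecture("", ())
    pid = hits[0].protein_id
    if any(h.protein_id != pid for h in hits):
        raise ValueError("hits span multiple proteins")
    labeled = sorted(((_label_for(h.domain_acc), h) for h in hits),
                     key=lambda t: (t[1].start, t[1].end))
    kept: list[tuple[str, DomainHit]] = []
    for lab, h in labeled:
        merged = False
        for i, (klab, kh) in enumerate(kept):
            if klab != lab:
                continue
            ov = min(h.end, kh.end) - max(h.start, kh.start) + 1
            if ov > 0.5 * (h.end - h.start + 1) and ov > 0.5 * (kh.end - kh.start + 1):
                if h.score > kh.score:
                    kept[i] = (lab, h)
                merged = True
                break
        if not merged:
            kept.append((lab, h))
    kept.sort(key=lambda t: (t[1].start, t[1].end))
    return DomainArchitecture(pid, tuple((lab, h.start, h.end) for lab, h in kept))


def classify_ligand(arch: DomainArchitecture,
                    best_query_symbol: str | None = None) -> GroupAssignment:
    """Assign a ligand-side homolog to Group I–V.

    Precedence puts the most specific domain first: IL12p40_C → I, IL23 → IV,
    IL12 → III, fn3 → II; with no diagnostic domain, a p28/CNTF-like best
    query → V, otherwise unassigned.
    """
    labels = set(arch.labels)
    pid = arch.protein_id
    if "IL12p40_C" in labels:
        return GroupAssignment(pid, "ligand", "I", "ligand_IL12p40_C")
    if "IL23" in labels:
        return GroupAssignment(pid, "ligand", "IV", "ligand_IL23")
    if "IL12" in labels:
        return GroupAssignment(pid, "ligand", "III", "ligand_IL12")
    if "fn3" in labels:
        return GroupAssignment(pid, "ligand", "II", "ligand_fn3")
    if best_query_symbol in P28_LIKE_SYMBOLS:
        return GroupAssignment(pid, "ligand", "V", "ligand_p28_like_query")
    return GroupAssignment(pid, "ligand", "unassigned", "ligand_no_rule")


def classify_receptor(arch: DomainArchitecture) -> GroupAssignment:
    """Assign a receptor-side homolog to Group I–V.

    With Lep_receptor_Ig present, exactly two fn3 → V, otherwise (with ≥1
    fn3) → III.  Without it: IL6Ra-bind → IV; a lone fn3 → I; 1–2 fn3 ending
    the architecture → II ("at the C-terminus" is read as fn3 being the final
    domain); anything else is unassigned.
    """
    pid = arch.protein_id
    labels = arch.labels
    n_fn3 = arch.count("fn3")
    if "Lep_receptor_Ig" in labels:
        if n_fn3 == 2:
            return GroupAssignment(pid, "receptor", "V", "receptor_lep_2fn3")
        if n_fn3 >= 1:
            return GroupAssignment(pid, "receptor", "III", "receptor_lep_fn3")
        return GroupAssignment(pid, "receptor", "unassigned", "receptor_lep_only")
    if "IL6Ra-bind" in labels:
        return GroupAssignment(pid, "receptor", "IV", "receptor_il6ra_bind")
    if labels == ("fn3",):
        return GroupAssignment(pid, "receptor", "I", "receptor_single_fn3")
    if labels and labels[-1] == "fn3" and n_fn3 in (1, 2):
        return GroupAssignment(pid, "receptor", "II", "receptor_cterm_fn3")
    return GroupAssignment(pid, "receptor", "unassigned", "receptor_no_rule")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    assignments: dict[str, int]
    k_selected: int
    cluster_stats: dict[int, tuple[float, float]]  # cluster → (mean, median) identity
    coordinates: dict[str, tuple[float, float]]
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)


def pairwise_identity_matrix(records: Sequence[ProteinRecord]) -> np.ndarray:
    """Symmetric percent-identity matrix (diagonal 100) from local alignments."""
    n = len(records)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = align_local(records[i], records[j])
            mat[i, j] = mat[j, i] = res.pct_identity
    return mat


def pca_projection(identity: np.ndarray) -> np.ndarray:
    """Top-2 principal components of the centered identity-feature matrix.

    Each protein's feature vector is its row of the identity matrix.  Sign
    convention: within each component the largest-magnitude loading is made
    positive, so coordinates are stable under row permutation.
    """
    identity = np.asarray(identity, dtype=float)
    if identity.ndim != 2 or identity.shape[0] != identity.shape[1]:
        raise ValueError("identity matrix must be square")
    if not np.allclose(identity, identity.T, atol=1e-8):
        raise ValueError("identity matrix must be symmetric")
    n = identity.shape[0]
    if float(np.var(identity, axis=0).sum()) < 1e-12:
        return np.zeros((n, 2))  # identical sequences: all points coincide
    k = min(2, n)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(identity)
    for c in range(coords.shape[1]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            coords[:, c] *= -1.0
    if coords.shape[1] < 2:
        coords = np.pad(coords, ((0, 0), (0, 2 - coords.shape[1])))
    return coords


def cluster_sequences(
    records: Sequence[ProteinRecord],
    min_clust: int = 6,
    max_clust: int = 11,
    seed: int = 0,
    identity: np.ndarray | None = None,
) -> ClusterReport:
    """k-means over PCA features with silhouette-selected k.

    Features are the principal components of the pairwise-identity matrix
    retaining ≥90% variance; k-means runs for each k in [min_clust,
    max_clust] with 10 restarts from a fixed seed, and the k maximizing the
    mean silhouette is kept.  Per-cluster mean/median identity is computed on
    the original identity matrix (NaN for singletons).
    """
    warnings: list[str] = []
    ids = [r.id for r in records]
    n = len(records)
    if n < 2:
        raise ValueError("clustering needs at least 2 proteins")
    if identity is None:
        identity = pairwise_identity_matrix(records)
    if n < max_clust:
        warnings.append(f"only {n} proteins; k range truncated at {n - 1}")
        max_clust = min(max_clust, n - 1)
        min_clust = min(min_clust, max_clust)

    centered = identity - identity.mean(axis=0, keepdims=True)
    total_var = float(np.var(centered, axis=0).sum())
    if total_var < 1e-12:
        # all sequences identical: clustering is meaningless, force min_clust
        assignments = {pid: 0 for pid in ids}
        coords = {pid: (0.0, 0.0) for pid in ids}
        warnings.append("degenerate input: identical sequences; k forced to min_clust")
        stats = {0: (100.0, 100.0)}
        return ClusterReport(assignments, min_clust, stats, coords, True, warnings)

    pca_full = PCA(svd_solver="full").fit(identity)
    ncomp = int(np.searchsorted(np.cumsum(pca_full.explained_variance_ratio_), 0.90) + 1)
    ncomp = max(2, min(ncomp, n - 1)) if n > 2 else 1
    feats = PCA(n_components=ncomp, svd_solver="full").fit_transform(identity)

    best = None
    import warnings as _warnings
    for k in range(min_clust, max_clust + 1):
        if k < 2 or k >= n:
            continue
        with _warnings.catch_warnings():
            # duplicate feature points (identical sequences) legitimately
            # yield fewer distinct centroids than k
            _warnings.simplefilter("ignore")
            km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
        if len(set(km.labels_)) < 2:
            continue
        sil = silhouette_score(feats, km.labels_)
        if best is None or sil > best[0]:
            best = (sil, k, km.labels_)
    if best is None:
        raise ValueError("no valid k in range")
    _, k_sel, labels = best

    stats: dict[int, tuple[float, float]] = {}
    for c in sorted(set(labels)):
        idx = np.flatnonzero(labels == c)
        if len(idx) < 2:
            stats[int(c)] = (float("nan"), float("nan"))
            continue
        vals = identity[np.ix_(idx, idx)][np.triu_indices(len(idx), k=1)]
        stats[int(c)] = (float(np.mean(vals)), float(np.median(vals)))

    coords2 = pca_projection(identity)
    return ClusterReport(
        {pid: int(c) for pid, c in zip(ids, labels)},
        k_sel, stats,
        {pid: (float(x), float(y)) for pid, (x, y) in zip(ids, coords2)},
        False, warnings,
    )
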