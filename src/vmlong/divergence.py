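"""Jensen-Shannon community-state dissimilarity and community state typing.

Divergences use base-2 logarithms, so the Jensen-Shannon divergence (JSD)
of any two community states lies in [0, 1]: 0 for identical states, 1 for
states with disjoint support.  Its square root is the Jensen-Shannon
distance, a metric.  Community state types (CSTs) are obtained by Ward
hierarchical clustering of the pairwise JSD matrix; clusters are named by
their dominant indicator taxon: CST I (Lactobacillus crispatus-dominated),
CST III (L. iners-dominated), CST IV-B (Lactobacillus-depleted, diverse
anaerobes such as Gardnerella vaginalis, BVAB1, Atopobium vaginae and
Megasphaera).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_data import CommunityState, SampleMetadata

__all__ = [
    "DivergenceMatrix",
    "CSTAssignment",
    "kl_divergence",
    "js_divergence",
    "js_distance",
    "pairwise_divergence",
    "ward_cluster",
    "label_csts",
    "cst_frequencies",
    "DEFAULT_REFERENCE_TAXA",
]

# Indicator taxa for the canonical six-type CST nomenclature; only the three
# types observed in term/preterm pregnancy cohorts are mapped by default.
DEFAULT_REFERENCE_TAXA: dict[str, str] = {
    "I": "Lactobacillus crispatus",
    "III": "Lactobacillus iners",
}
LACTOBACILLUS_PREFIX = "Lactobacillus"


@dataclass(frozen=True)
class DivergenceMatrix:
    sample_ids: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.sample_ids),) * 2:
            raise ValueError("divergence matrix shape does not match sample list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("divergence matrix must be symmetric")
        object.__setattr__(self, "values", v)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class CSTAssignment:
    sample_ids: tuple[str, ...]
    cluster_index: np.ndarray  # 1-based cluster ids, one per sample
    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge tree
    labels: dict[int, str] | None = None  # cluster id -> CST name

    def label_of(self, sample_id: str) -> str:
        if self.labels is None:
            raise ValueError("clusters have not been labeled yet")
        i = self.sample_ids.index(sample_id)
        return self.labels[int(self.cluster_index[i])]

    @property
    def cst_labels(self) -> list[str]:
        if self.labels is None:
            raise ValueError("clusters have not been labeled yet")
        return [self.labels[int(c)] for c in self.cluster_index]

    def to_frame(self, meta: list[SampleMetadata] | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"sample_id": self.sample_ids, "cluster_index": self.cluster_index}
        )
        if self.labels is not None:
            df["cst_label"] = self.cst_labels
        if meta is not None:
            by_id = {m.sample_id: m for m in meta}
            df["subject_id"] = [by_id[s].subject_id for s in self.sample_ids]
            df["gestational_age"] = [by_id[s].gestational_age for s in self.sample_ids]
        return df


def _as_prob(p) -> np.ndarray:
    arr = p.abundances if isinstance(p, CommunityState) else np.asarray(p, dtype=float)
    return np.asarray(arr, dtype=float)


def kl_divergence(p, q) -> float:
    """Kullback-Leibler divergence sum_i p_i log2(p_i / q_i), in bits.

    Terms with p_i = 0 contribute 0 (x log x -> 0).  Where p has mass but q
    does not, the divergence is infinite and ``inf`` is returned explicitly.
    """
    p, q = _as_prob(p), _as_prob(q)
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    support = p > 0
    if np.any(q[support] == 0):
        return float("inf")
    ps, qs = p[support], q[support]
    return float(np.sum(ps * np.log2(ps / qs)))


def js_divergence(p, q) -> float:
    """Jensen-Shannon divergence: mean of KL(p, a) and KL(q, a), a = (p+q)/2.

    Always finite (the mixture a has support wherever p or q does) and in
    [0, 1] with base-2 logs.
    """
    p, q = _as_prob(p), _as_prob(q)
    if p.shape != q.shape:
        raise ValueError(f"dimension mismatch: {p.shape} vs {q.shape}")
    a = 0.5 * (p + q)
    val = 0.5 * (kl_divergence(p, a) + kl_divergence(q, a))
    # clamp tiny negative rounding noise
    return float(min(max(val, 0.0), 1.0)) if -1e-12 < val < 1 + 1e-12 else float(val)


def js_distance(p, q) -> float:
    """Square root of the Jensen-Shannon divergence (a metric)."""
    return float(np.sqrt(js_divergence(p, q)))


def _pairwise_jsd_matrix(states: list[CommunityState]) -> np.ndarray:
    # vectorized: entropy-form JSD(p,q) = H((p+q)/2) - (H(p)+H(q))/2, base 2
    P = np.vstack([s.abundances for s in states])
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log2(P), 0.0)
    H = -plogp.sum(axis=1)
    n = P.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        A = 0.5 * (P[i] + P[i + 1 :])
        with np.errstate(divide="ignore", invalid="ignore"):
            alog = np.where(A > 0, A * np.log2(A), 0.0)
        Hm = -alog.sum(axis=1)
        vals = Hm - 0.5 * (H[i] + H[i + 1 :])
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return np.clip(out, 0.0, 1.0)


def pairwise_divergence(
    states: list[CommunityState], metric: str = "jsd"
) -> DivergenceMatrix:
    """Pairwise JSD (or JS-distance) matrix over community states."""
    if len(states) < 2:
        raise ValueError("need at least 2 community states")
    dims = {s.abundances.size for s in states}
    if len(dims) != 1:
        raise ValueError("community states must share a common taxon basis")
    if metric not in ("jsd", "js_distance"):
        raise ValueError(f"unknown metric {metric!r}")
    vals = _pairwise_jsd_matrix(states)
    if metric == "js_distance":
        vals = np.sqrt(vals)
    return DivergenceMatrix(tuple(s.sample_id for s in states), vals)


def ward_cluster(dist: DivergenceMatrix, n_clusters: int = 3) -> CSTAssignment:
    """Ward-linkage agglomerative clustering of a precomputed dissimilarity.

    Classical Ward on the supplied matrix: the dissimilarities are treated as
    Euclidean-distance surrogates by the Lance-Williams Ward update.  The tree
    is cut to exactly ``n_clusters`` groups.
    """
    n = len(dist.sample_ids)
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must be in [1, {n}], got {n_clusters}")
    Z = linkage(dist.condensed(), method="ward")
    idx = fcluster(Z, t=n_clusters, criterion="maxclust")
    if len(np.unique(idx)) != n_clusters:
        raise RuntimeError("tree cut did not yield the requested cluster count")
    return CSTAssignment(dist.sample_ids, idx, Z)


def label_csts(
    assign: CSTAssignment,
    states: list[CommunityState],
    taxa: tuple[str, ...],
    reference_taxa: dict[str, str] | None = None,
    lactobacillus_threshold: float = 0.5,
) -> CSTAssignment:
    """Name each cluster by its mean-composition dominant indicator taxon.

    A cluster whose mean total Lactobacillus abundance falls below
    ``lactobacillus_threshold`` is labeled IV-B; a Lactobacillus-dominated
    cluster takes the CST of its top indicator taxon (I for L. crispatus,
    III for L. iners by default) or "other" when no indicator matches.
    """
    reference_taxa = dict(DEFAULT_REFERENCE_TAXA if reference_taxa is None else reference_taxa)
    by_id = {s.sample_id: s for s in states}
    P = np.vstack([by_id[sid].abundances for sid in assign.sample_ids])
    taxa = tuple(taxa)
    lacto_cols = [i for i, t in enumerate(taxa) if t.startswith(LACTOBACILLUS_PREFIX)]
    indicator_cols = {cst: taxa.index(t) for cst, t in reference_taxa.items() if t in taxa}
    labels: dict[int, str] = {}
    for c in np.unique(assign.cluster_index):
        mean = P[assign.cluster_index == c].mean(axis=0)
        lacto_total = mean[lacto_cols].sum() if lacto_cols else 0.0
        if lacto_total < lactobacillus_threshold:
            labels[int(c)] = "IV-B"
            continue
        best, best_ab = "other", 0.0
        for cst, col in indicator_cols.items():
            if mean[col] > best_ab:
                best, best_ab = cst, mean[col]
        labels[int(c)] = best if best_ab > 0 else "other"
    return CSTAssignment(assign.sample_ids, assign.cluster_index, assign.linkage_matrix, labels)


def cst_frequencies(
    assign: CSTAssignment, meta: list[SampleMetadata]
) -> pd.DataFrame:
    """CST percentage table, overall and per study group (rows sum to 100)."""
    by_id = {m.sample_id: m for m in meta}
    df = pd.DataFrame(
        {
            "cst": assign.cst_labels,
            "group": [by_id[s].group for s in assign.sample_ids],
        }
    )
    rows = {"overall": df["cst"].value_counts(normalize=True) * 100}
    for g, sub in df.groupby("group"):
        rows[str(g)] = sub["cst"].value_counts(normalize=True) * 100
    out = pd.DataFrame(rows).T.fillna(0.0)
    out.index.name = "group"
    return out
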