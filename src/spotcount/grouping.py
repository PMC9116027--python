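"""Location clustering and cluster-specific re-analysis.

Pipeline: depth-normalized log expression -> variance-stabilized HVG
selection -> PCA -> shared-nearest-neighbor graph -> Louvain communities.
Every default the upstream toolkits leave implicit is fixed here
explicitly: k = 20 neighbors, Jaccard SNN weights pruned below 1/15,
lowess span 0.3 for the mean-variance trend, standardized values clipped
at sqrt(n), and a mandatory seed.

External labels may be injected to bypass clustering entirely (mirrors
datasets analyzed with original-study labels).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genes import filter_genes, run_gene_panel
from .matrix import CountMatrix

__all__ = [
    "ClusterAssignment",
    "normalize_log",
    "select_hvg",
    "embed_pca",
    "cluster_locations",
    "cluster_specific_panel",
    "before_after_ratios",
]

logger = logging.getLogger(__name__)

SCALE_FACTOR = 1e4
SNN_PRUNE = 1.0 / 15.0


@dataclass
class ClusterAssignment:
    labels: np.ndarray                       # one small-int label per location
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        # relabel to contiguous 0..K-1 in order of first appearance
        _, first = np.unique(self.labels, return_index=True)
        mapping = {
            old: new
            for new, old in enumerate(self.labels[np.sort(first)])
        }
        self.labels = np.array([mapping[v] for v in self.labels])

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def normalize_log(m: CountMatrix) -> np.ndarray:
    """ln(1 + SCALE_FACTOR * y / N) per entry; depth-normalized log counts."""
    N = m.offsets
    if (N <= 0).any():
        raise ValueError("zero-total locations must be filtered first")
    return np.log1p(SCALE_FACTOR * m.counts / N[None, :])


def select_hvg(m: CountMatrix, n_top: int = 2000) -> list[str]:
    """Variance-stabilizing HVG ranking on raw counts.

    Per-gene standardized variance: the expected standard deviation at a
    gene's mean comes from a lowess fit (span 0.3) of log10 variance on
    log10 mean; standardized values are clipped at sqrt(n) before the
    variance is recomputed. Ties and order are deterministic.
    """
    y = m.counts.astype(float)
    n = m.n_locations
    mean = y.mean(axis=1)
    var = y.var(axis=1, ddof=1)
    if m.n_genes <= n_top:
        return list(m.gene_ids)

    usable = (mean > 0) & (var > 0)
    log_mean = np.log10(mean[usable])
    log_var = np.log10(var[usable])
    fitted = lowess(log_var, log_mean, frac=0.3, return_sorted=False)
    exp_sd = np.sqrt(10.0**fitted)

    std_var = np.zeros(m.n_genes)
    rows = np.flatnonzero(usable)
    clip = np.sqrt(n)
    for j, g in enumerate(rows):
        z = (y[g] - mean[g]) / exp_sd[j]
        z = np.minimum(z, clip)
        std_var[g] = (z**2).sum() / (n - 1)

    order = np.argsort(-std_var, kind="stable")
    return [m.gene_ids[i] for i in order[:n_top]]


def embed_pca(x: np.ndarray, n_pcs: int = 15) -> np.ndarray:
    """PCA scores (locations x components) of a gene x location matrix.

    Rows are centered and unit-scaled (zero-variance rows dropped); the sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std(axis=1, ddof=0)
    keep = sd > 0
    xs = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    max_pcs = min(xs.shape)
    if n_pcs > max_pcs:
        logger.warning("n_pcs=%d reduced to %d (matrix rank limit)", n_pcs, max_pcs)
        n_pcs = max_pcs
    # SVD of locations x genes
    U, S, Vt = np.linalg.svd(xs.T, full_matrices=False)
    scores = U[:, :n_pcs] * S[:n_pcs]
    loadings = Vt[:n_pcs]
    for c in range(n_pcs):
        if loadings[c, np.argmax(np.abs(loadings[c]))] < 0:
            scores[:, c] *= -1
    return scores


def _snn_graph(scores: np.ndarray, k_neighbors: int) -> igraph.Graph:
    n = scores.shape[0]
    nn = NearestNeighbors(n_neighbors=k_neighbors).fit(scores)
    _, idx = nn.kneighbors(scores)  # includes self
    neigh = [set(row) for row in idx]
    edges, weights = [], []
    for i in range(n):
        cands = set()
        for j in idx[i]:
            cands.update(idx[j])
        for j in cands:
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[int(j)])
            jac = inter / (2 * k_neighbors - inter)
            if jac >= SNN_PRUNE:
                edges.append((i, int(j)))
                weights.append(jac)
    g = igraph.Graph(n=n, edges=edges)
    g.es["weight"] = weights
    return g


def cluster_locations(
    scores: np.ndarray,
    resolution: float = 0.5,
    k_neighbors: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """SNN graph + Louvain modularity communities on embedding scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] < k_neighbors + 1:
        raise ValueError(
            f"{scores.shape[0]} locations < k_neighbors+1 = {k_neighbors + 1}"
        )
    g = _snn_graph(scores, k_neighbors)
    state = random.getstate()
    try:
        random.seed(seed)  # igraph draws from python's random module
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        random.setstate(state)
    return ClusterAssignment(
        labels=np.asarray(part.membership),
        params={
            "resolution": resolution,
            "k_neighbors": k_neighbors,
            "snn_prune": SNN_PRUNE,
            "seed": seed,
        },
    )


def cluster_pipeline(
    m: CountMatrix,
    n_hvg: int = 2000,
    n_pcs: int = 15,
    resolution: float = 0.5,
    k_neighbors: int = 20,
    seed: int = 0,
) -> ClusterAssignment:
    """normalize -> HVG -> PCA -> SNN/Louvain, with parameters recorded."""
    hvg = select_hvg(m, n_top=n_hvg)
    sub = m.subset_genes([m.gene_ids.index(g) for g in hvg])
    x = normalize_log(sub)
    scores = embed_pca(x, n_pcs=n_pcs)
    ca = cluster_locations(scores, resolution, k_neighbors, seed)
    ca.params.update({"scale_factor": SCALE_FACTOR, "n_hvg": n_hvg, "n_pcs": n_pcs})
    return ca


def cluster_specific_panel(
    m: CountMatrix,
    ca: ClusterAssignment,
    min_cluster_size: int = 20,
    alpha: float = 0.05,
    boundary_mixture: bool = False,
) -> dict[int, pd.DataFrame]:
    """Re-run the gene panel inside each cluster.

    Genes all-zero within a cluster are dropped there; offsets and the
    Bonferroni denominator are cluster-local. Clusters below
    ``min_cluster_size`` are skipped with a log entry.
    """
    if len(ca.labels) != m.n_locations:
        raise ValueError("assignment length does not match matrix locations")
    panels: dict[int, pd.DataFrame] = {}
    for c in range(ca.n_clusters):
        idx = np.flatnonzero(ca.labels == c)
        if len(idx) < min_cluster_size:
            logger.info("skipping cluster %d (%d locations)", c, len(idx))
            continue
        sub = filter_genes(m.subset_locations(idx))
        panels[c] = run_gene_panel(
            sub, alpha=alpha, boundary_mixture=boundary_mixture
        )
    return panels


_CATEGORIES = (
    [("prefer", f) for f in ("poisson", "nb", "zip", "zinb")]
    + [("sig", t) for t in ("p_zip", "p_nb", "nb_zinb", "zip_zinb")]
)


def _category_prop(panel: pd.DataFrame, kind: str, name: str) -> float:
    ok = panel[panel["error"] == ""]
    if len(ok) == 0:
        return np.nan
    if kind == "prefer":
        return float((ok["preferred_family"] == name).mean())
    return float(ok[f"sig_{name}"].mean())


def before_after_ratios(
    whole: pd.DataFrame, per_cluster: dict[int, pd.DataFrame]
) -> tuple[pd.DataFrame, dict]:
    """After/before proportion ratios per cluster and their medians.

    For each of eight categories (four AIC preferences, four LRT-significant
    sets) the within-cluster proportion is divided by the whole-tissue
    proportion. Clusters with a zero whole-tissue proportion have an
    undefined ratio and are omitted from that category's median.
    """
    rows = []
    for kind, name in _CATEGORIES:
        before = _category_prop(whole, kind, name)
        for c, panel in per_cluster.items():
            after = _category_prop(panel, kind, name)
            ratio = after / before if before > 0 else np.nan
            rows.append(
                {
                    "cluster": c,
                    "category": f"{kind}_{name}",
                    "prop_before": before,
                    "prop_after": after,
                    "ratio": ratio,
                }
            )
    table = pd.DataFrame(rows)
    medians = {}
    for cat, grp in table.groupby("category"):
        defined = grp["ratio"].dropna()
        n_omitted = int(grp["ratio"].isna().sum())
        if n_omitted:
            logger.info("category %s: %d cluster(s) omitted from median", cat, n_omitted)
        medians[cat] = float(defined.median()) if len(defined) else None
    return table, medians
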