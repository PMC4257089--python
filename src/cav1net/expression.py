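"""Fold-change expression analysis: clustering and CAV1 correlation.

The downstream pipeline for patient expression data: per-gene log2
fold-change of each disease-subtype group versus healthy controls,
agglomerative clustering of the fold-change profiles under the uncentered
correlation metric with unweighted average linkage (the classic Cluster 3.0
configuration, with Java TreeView-loadable ``.cdt``/``.gtr`` output), and
per-gene Pearson correlation against a reference gene (CAV1) across subtype
columns.

A seeded synthetic fold-change generator with planted CAV1 correlations
stands in for the cohort microarray data (which requires an external
download); its default planted targets are the correlations reported for
adult T-cell leukemia subtypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "compute_fold_change",
    "pearson_correlation",
    "uncentered_correlation",
    "ClusterTree",
    "hierarchical_cluster",
    "correlate_with_reference",
    "generate_synthetic_foldchange",
    "PLANTED_ATL",
    "ATL_GROUPS",
    "write_cdt_gtr",
]

#: default planted CAV1 correlations for the synthetic fold-change generator
#: (the reported ATL-subtype correlation signature)
PLANTED_ATL: Dict[str, float] = {
    "BCL10": 0.947,
    "DEC2": 0.782,
    "SHP2": 0.742,
    "GATA3": 0.694,
    "SOS1": -0.981,
    "FYN": -0.949,
    "SOS2": -0.825,
    "CD26": -0.740,
}

#: ATL subtype column order (healthy is the fold-change denominator)
ATL_GROUPS = ("ASYM", "SMLD", "CHRN", "ACUT")


# ---------------------------------------------------------------------------
# Fold change
# ---------------------------------------------------------------------------

def compute_fold_change(matrix: pd.DataFrame,
                        groups: Mapping[str, str],
                        control_group: str = "Healthy") -> pd.DataFrame:
    """log2(group mean / control mean) per gene and non-control group.

    ``matrix`` is genes x samples with positive intensities; ``groups`` maps
    each sample to its group.  Column order follows first appearance in
    ``groups`` (control excluded).
    """
    ungrouped = [s for s in matrix.columns if s not in groups]
    if ungrouped:
        raise ValueError(f"samples without a group: {ungrouped}")
    if (matrix.values <= 0).any():
        raise ValueError("intensities must be positive")
    order: List[str] = []
    for sample in matrix.columns:
        g = groups[sample]
        if g not in order:
            order.append(g)
    if control_group not in order:
        raise ValueError(f"control group {control_group!r} has no samples")

    control_samples = [s for s in matrix.columns if groups[s] == control_group]
    control_mean = matrix[control_samples].mean(axis=1)
    cols = {}
    for g in order:
        if g == control_group:
            continue
        samples = [s for s in matrix.columns if groups[s] == g]
        cols[g] = np.log2(matrix[samples].mean(axis=1) / control_mean)
    fc = pd.DataFrame(cols)
    fc.index.name = matrix.index.name or "gene"
    return fc


# ---------------------------------------------------------------------------
# Correlation measures
# ---------------------------------------------------------------------------

def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; rejects constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))


def uncentered_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine similarity (Pearson without mean-centering)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be 1-D of equal length >= 1")
    nx = np.sqrt(x @ x)
    ny = np.sqrt(y @ y)
    if nx == 0 or ny == 0:
        raise ValueError("uncentered correlation undefined for a zero vector")
    return float((x @ y) / (nx * ny))


_METRICS: Dict[str, Callable] = {
    "uncentered": uncentered_correlation,
    "pearson": pearson_correlation,
}


# ---------------------------------------------------------------------------
# Hierarchical clustering (UPGMA over 1 - similarity)
# ---------------------------------------------------------------------------

@dataclass
class ClusterTree:
    """Merge history of an agglomerative clustering.

    Cluster ids follow the usual convention: leaves are ``0..n-1`` in input
    order; the ``i``-th merge creates cluster ``n + i``.  Each merge records
    (left id, right id, similarity at merge), where the similarity is the
    unweighted average over all original item pairs between the two clusters.
    """

    n_items: int
    labels: List[str]
    merges: List[Tuple[int, int, float]]

    @property
    def leaf_order(self) -> List[int]:
        """Left-to-right leaf order of the dendrogram (left = earlier id)."""
        children = {self.n_items + i: (a, b) for i, (a, b, _) in enumerate(self.merges)}
        merged = {a for a, _, _ in self.merges} | {b for _, b, _ in self.merges}
        roots = [i for i in range(self.n_items + len(self.merges)) if i not in merged]

        order: List[int] = []

        def walk(node: int) -> None:
            if node < self.n_items:
                order.append(node)
            else:
                a, b = children[node]
                walk(a)
                walk(b)

        for r in roots:
            walk(r)
        return order

    def members(self, node: int) -> frozenset:
        if node < self.n_items:
            return frozenset({node})
        a, b, _ = self.merges[node - self.n_items]
        return self.members(a) | self.members(b)


def hierarchical_cluster(matrix,
                         similarity: str = "uncentered",
                         labels: Optional[Sequence[str]] = None) -> ClusterTree:
    """Agglomerative clustering on distance ``1 - similarity``, UPGMA linkage.

    The inter-cluster distance is the unweighted mean over all pairs of
    *original* items (recomputed exactly at each step).  Ties break toward
    the pair with the lowest cluster ids (lowest first member on the first
    merge round).
    """
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = list(matrix.index)
        data = matrix.values.astype(float)
    else:
        data = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [f"item{i}" for i in range(len(data))]
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    metric = _METRICS[similarity] if isinstance(similarity, str) else similarity

    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = 1.0 - metric(data[i], data[j])

    clusters: Dict[int, List[int]] = {i: [i] for i in range(n)}
    merges: List[Tuple[int, int, float]] = []
    next_id = n
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = float(np.mean([dist[p, q]
                                   for p in clusters[a] for q in clusters[b]]))
                if best is None or d < best[0] - 1e-12:
                    best = (d, a, b)
        d, a, b = best
        merges.append((a, b, 1.0 - d))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return ClusterTree(n, list(labels), merges)


def write_cdt_gtr(tree: ClusterTree, matrix: pd.DataFrame, prefix) -> None:
    """Write Cluster 3.0-compatible ``.cdt`` and ``.gtr`` files.

    ``matrix`` rows must match the items clustered (same order as the tree's
    leaves by index).  Java TreeView loads the pair.
    """
    from pathlib import Path

    prefix = Path(prefix)
    n = tree.n_items

    def node_name(i: int) -> str:
        return f"GENE{i}X" if i < n else f"NODE{i - n}X"

    gtr_lines = []
    for k, (a, b, sim) in enumerate(tree.merges):
        gtr_lines.append(f"NODE{k}X\t{node_name(a)}\t{node_name(b)}\t{sim:.6f}")
    prefix.with_suffix(".gtr").write_text("\n".join(gtr_lines) + "\n",
                                          encoding="utf-8")

    cols = list(matrix.columns)
    header = "GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(cols)
    eweight = "EWEIGHT\t\t\t" + "\t1" * len(cols)
    lines = [header, eweight]
    for i in tree.leaf_order:
        label = tree.labels[i]
        values = "\t".join(f"{v:.6f}" for v in matrix.iloc[i].values)
        lines.append(f"GENE{i}X\t{label}\t{label}\t1\t{values}")
    prefix.with_suffix(".cdt").write_text("\n".join(lines) + "\n",
                                          encoding="utf-8")


# ---------------------------------------------------------------------------
# Correlation against a reference gene
# ---------------------------------------------------------------------------

def correlate_with_reference(fc_matrix: pd.DataFrame,
                             reference_gene: str = "CAV1") -> pd.DataFrame:
    """Per-gene Pearson r (plus regression slope/intercept) vs the reference.

    Computed across the fold-change columns; genes with constant profiles are
    skipped with a warning.  Sorted by r descending.
    """
    if reference_gene not in fc_matrix.index:
        raise ValueError(f"reference gene {reference_gene!r} not in matrix")
    if fc_matrix.shape[1] < 3:
        raise ValueError("need at least 3 columns for correlation")
    ref = fc_matrix.loc[reference_gene].values.astype(float)
    if np.ptp(ref) == 0:
        raise ValueError("reference profile is constant")
    rows = []
    for gene in fc_matrix.index:
        y = fc_matrix.loc[gene].values.astype(float)
        if np.ptp(y) == 0:
            warnings.warn(f"gene {gene!r} has a constant profile; skipped")
            continue
        r = pearson_correlation(ref, y)
        slope = r * y.std(ddof=0) / ref.std(ddof=0)
        intercept = y.mean() - slope * ref.mean()
        rows.append((gene, r, slope, intercept))
    out = pd.DataFrame(rows, columns=["gene", "r", "slope", "intercept"])
    out = out.sort_values(["r", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Synthetic fold-change generator
# ---------------------------------------------------------------------------

def generate_synthetic_foldchange(planted: Optional[Mapping[str, float]] = None,
                                  n_columns: int = 4,
                                  noise_sd: float = 1.0,
                                  seed: int = 0,
                                  reference_gene: str = "CAV1",
                                  column_names: Optional[Sequence[str]] = None
                                  ) -> pd.DataFrame:
    """Seeded fold-change matrix with planted correlations to the reference.

    The reference profile ``z`` is standard normal over the columns; each
    planted gene is ``r*z + sqrt(1-r^2)*noise_sd*eps`` with independent
    standard-normal ``eps`` — at ``noise_sd=1`` the population correlation
    with the reference equals the planted ``r``.
    """
    if planted is None:
        planted = PLANTED_ATL
    if n_columns < 3:
        raise ValueError("need at least 3 columns")
    for gene, r in planted.items():
        if not (-1.0 < r < 1.0):
            raise ValueError(f"planted r for {gene!r} must be in (-1, 1)")
    if column_names is None:
        column_names = (list(ATL_GROUPS) if n_columns == 4
                        else [f"G{j}" for j in range(n_columns)])
    if len(column_names) != n_columns:
        raise ValueError("column_names length must equal n_columns")

    rng = np.random.default_rng(seed)
    z = rng.standard_normal(n_columns)
    rows = {reference_gene: z}
    for gene, r in planted.items():
        eps = rng.standard_normal(n_columns)
        rows[gene] = r * z + np.sqrt(1.0 - r * r) * noise_sd * eps
    fc = pd.DataFrame.from_dict(rows, orient="index", columns=list(column_names))
    fc.index.name = "gene"
    return fc
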