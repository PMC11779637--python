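"""Tabular stages of imaging-mass-cytometry analysis: priority-ordered cell
phenotyping from mask-overlap fractions, silhouette-driven cluster-resolution
selection, and relative-abundance summaries.

A segmented cell is assigned the first phenotype, in a fixed priority order,
whose mask overlaps the cell by at least 10%; cells below 10% overlap with
every mask stay unassigned.  The default priority order is neutrophil, NK,
dendritic, macrophage, M-MDSC, G-MDSC, T, tumor, stromal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples
from sklearn.neighbors import kneighbors_graph

DEFAULT_PRIORITY = ("neutrophil", "NK", "dendritic", "macrophage",
                    "M-MDSC", "G-MDSC", "T", "tumor", "stromal")
OVERLAP_THRESHOLD = 0.10


def assign_phenotypes(cells: pd.DataFrame, threshold: float = OVERLAP_THRESHOLD,
                      priority: tuple = DEFAULT_PRIORITY) -> pd.Series:
    """Per-cell phenotype from overlap_* columns.

    The first phenotype in ``priority`` with overlap >= ``threshold`` wins —
    order beats magnitude.  Cells below threshold on every mask are
    'unassigned'.  Overlap columns not named in the priority list are
    rejected.
    """
    overlap_cols = [c for c in cells.columns if c.startswith("overlap_")]
    if not overlap_cols:
        raise ValueError("no overlap_* columns in cell table")
    unknown = [c for c in overlap_cols if c[len("overlap_"):] not in priority]
    if unknown:
        raise ValueError(f"overlap columns not in the priority list: {unknown}")
    out = pd.Series("unassigned", index=cells.index, name="phenotype")
    assigned = np.zeros(len(cells), dtype=bool)
    for ph in priority:
        col = f"overlap_{ph}"
        if col not in cells.columns:
            continue
        hit = (~assigned) & (cells[col].to_numpy(dtype=float) >= threshold)
        out.iloc[np.flatnonzero(hit)] = ph
        assigned |= hit
    return out


def leiden_clusterer(features: np.ndarray, resolution: float, seed: int,
                     n_neighbors: int = 15) -> np.ndarray:
    """Default injected clusterer: kNN graph + Leiden community detection at
    the given resolution (graph-clustering backend comparable to the usual
    single-cell toolchains)."""
    import igraph as ig
    import leidenalg

    n = features.shape[0]
    knn = kneighbors_graph(features, n_neighbors=min(n_neighbors, n - 1),
                           mode="connectivity")
    knn = knn.maximum(knn.T).tocoo()
    g = ig.Graph(n=n, edges=list(zip(knn.row.tolist(), knn.col.tolist())))
    g.simplify()
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=int(seed))
    return np.asarray(part.membership)


def select_cluster_resolution(features: np.ndarray,
                              resolutions: tuple = (0.3, 0.5, 0.7, 0.9),
                              seed: int = 123, clusterer=leiden_clusterer) -> dict:
    """Cluster at each resolution with a fixed seed and return the solution
    with the highest median silhouette (ties break toward the lower
    resolution).  Resolutions yielding a single cluster are skipped."""
    features = np.asarray(features, dtype=float)
    if features.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    best = None
    for res in sorted(resolutions):
        labels = clusterer(features, res, seed)
        if len(np.unique(labels)) < 2:
            warnings.warn(f"resolution {res} yields a single cluster; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        med = float(np.median(silhouette_samples(features, labels)))
        if best is None or med > best["median_silhouette"]:
            best = {"resolution": res, "labels": labels,
                    "median_silhouette": med,
                    "n_clusters": int(len(np.unique(labels)))}
    if best is None:
        raise ValueError("no valid clustering: every resolution collapsed "
                         "to a single cluster")
    return best


def relative_abundance(assignments: pd.DataFrame, numerator: set,
                       denominator: set | None = None) -> pd.Series:
    """Per-sample fraction of numerator-phenotype cells over denominator cells
    (all cells when ``denominator`` is None).  A zero denominator yields NaN."""
    req = {"sample", "phenotype"}
    if not req.issubset(assignments.columns):
        raise ValueError(f"assignments need columns {sorted(req)}")
    out = {}
    for sample, grp in assignments.groupby("sample"):
        denom = grp if denominator is None else grp[grp["phenotype"].isin(denominator)]
        num = grp[grp["phenotype"].isin(numerator)]
        out[sample] = len(num) / len(denom) if len(denom) else np.nan
    return pd.Series(out, name="fraction").sort_index()
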