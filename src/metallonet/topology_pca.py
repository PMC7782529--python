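"""Topology profiling and PCA-based plausibility testing of networks.

Seven headline topological parameters are computed per network (node count,
edge count, average degree, density, average clustering coefficient,
characteristic path length and diameter — the path metrics on the largest
connected component).  PCA of the column-standardized parameter matrix over
all networks then tests whether biologically constructed networks (metal and
pathway classes) occupy a different region of topology space than
size-matched random graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core_io import InteractionGraph, logger

PARAMETER_NAMES = (
    "n_nodes",
    "n_edges",
    "avg_degree",
    "density",
    "avg_clustering",
    "char_path_length",
    "diameter",
)


@dataclass
class TopologyProfile:
    network_id: str
    label: str                     # metal | random | pathway
    parameters: dict[str, float]

    def vector(self, names: tuple[str, ...] = PARAMETER_NAMES) -> np.ndarray:
        return np.array([self.parameters[n] for n in names], dtype=float)


def topology_profile(graph: InteractionGraph) -> TopologyProfile:
    """Compute the seven parameters; singleton graphs get path length and
    diameter 0 by convention."""
    g = graph.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot profile an empty graph")
    m = g.number_of_edges()
    avg_degree = 2.0 * m / n
    density = nx.density(g) if n > 1 else 0.0
    clustering = nx.average_clustering(g) if n > 0 else 0.0
    largest = max(nx.connected_components(g), key=len)
    if len(largest) > 1:
        comp = g.subgraph(largest)
        cpl = nx.average_shortest_path_length(comp)
        diam = nx.diameter(comp)
    else:
        cpl = 0.0
        diam = 0.0
    params = {
        "n_nodes": float(n),
        "n_edges": float(m),
        "avg_degree": avg_degree,
        "density": density,
        "avg_clustering": clustering,
        "char_path_length": float(cpl),
        "diameter": float(diam),
    }
    return TopologyProfile(network_id=graph.name or "network", label=graph.label,
                           parameters=params)


@dataclass
class PCAResult:
    scores: pd.DataFrame            # networks x components
    loadings: pd.DataFrame          # parameters x components
    variance_fractions: np.ndarray  # over all retained components
    labels: pd.Series               # network -> class label
    dropped_columns: list[str] = field(default_factory=list)


def run_pca(profiles: list[TopologyProfile], standardize: bool = True,
            parameter_names: tuple[str, ...] = PARAMETER_NAMES) -> PCAResult:
    """PCA of the (optionally column-standardized) parameter matrix.

    Constant columns are dropped with a warning (they carry no variance and
    break standardization).  The sign of each component is fixed by making
    its largest-magnitude loading positive, so results are bit-stable.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles for PCA")
    ids = [p.network_id for p in profiles]
    if len(set(ids)) != len(ids):
        ids = [f"{p.network_id}#{i}" for i, p in enumerate(profiles)]
    X = pd.DataFrame([p.vector(parameter_names) for p in profiles],
                     index=ids, columns=list(parameter_names))
    constant = [c for c in X.columns if np.isclose(X[c].std(ddof=0), 0.0)]
    if constant:
        logger.warning("dropping constant parameter column(s): %s", constant)
        X = X.drop(columns=constant)
    if X.shape[1] == 0:
        raise ValueError("all parameter columns are constant")
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    if standardize:
        M = M / M.std(axis=0, ddof=1)
    pca = PCA()
    scores = pca.fit_transform(M)
    loadings = pca.components_.T           # parameters x components
    # sign convention: largest-|loading| entry of each component positive
    # (near-ties resolved to the first entry, so float noise cannot flip it)
    for j in range(loadings.shape[1]):
        mags = np.abs(loadings[:, j])
        k = int(np.flatnonzero(mags >= mags.max() - 1e-9)[0])
        if loadings[k, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(scores.shape[1])]
    return PCAResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        variance_fractions=pca.explained_variance_ratio_.copy(),
        labels=pd.Series([p.label for p in profiles], index=X.index),
        dropped_columns=constant,
    )


@dataclass
class SeparationReport:
    silhouette_bio_vs_random: float
    centroid_distances: dict[tuple[str, str], float]


def grouping_score(result: PCAResult, labels: pd.Series | None = None,
                   n_components: int = 2) -> SeparationReport:
    """Quantify whether metal+pathway networks separate from random ones.

    Silhouette of the two-group partition {metal ∪ pathway} vs {random} on
    the first ``n_components`` PC scores, plus pairwise class-centroid
    distances in the same space.
    """
    labels = result.labels if labels is None else labels
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if (labels == c).sum() < 1:
            raise ValueError(f"class {c!r} has no members")
    S = result.scores.iloc[:, :n_components].to_numpy()
    binary = np.where(labels.to_numpy() == "random", "random", "biological")
    if len(set(binary)) == 2:
        sil = float(silhouette_score(S, binary))
    else:
        sil = float("nan")
    centroids = {c: S[labels.to_numpy() == c].mean(axis=0) for c in classes}
    dists = {}
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            dists[(a, b)] = float(np.linalg.norm(centroids[a] - centroids[b]))
    return SeparationReport(silhouette_bio_vs_random=sil, centroid_distances=dists)


def profiles_frame(profiles: list[TopologyProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"network": p.network_id, "label": p.label}
        row.update(p.parameters)
        rows.append(row)
    return pd.DataFrame(rows)
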