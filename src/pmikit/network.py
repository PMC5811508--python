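"""Sample correlation networks, modularity across PMI bins, and MDS.

To test whether tissue transcriptional signatures persist across PMI, the
samples in each PMI bin are balanced (the same number of samples per tissue
in every bin), a network is built whose nodes are samples and whose edges
connect sample pairs with Pearson correlation above a threshold, and the
Newman-Girvan modularity of the partition by tissue label is computed on
the unweighted thresholded graph. The MDS embedding uses the
1 - Pearson-correlation distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform
from sklearn.manifold import MDS

from .containers import ExpressionMatrix
from .preprocess import assign_pmi_intervals

__all__ = [
    "SampleNetwork",
    "balanced_subsample",
    "build_network",
    "modularity_score",
    "modularity_sweep",
    "mds_embed",
]


@dataclass
class SampleNetwork:
    """Thresholded, unweighted sample-correlation graph with tissue labels."""

    graph: nx.Graph
    threshold: float
    labels: dict[str, str]

    @property
    def density(self) -> float:
        n = self.graph.number_of_nodes()
        if n < 2:
            return 0.0
        return self.graph.number_of_edges() / (n * (n - 1) / 2)


def balanced_subsample(
    samples: pd.DataFrame,
    min_per_bin: int = 10,
    seed: int = 0,
    bins: list[str] | None = None,
) -> dict[str, list[str]]:
    """Per PMI bin, the same number of samples from each retained tissue.

    Tissues with fewer than ``min_per_bin`` samples in any bin are dropped;
    every retained tissue contributes exactly k samples per bin, where k is
    the minimum available count over all (bin, tissue) pairs. Selection is
    seeded and reproducible.
    """
    post = samples.loc[~samples["premortem"]].copy()
    intervals = assign_pmi_intervals(post)
    post = post.set_index("sample_id")
    post["bin"] = intervals
    counts = post.groupby(["tissue", "bin"], observed=True).size().unstack(fill_value=0)
    if bins is None:
        bins = [b for b in counts.columns if counts[b].sum() > 0]
    counts = counts[bins]
    ok = counts.ge(min_per_bin).all(axis=1)
    tissues = counts.index[ok]
    if len(tissues) == 0:
        raise ValueError(f"no tissue has >= {min_per_bin} samples in every bin")
    k = int(counts.loc[tissues].min().min())
    rng = np.random.default_rng(seed)
    out: dict[str, list[str]] = {}
    for b in bins:
        chosen: list[str] = []
        for t in tissues:
            pool = post.index[(post["tissue"] == t) & (post["bin"] == b)].to_numpy()
            chosen.extend(rng.choice(np.sort(pool), size=k, replace=False))
        out[str(b)] = chosen
    return out


def build_network(
    log_expr: pd.DataFrame, threshold: float, labels: dict[str, str]
) -> SampleNetwork:
    """Build the sample graph: edge iff pairwise Pearson r > threshold."""
    corr = np.corrcoef(log_expr.to_numpy(float).T)
    ids = list(log_expr.columns)
    G = nx.Graph()
    G.add_nodes_from(ids)
    n = len(ids)
    iu, ju = np.triu_indices(n, k=1)
    hits = corr[iu, ju] > threshold
    G.add_edges_from((ids[i], ids[j]) for i, j in zip(iu[hits], ju[hits]))
    return SampleNetwork(graph=G, threshold=threshold, labels=dict(labels))


def modularity_score(net: SampleNetwork) -> float:
    """Newman-Girvan modularity of the tissue-label partition,
    Q = sum_c [e_c/m - (d_c/2m)^2] on the unweighted graph."""
    missing = [n for n in net.graph.nodes if n not in net.labels]
    if missing:
        raise ValueError(f"nodes without a tissue label: {missing[:5]}")
    if net.graph.number_of_edges() == 0:
        warnings.warn("network has no edges; modularity defined as 0")
        return 0.0
    groups: dict[str, set] = {}
    for node in net.graph.nodes:
        groups.setdefault(net.labels[node], set()).add(node)
    return float(nx.algorithms.community.modularity(net.graph, groups.values()))


def modularity_sweep(
    mat: ExpressionMatrix,
    bins: dict[str, list[str]],
    thresholds: list[float],
    samples: pd.DataFrame,
) -> pd.DataFrame:
    """Per (PMI bin, threshold): network density and modularity.

    Correlations are computed on log2(RPKM + 1), matching the expression
    scale used to define the networks.
    """
    if not thresholds:
        raise ValueError("empty threshold list")
    labels = samples.set_index("sample_id")["tissue"].to_dict()
    log_expr = np.log2(mat.rpkm + 1.0)
    rows = []
    for b, ids in bins.items():
        sub = log_expr[ids]
        for thr in thresholds:
            net = build_network(sub, thr, labels)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                q = modularity_score(net)
            rows.append(
                {
                    "bin": b,
                    "threshold": thr,
                    "n_samples": len(ids),
                    "n_edges": net.graph.number_of_edges(),
                    "density": net.density,
                    "modularity": q,
                }
            )
    return pd.DataFrame(rows)


def mds_embed(
    log_expr: pd.DataFrame, dims: int = 2, seed: int = 0
) -> tuple[pd.DataFrame, float, np.ndarray]:
    """Non-metric MDS on the 1 - Pearson-correlation distance.

    Returns (coordinates, stress, average-linkage matrix on the same
    distance). Samples with a constant profile have undefined correlation
    and are dropped with a warning.
    """
    X = log_expr.to_numpy(float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(f"dropping {np.sum(~keep)} constant samples from the embedding")
        X = X[:, keep]
    ids = log_expr.columns[keep]
    if X.shape[1] < dims + 1:
        raise ValueError("need at least dims + 1 non-constant samples")
    dist = 1.0 - np.corrcoef(X.T)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    mds = MDS(
        n_components=dims,
        dissimilarity="precomputed",
        metric=False,
        normalized_stress=True,
        random_state=seed,
        n_init=4,
        max_iter=300,
    )
    coords = mds.fit_transform((dist + dist.T) / 2)
    linkage = average(squareform((dist + dist.T) / 2, checks=False))
    frame = pd.DataFrame(
        coords, index=ids, columns=[f"dim{i + 1}" for i in range(dims)]
    )
    return frame, float(mds.stress_), linkage
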