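"""Survey2Vector network inference: cosine similarity and thresholding.

Respondents become nodes; the cosine similarity S_ij between their [0, 1]
feature vectors is computed for every pair, and an undirected simple graph
is formed by linking pairs with S_ij >= t.  Because feature vectors are
nonnegative, all similarities lie in [0, 1].  The published threshold for
the reference cohort was t = 0.7799, chosen there to match an average
degree estimated by the company's HR director; the estimation procedure
itself was never published, so calibration here is by the empirical
similarity quantile that attains a requested average degree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .codec import FeatureMatrix

#: Published similarity threshold for the reference cohort.
DEFAULT_THRESHOLD = 0.7799


class NetworkInferenceError(ValueError):
    pass


@dataclass
class SimilarityMatrix:
    """Symmetric N x N cosine-similarity matrix with unit diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise NetworkInferenceError("similarity matrix shape mismatch")

    @property
    def n(self) -> int:
        return len(self.ids)

    def offdiagonal(self) -> np.ndarray:
        """Upper-triangle similarities as a flat vector (one per dyad)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="respondent_id")


def cosine_similarity_matrix(features: FeatureMatrix) -> SimilarityMatrix:
    """S_ij = <X_i, X_j> / (||X_i|| ||X_j||) for all respondent pairs.

    The diagonal is set to exactly 1 and rounding overshoot is clipped to
    [0, 1].  A zero-norm row has no direction and is an error naming the
    respondent.
    """
    x = features.values
    norms = np.linalg.norm(x, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise NetworkInferenceError(
            f"respondent {features.row_ids[zero[0]]!r} has a zero feature "
            "vector; cosine similarity is undefined")
    sims = (x @ x.T) / np.outer(norms, norms)
    np.clip(sims, 0.0, 1.0, out=sims)
    np.fill_diagonal(sims, 1.0)
    sims = 0.5 * (sims + sims.T)  # enforce exact symmetry
    return SimilarityMatrix(sims, list(features.row_ids))


def threshold_network(sims: SimilarityMatrix, t: float,
                      attrs: dict[str, str] | pd.Series | None = None
                      ) -> nx.Graph:
    """Adjacency by thresholding: edge (i, j) iff S_ij >= t, i != j.

    Isolated nodes are retained.  ``attrs`` maps respondent id to burnout
    status and is stored as the ``burnout`` node attribute.
    """
    if not 0.0 <= t <= 1.0:
        raise NetworkInferenceError("threshold must lie in [0, 1]")
    n = sims.n
    g = nx.Graph(threshold_used=float(t))
    g.add_nodes_from(sims.ids)
    adj = sims.values >= t
    iu, ju = np.nonzero(np.triu(adj, k=1))
    ids = sims.ids
    g.add_edges_from((ids[i], ids[j]) for i, j in zip(iu, ju))
    if attrs is not None:
        mapping = dict(attrs) if not isinstance(attrs, dict) else attrs
        missing = [i for i in ids if i not in mapping]
        if missing:
            raise NetworkInferenceError(
                f"no burnout status for respondent {missing[0]!r}")
        nx.set_node_attributes(
            g, {i: mapping[i] for i in ids}, "burnout")
    return g


def calibrate_threshold(sims: SimilarityMatrix,
                        target_avg_degree: float) -> float:
    """Largest threshold whose network has average degree >= target.

    The threshold is the empirical quantile of the off-diagonal
    similarities at rank 1 - d/(N-1): with E = ceil(N*d/2) edges wanted,
    t is the E-th largest dyad similarity, so the >= rule admits at least
    E edges (more only under ties at t).
    """
    n = sims.n
    if not 0 < target_avg_degree <= n - 1:
        raise NetworkInferenceError(
            f"target average degree must lie in (0, {n - 1}]")
    off = np.sort(sims.offdiagonal())[::-1]
    n_edges = int(np.ceil(target_avg_degree * n / 2.0))
    n_edges = min(n_edges, off.size)
    return float(off[n_edges - 1])


def network_summary(g: nx.Graph) -> dict:
    """Basic size/degree/density summary plus burnout composition."""
    n = g.number_of_nodes()
    e = g.number_of_edges()
    density = 2.0 * e / (n * (n - 1)) if n > 1 else 0.0
    statuses = [d.get("burnout") for _, d in g.nodes(data=True)]
    counts: dict[str, int] = {}
    for s in statuses:
        if s is not None:
            counts[s] = counts.get(s, 0) + 1
    return {
        "n_nodes": n,
        "n_edges": e,
        "average_degree": 2.0 * e / n if n else 0.0,
        "density": density,
        "burnout_counts": counts,
        "threshold_used": g.graph.get("threshold_used"),
    }


def write_network(g: nx.Graph, edges_path, attrs_path) -> None:
    """Edge list (id_i, id_j) and node-attribute table, both TSV."""
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("id_i\tid_j\n")
        for u, v in g.edges():
            fh.write(f"{u}\t{v}\n")
    with open(attrs_path, "w", encoding="utf-8") as fh:
        fh.write("respondent_id\tburnout\n")
        for node, data in g.nodes(data=True):
            fh.write(f"{node}\t{data.get('burnout', '')}\n")


def read_network(edges_path, attrs_path) -> nx.Graph:
    attrs = pd.read_csv(attrs_path, sep="\t", dtype=str)
    g = nx.Graph()
    for _, row in attrs.iterrows():
        g.add_node(row["respondent_id"], burnout=row["burnout"])
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    for _, row in edges.iterrows():
        if row["id_i"] not in g or row["id_j"] not in g:
            raise NetworkInferenceError(
                f"edge references unknown node {row['id_i']!r}/"
                f"{row['id_j']!r}")
        g.add_edge(row["id_i"], row["id_j"])
    return g
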