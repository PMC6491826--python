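"""Per-state co-occurrence networks from thresholded correlations.

Within each disease state, feature-feature correlations (Pearson by default,
Spearman by flag) are computed across that state's samples after a
prevalence filter; pairs whose coefficient passes a fixed threshold become
edges.  Node weight is the feature's mean relative abundance in the state.
Networks from different states share the feature vocabulary and can be
compared edge-set-wise (shared vs state-unique co-occurrences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .tables import CountTable, write_commented_tsv


class NetworkError(ValueError):
    """Raised for invalid network inputs."""


@dataclass(frozen=True)
class NetworkConfig:
    method: str = "pearson"
    threshold: float = 0.5
    use_absolute: bool = True
    min_prevalence: float = 0.1

    def __post_init__(self) -> None:
        if self.method not in ("pearson", "spearman"):
            raise NetworkError(f"unknown correlation method {self.method!r}")
        if not (0.0 < self.threshold <= 1.0):
            raise NetworkError("threshold must be in (0, 1]")
        if not (0.0 <= self.min_prevalence <= 1.0):
            raise NetworkError("min_prevalence must be in [0, 1]")


@dataclass
class CooccurrenceNetwork:
    """Thresholded correlation network for one disease state."""

    state: str
    nodes: dict[str, float]  # feature id -> mean relative abundance
    edges: dict[tuple[str, str], float]  # sorted pair -> correlation

    def edge_set(self) -> set[tuple[str, str]]:
        return set(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(state=self.state)
        for fid, w in self.nodes.items():
            g.add_node(fid, mean_rel_abundance=float(w))
        for (a, b), r in self.edges.items():
            g.add_edge(a, b, correlation=float(r), sign=1 if r >= 0 else -1)
        return g


@dataclass
class NetworkComparison:
    """Edge-set comparison across states."""

    totals: pd.DataFrame  # state, n_edges, n_unique
    shared: dict[tuple[str, str], set[tuple[str, str]]]
    unique: dict[str, set[tuple[str, str]]]


def correlation_matrix(sub_table: CountTable, method: str = "pearson") -> pd.DataFrame:
    """Feature-feature correlation over one state's samples.

    Constant-valued features (correlation undefined) are dropped with a
    warning naming them.  Spearman is Pearson on mid-ranks.
    """
    values = sub_table.values
    if values.shape[1] < 3:
        raise NetworkError(
            f"need at least 3 samples to estimate correlations, got {values.shape[1]}"
        )
    constant = values.std(axis=1) == 0
    if constant.any():
        dropped = [f for f, c in zip(sub_table.feature_ids, constant) if c]
        warnings.warn(
            f"dropping constant feature(s) with undefined correlation: "
            f"{', '.join(dropped)}",
            stacklevel=2,
        )
    kept = [f for f, c in zip(sub_table.feature_ids, constant) if not c]
    data = values[~constant]
    if len(kept) < 2:
        raise NetworkError("fewer than 2 non-constant features")
    if method == "spearman":
        data = np.apply_along_axis(stats.rankdata, 1, data)
    elif method != "pearson":
        raise NetworkError(f"unknown correlation method {method!r}")
    corr = np.corrcoef(data)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=kept, columns=kept)


def build_network(
    sub_table: CountTable, config: NetworkConfig, state: str
) -> CooccurrenceNetwork:
    """Prevalence-filter, correlate, and threshold one state's sub-table."""
    prevalence = (sub_table.values > 0).mean(axis=1)
    keep_ids = [
        f for f, pr in zip(sub_table.feature_ids, prevalence) if pr >= config.min_prevalence
    ]
    if len(keep_ids) < 2:
        raise NetworkError(
            f"state {state!r}: fewer than 2 features pass the prevalence filter"
        )
    filtered = sub_table.subset_features(keep_ids)
    corr = correlation_matrix(filtered, config.method)
    colsums = filtered.values.sum(axis=0)
    if (colsums <= 0).any():
        raise NetworkError(f"state {state!r}: sample with zero total abundance")
    rel = filtered.values / colsums
    mean_rel = {f: float(m) for f, m in zip(filtered.feature_ids, rel.mean(axis=1))}
    ids = list(corr.index)
    nodes = {f: mean_rel[f] for f in ids}
    edges: dict[tuple[str, str], float] = {}
    mat = corr.to_numpy()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = float(mat[i, j])
            passes = abs(r) > config.threshold if config.use_absolute else r > config.threshold
            if passes:
                a, b = sorted((ids[i], ids[j]))
                edges[(a, b)] = r
    return CooccurrenceNetwork(state=state, nodes=nodes, edges=edges)


def compare_networks(
    networks: Sequence[CooccurrenceNetwork],
) -> NetworkComparison:
    """Per-state edge totals, pairwise shared edges, and state-unique edges."""
    if len(networks) < 2:
        raise NetworkError("need at least 2 networks to compare")
    vocabularies = [set(n.nodes) for n in networks]
    if not any(
        vocabularies[i] & vocabularies[j]
        for i in range(len(networks))
        for j in range(i + 1, len(networks))
    ):
        raise NetworkError("networks share no features; vocabularies are disjoint")
    edge_sets = {n.state: n.edge_set() for n in networks}
    states = [n.state for n in networks]
    shared: dict[tuple[str, str], set[tuple[str, str]]] = {}
    for i in range(len(states)):
        for j in range(i + 1, len(states)):
            shared[(states[i], states[j])] = edge_sets[states[i]] & edge_sets[states[j]]
    unique: dict[str, set[tuple[str, str]]] = {}
    for s in states:
        others = set().union(*(edge_sets[t] for t in states if t != s))
        unique[s] = edge_sets[s] - others
    totals = pd.DataFrame(
        {
            "state": states,
            "n_edges": [len(edge_sets[s]) for s in states],
            "n_unique": [len(unique[s]) for s in states],
        }
    )
    return NetworkComparison(totals=totals, shared=shared, unique=unique)


def edges_frame(networks: Sequence[CooccurrenceNetwork]) -> pd.DataFrame:
    rows = []
    for net in networks:
        for (a, b), r in sorted(net.edges.items()):
            rows.append(
                {
                    "state": net.state,
                    "feature_a": a,
                    "feature_b": b,
                    "correlation": r,
                    "sign": 1 if r >= 0 else -1,
                }
            )
    return pd.DataFrame(rows, columns=["state", "feature_a", "feature_b", "correlation", "sign"])


def write_edges(networks: Sequence[CooccurrenceNetwork], path, comment: str | None = None) -> None:
    write_commented_tsv(edges_frame(networks), path, comment)


def write_graphml(networks: Sequence[CooccurrenceNetwork], path) -> None:
    """All per-state networks in one GraphML file, as a disjoint union.

    Nodes are namespaced ``state::feature`` so the same feature can carry a
    different mean abundance in each state.
    """
    g = nx.Graph()
    for net in networks:
        for fid, w in sorted(net.nodes.items()):
            g.add_node(
                f"{net.state}::{fid}",
                state=net.state,
                feature_id=fid,
                mean_rel_abundance=float(w),
            )
        for (a, b), r in sorted(net.edges.items()):
            g.add_edge(
                f"{net.state}::{a}",
                f"{net.state}::{b}",
                state=net.state,
                correlation=float(r),
                sign=1 if r >= 0 else -1,
            )
    nx.write_graphml(g, path)
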