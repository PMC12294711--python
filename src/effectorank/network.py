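"""Seeded network scoring of candidates on a protein-interaction graph.

Candidates are scored by proximity to the training (seed) genes on an
undirected, optionally confidence-weighted PPI network:

* PageRank with priors — the stationary distribution of a damped
  random walk whose teleport distribution is concentrated on the seed
  genes.  With a uniform prior this reduces to the classical
  ``PR(u) = (1 - d)/N + d * sum_v PR(v)/L(v)``; with a seed prior the
  uniform teleport is replaced by ``(1 - d) * prior(u)``.
* K-step Markov — finite-horizon diffusion: start uniform over seeds,
  apply the walk matrix k times, and report the per-node visit mass
  averaged over steps 1..k.
* degree and betweenness centrality as structural diagnostics.

Both walk variants use the same column-stochastic transition matrix in
which an edge is traversed in both directions with probability
proportional to its confidence weight; dangling (isolated) nodes
teleport back to the prior with probability 1, so scores always sum
to 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

from effectorank.geneset_io import GeneSet, ValidationError, normalize_symbol

NetStatistic = Literal["pagerank", "kstep", "rank_average"]


@dataclass
class NetworkParams:
    """Random-walk parameters.

    ``damping`` is the probability of following an edge rather than
    teleporting to the prior (0.85 is the conventional choice);
    ``tol`` is the L1 convergence threshold of the power iteration;
    ``k_steps`` is the horizon of the K-step Markov model.
    """

    damping: float = 0.85
    tol: float = 1e-10
    max_iter: int = 1000
    k_steps: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.damping < 1.0:
            raise ValidationError(f"damping must be in [0, 1), got {self.damping}")
        if self.tol <= 0:
            raise ValidationError(f"tol must be positive, got {self.tol}")
        if self.max_iter < 1 or self.k_steps < 1:
            raise ValidationError("max_iter and k_steps must be positive integers")


@dataclass
class PPINetwork:
    """Undirected PPI graph with optional edge confidence weights in (0, 1]."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            raise ValidationError(f"self-loops are not allowed: {loops[:5]}")
        for u, v, data in self.graph.edges(data=True):
            w = data.get("weight", 1.0)
            if not 0.0 < w <= 1.0:
                raise ValidationError(
                    f"edge ({u}, {v}) has confidence weight {w} outside (0, 1]"
                )

    @classmethod
    def from_edges(
        cls, edges: Iterable[tuple[str, str] | tuple[str, str, float]]
    ) -> "PPINetwork":
        graph = nx.Graph()
        for edge in edges:
            u, v = normalize_symbol(edge[0]), normalize_symbol(edge[1])
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            weight = float(edge[2]) if len(edge) > 2 else 1.0
            graph.add_edge(u, v, weight=weight)
        return cls(graph)

    @classmethod
    def from_edgelist_file(cls, path: str | Path) -> "PPINetwork":
        """Read a tab-separated edge list ``gene_a<TAB>gene_b[<TAB>weight]``."""
        path = Path(path)
        edges: list[tuple[str, str, float]] = []
        with path.open("r", encoding="utf-8") as handle:
            for lineno, line in enumerate(handle, start=1):
                stripped = line.strip()
                if not stripped or stripped.startswith("#"):
                    continue
                fields = stripped.split("\t")
                if len(fields) < 2:
                    raise ValidationError(
                        f"{path}:{lineno}: expected >= 2 tab-separated fields"
                    )
                weight = float(fields[2]) if len(fields) > 2 else 1.0
                edges.append((fields[0], fields[1], weight))
        return cls.from_edges(edges)

    def write_edgelist(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w", encoding="utf-8", newline="\n") as handle:
            for u, v, data in sorted(
                (tuple(sorted((a, b))) + (d,) for a, b, d in self.graph.edges(data=True)),
                key=lambda e: (e[0], e[1]),
            ):
                handle.write(f"{u}\t{v}\t{data.get('weight', 1.0):.6g}\n")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class NetworkScore:
    """Per-candidate network statistics; ``net_score`` feeds integration."""

    gene: str
    pagerank_prior: float
    kstep_mass: float
    degree: int
    betweenness: float
    net_score: float
    in_network: bool = True


def _walk_matrix(net: PPINetwork) -> tuple[list[str], sp.csr_matrix, np.ndarray]:
    """Column-stochastic transition matrix and dangling-node indicator."""
    nodes = net.nodes
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    rows, cols, vals = [], [], []
    strength = np.zeros(n)
    for u, v, data in net.graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        iu, iv = index[u], index[v]
        strength[iu] += w
        strength[iv] += w
        rows.extend([iv, iu])
        cols.extend([iu, iv])
        vals.extend([w, w])
    dangling = strength == 0.0
    safe = np.where(dangling, 1.0, strength)
    vals = [w / safe[c] for w, c in zip(vals, cols)]
    matrix = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return nodes, matrix, dangling


def _prior_vector(
    nodes: Sequence[str],
    seeds: GeneSet,
    prior: Mapping[str, float] | None,
) -> np.ndarray:
    index = {node: i for i, node in enumerate(nodes)}
    vec = np.zeros(len(nodes))
    if prior is not None:
        for node, mass in prior.items():
            if node in index:
                vec[index[node]] = mass
        if vec.sum() <= 0:
            raise ValidationError("prior has no mass on network nodes")
        return vec / vec.sum()
    present = [s for s in seeds if s in index]
    missing = sorted(seeds.genes - set(present))
    if not present:
        raise ValidationError(
            f"no seed gene is present in the network; missing: {missing[:10]}"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} seed genes absent from the network "
            f"(e.g. {missing[:5]}); prior spread over the remaining {len(present)}"
        )
    vec[[index[s] for s in present]] = 1.0 / len(present)
    return vec


def pagerank_with_priors(
    net: PPINetwork,
    seeds: GeneSet,
    params: NetworkParams | None = None,
    prior: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Stationary distribution of the seed-teleporting damped random walk.

    Power iteration of ``x <- (1 - d) * prior + d * (W x + m_dangling * prior)``
    where W is the column-stochastic walk matrix and ``m_dangling`` the
    probability mass sitting on degree-zero nodes.  The prior defaults
    to uniform over the seeds present in the network.  Converges when
    the L1 change drops below ``params.tol``; non-convergence returns
    the last iterate with a warning.  Scores sum to 1.
    """
    params = params or NetworkParams()
    nodes, matrix, dangling = _walk_matrix(net)
    if not nodes:
        raise ValidationError("network is empty")
    p = _prior_vector(nodes, seeds, prior)
    d = params.damping
    x = p.copy()
    for _ in range(params.max_iter):
        x_next = (1.0 - d) * p + d * (matrix @ x + x[dangling].sum() * p)
        if np.abs(x_next - x).sum() < params.tol:
            x = x_next
            break
        x = x_next
    else:
        warnings.warn(
            f"PageRank power iteration did not converge in {params.max_iter} "
            "iterations; returning the last iterate"
        )
    return dict(zip(nodes, x))


def k_step_markov(
    net: PPINetwork,
    seeds: GeneSet,
    k_steps: int = 3,
    prior: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Finite-horizon diffusion mass from the seeds.

    Starting uniform over seeds, the undamped walk matrix is applied
    ``k_steps`` times; the returned value per node is its visit mass
    averaged over steps 1..k (dangling mass is returned to the prior,
    so each step's masses sum to 1).
    """
    if k_steps < 1:
        raise ValidationError(f"k_steps must be >= 1, got {k_steps}")
    nodes, matrix, dangling = _walk_matrix(net)
    if not nodes:
        raise ValidationError("network is empty")
    p = _prior_vector(nodes, seeds, prior)
    x = p.copy()
    acc = np.zeros_like(x)
    for _ in range(k_steps):
        x = matrix @ x + x[dangling].sum() * p
        acc += x
    return dict(zip(nodes, acc / k_steps))


def centralities(net: PPINetwork) -> dict[str, tuple[int, float]]:
    """Unweighted degree and unnormalized betweenness per node.

    Betweenness counts shortest paths between node pairs passing
    through the node, split fractionally over tied shortest paths.
    """
    if len(net) == 0:
        raise ValidationError("network is empty")
    betweenness = nx.betweenness_centrality(net.graph, normalized=False)
    return {
        node: (int(net.graph.degree(node)), float(betweenness[node]))
        for node in net.nodes
    }


def score_candidates_network(
    net: PPINetwork,
    seeds: GeneSet,
    candidates: Iterable[str],
    params: NetworkParams | None = None,
    net_statistic: NetStatistic = "pagerank",
    include_centralities: bool = True,
) -> list[NetworkScore]:
    """Score candidate genes by seeded network proximity.

    ``net_statistic`` selects the value fed to integration: the
    PageRank-with-priors score (default), the K-step Markov mass, or
    the average of the (descending) ranks of all four statistics
    converted back to a score.  Candidates absent from the network get
    all-zero scores with a warning.
    """
    params = params or NetworkParams()
    candidate_list = sorted(set(normalize_symbol(c) for c in candidates))
    pagerank = pagerank_with_priors(net, seeds, params)
    kstep = k_step_markov(net, seeds, params.k_steps)
    if include_centralities:
        central = centralities(net)
    else:
        central = {node: (int(net.graph.degree(node)), 0.0) for node in net.nodes}
    missing = [c for c in candidate_list if c not in pagerank]
    if missing:
        warnings.warn(
            f"{len(missing)} candidates absent from the network "
            f"(e.g. {missing[:5]}); they score 0"
        )
    raw: dict[str, dict[str, float]] = {}
    for gene in candidate_list:
        if gene in pagerank:
            deg, btw = central[gene]
            raw[gene] = {
                "pagerank": pagerank[gene],
                "kstep": kstep[gene],
                "degree": float(deg),
                "betweenness": btw,
            }
        else:
            raw[gene] = {"pagerank": 0.0, "kstep": 0.0, "degree": 0.0, "betweenness": 0.0}
    if net_statistic == "rank_average":
        net_values = _rank_average(raw, candidate_list)
    elif net_statistic in ("pagerank", "kstep"):
        net_values = {g: raw[g][net_statistic] for g in candidate_list}
    else:
        raise ValidationError(f"unknown net_statistic {net_statistic!r}")
    return [
        NetworkScore(
            gene=gene,
            pagerank_prior=raw[gene]["pagerank"],
            kstep_mass=raw[gene]["kstep"],
            degree=int(raw[gene]["degree"]),
            betweenness=raw[gene]["betweenness"],
            net_score=net_values[gene],
            in_network=gene not in missing,
        )
        for gene in candidate_list
    ]


def _rank_average(
    raw: Mapping[str, Mapping[str, float]], genes: Sequence[str]
) -> dict[str, float]:
    """Average descending rank over the four statistics, mapped to a score.

    The returned value is ``m - mean_rank`` so that higher still means
    better, keeping the integration stage's orientation uniform.
    """
    m = len(genes)
    totals = {g: 0.0 for g in genes}
    for stat in ("pagerank", "kstep", "degree", "betweenness"):
        ordered = sorted(genes, key=lambda g: (-raw[g][stat], g))
        for rank, gene in enumerate(ordered, start=1):
            totals[gene] += rank
    return {g: m - totals[g] / 4.0 for g in genes}
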