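"""Linear integration of functional and network evidence into a FinalScore.

Both evidence channels are min-max scaled over the candidate set and
combined as

    FinalScore = alpha * Gene_scaled + (1 - alpha) * Net_scaled
                 + beta * IsTopNet

with alpha = beta = 0.5 by default.  IsTopNet flags the candidates in
the top 5% of network scores (ceiling, so the set is non-empty for
small panels).  The formula adds the beta term for top-network genes;
a ``beta_sign="penalty"`` switch subtracts it instead, for the reading
in which highly connected hub genes are down-weighted rather than
boosted.  Candidates are ranked in descending FinalScore.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from effectorank.functional import FunctionalScore
from effectorank.geneset_io import ValidationError
from effectorank.network import NetworkScore


@dataclass
class IntegrationParams:
    """Weights of the linear combination.

    ``alpha`` balances functional vs network evidence, ``beta`` is the
    magnitude of the top-network indicator term, ``top_fraction`` the
    fraction of candidates flagged as top-network.
    """

    alpha: float = 0.5
    beta: float = 0.5
    top_fraction: float = 0.05
    beta_sign: Literal["bonus", "penalty"] = "bonus"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.beta < 0:
            raise ValidationError(f"beta must be >= 0, got {self.beta}")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValidationError(
                f"top_fraction must be in (0, 1], got {self.top_fraction}"
            )
        if self.beta_sign not in ("bonus", "penalty"):
            raise ValidationError(f"unknown beta_sign {self.beta_sign!r}")


@dataclass
class IntegratedRanking:
    """One candidate's scaled scores, indicator, FinalScore, and rank."""

    gene: str
    gene_scaled: float
    net_scaled: float
    is_top_net: int
    final_score: float
    rank: int


def minmax_scale(values: Sequence[float]) -> np.ndarray:
    """Scale values to [0, 1] as ``(x - min) / (max - min)``.

    Constant input (including a single value) maps to all zeros with a
    warning; empty input is an error.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("minmax_scale requires at least one value")
    span = arr.max() - arr.min()
    if span == 0.0:
        if arr.size > 1:
            warnings.warn("constant score vector; all scaled values set to 0")
        return np.zeros_like(arr)
    return (arr - arr.min()) / span


def final_score(
    gene_scaled: float,
    net_scaled: float,
    is_top_net: int,
    params: IntegrationParams | None = None,
) -> float:
    """The linear FinalScore for one candidate."""
    params = params or IntegrationParams()
    if is_top_net not in (0, 1):
        raise ValidationError(f"is_top_net must be 0 or 1, got {is_top_net}")
    sign = 1.0 if params.beta_sign == "bonus" else -1.0
    return (
        params.alpha * gene_scaled
        + (1.0 - params.alpha) * net_scaled
        + sign * params.beta * is_top_net
    )


def rank_candidates(
    functional: Sequence[FunctionalScore],
    network: Sequence[NetworkScore],
    params: IntegrationParams | None = None,
) -> list[IntegratedRanking]:
    """Integrate the two evidence channels and rank all candidates.

    The two inputs must cover exactly the same candidate set.  The
    top-network indicator goes to the ``ceil(top_fraction * m)``
    candidates with the highest raw network scores (ties broken by
    descending score then symbol).  Output is sorted by descending
    FinalScore, ties by descending Gene_scaled then symbol, with dense
    ranks 1..m.
    """
    params = params or IntegrationParams()
    functional_by_gene = {s.gene: s for s in functional}
    network_by_gene = {s.gene: s for s in network}
    only_functional = sorted(set(functional_by_gene) - set(network_by_gene))
    only_network = sorted(set(network_by_gene) - set(functional_by_gene))
    if only_functional or only_network:
        raise ValidationError(
            "candidate mismatch between evidence channels; "
            f"functional-only: {only_functional[:10]}, "
            f"network-only: {only_network[:10]}"
        )
    genes = sorted(functional_by_gene)
    if not genes:
        raise ValidationError("no candidates to rank")
    gene_scaled = dict(
        zip(genes, minmax_scale([functional_by_gene[g].s_combined for g in genes]))
    )
    net_raw = {g: network_by_gene[g].net_score for g in genes}
    net_scaled = dict(zip(genes, minmax_scale([net_raw[g] for g in genes])))
    n_top = math.ceil(params.top_fraction * len(genes))
    top_net = set(sorted(genes, key=lambda g: (-net_raw[g], g))[:n_top])
    rows = [
        IntegratedRanking(
            gene=g,
            gene_scaled=float(gene_scaled[g]),
            net_scaled=float(net_scaled[g]),
            is_top_net=int(g in top_net),
            final_score=final_score(
                float(gene_scaled[g]), float(net_scaled[g]), int(g in top_net), params
            ),
            rank=0,
        )
        for g in genes
    ]
    rows.sort(key=lambda r: (-r.final_score, -r.gene_scaled, r.gene))
    for rank, row in enumerate(rows, start=1):
        row.rank = rank
    return rows
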