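"""Regulator (kinase / transcription-factor) enrichment with rank aggregation.

Each evidence source is a regulator -> target-set library.  Within a
source, every regulator's target set is tested against the query with a
one-sided Fisher exact test and BH-corrected; regulators are then
ranked 1..m by ascending p.  Across sources, a regulator's MeanRank is
the average of its integer ranks over the sources that contain it, and
its best scaled rank is the minimum of rank / (regulators tested in
that source).  Lower MeanRank means stronger evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

from scipy.stats import fisher_exact

from effectorank.enrichment import adjust_pvalues
from effectorank.geneset_io import GeneSet, ValidationError


@dataclass
class RegulatorLibrary:
    """One evidence source: a mapping regulator symbol -> target gene set."""

    source_name: str
    regulators: dict[str, GeneSet]

    def __post_init__(self) -> None:
        empties = [r for r, t in self.regulators.items() if len(t) == 0]
        if empties:
            warnings.warn(
                f"source {self.source_name!r}: skipping regulators with empty "
                f"target sets: {sorted(empties)}"
            )
            for r in empties:
                del self.regulators[r]

    def all_targets(self) -> frozenset[str]:
        out: set[str] = set()
        for targets in self.regulators.values():
            out |= targets.genes
        return frozenset(out)


@dataclass
class AggregateRanking:
    """A regulator's per-source ranks/p-values and their aggregation."""

    regulator: str
    per_source_rank: dict[str, int]
    mean_rank: float
    best_scaled_rank: float
    per_source_p: dict[str, float] = field(default_factory=dict)


def per_library_pvalues(
    query: GeneSet,
    library: RegulatorLibrary,
    universe_size: int | None = None,
) -> dict[str, float]:
    """One-sided Fisher exact enrichment p per regulator in one source.

    The 2x2 table crosses query membership with target membership over a
    universe that defaults to the union of all the source's targets plus
    the query.  The one-sided (greater) Fisher p equals the
    hypergeometric upper tail at the observed overlap.
    """
    if len(query) == 0:
        raise ValidationError("query gene set is empty")
    if not library.regulators:
        raise ValidationError(f"source {library.source_name!r} has no regulators")
    universe = library.all_targets() | query.genes
    N = universe_size if universe_size is not None else len(universe)
    n = len(query)
    if N < n:
        raise ValidationError(f"universe size {N} smaller than query size {n}")
    pvalues: dict[str, float] = {}
    for regulator, targets in library.regulators.items():
        K = len(targets)
        k = len(targets.genes & query.genes)
        table = [[k, K - k], [n - k, N - K - n + k]]
        if table[1][1] < 0:
            raise ValidationError(
                f"source {library.source_name!r}, regulator {regulator!r}: "
                f"universe size {N} too small for the 2x2 table"
            )
        _, p = fisher_exact(table, alternative="greater")
        pvalues[regulator] = float(p)
    return pvalues


def rank_regulators(pvalues: Mapping[str, float]) -> dict[str, int]:
    """Integer ranks 1..m by ascending p, ties broken by regulator symbol."""
    ordered = sorted(pvalues, key=lambda r: (pvalues[r], r))
    return {regulator: rank for rank, regulator in enumerate(ordered, start=1)}


def aggregate_mean_rank(
    per_source_ranks: Mapping[str, Mapping[str, int]],
    missing_policy: Literal["observed", "penalty"] = "observed",
) -> list[AggregateRanking]:
    """Aggregate per-source integer ranks into MeanRank / best scaled rank.

    Under the default ``observed`` policy a regulator absent from a
    source contributes nothing to its mean; under ``penalty`` it is
    charged rank ``m + 1`` in that source (m = regulators tested there).
    Output is sorted ascending by mean rank, ties by best scaled rank
    then symbol.
    """
    if not per_source_ranks or all(not r for r in per_source_ranks.values()):
        raise ValidationError("need at least one source with one ranked regulator")
    sizes = {src: len(ranks) for src, ranks in per_source_ranks.items()}
    regulators: set[str] = set()
    for ranks in per_source_ranks.values():
        regulators |= set(ranks)
    out: list[AggregateRanking] = []
    for regulator in sorted(regulators):
        observed = {
            src: ranks[regulator]
            for src, ranks in per_source_ranks.items()
            if regulator in ranks
        }
        if missing_policy == "penalty":
            effective = {
                src: per_source_ranks[src].get(regulator, sizes[src] + 1)
                for src in per_source_ranks
            }
        elif missing_policy == "observed":
            effective = observed
        else:
            raise ValidationError(f"unknown missing_policy {missing_policy!r}")
        mean_rank = sum(effective.values()) / len(effective)
        best_scaled = min(rank / sizes[src] for src, rank in observed.items())
        out.append(
            AggregateRanking(
                regulator=regulator,
                per_source_rank=dict(observed),
                mean_rank=mean_rank,
                best_scaled_rank=best_scaled,
            )
        )
    out.sort(key=lambda a: (a.mean_rank, a.best_scaled_rank, a.regulator))
    return out


def aggregate_regulators(
    query: GeneSet,
    libraries: Sequence[RegulatorLibrary],
    universe_size: int | None = None,
    missing_policy: Literal["observed", "penalty"] = "observed",
) -> list[AggregateRanking]:
    """Full regulator-enrichment flow over several sources.

    Runs the per-source Fisher tests, BH-corrects within each source,
    ranks by raw p, and aggregates across sources.  The returned
    ``per_source_p`` values are the BH-corrected ones.
    """
    per_source_ranks: dict[str, dict[str, int]] = {}
    per_source_bh: dict[str, dict[str, float]] = {}
    for library in libraries:
        pvalues = per_library_pvalues(query, library, universe_size=universe_size)
        regulators = sorted(pvalues)
        bh = adjust_pvalues([pvalues[r] for r in regulators], "bh")
        per_source_bh[library.source_name] = dict(zip(regulators, bh))
        per_source_ranks[library.source_name] = rank_regulators(pvalues)
    aggregated = aggregate_mean_rank(per_source_ranks, missing_policy=missing_policy)
    for entry in aggregated:
        entry.per_source_p = {
            src: per_source_bh[src][entry.regulator]
            for src in per_source_bh
            if entry.regulator in per_source_bh[src]
        }
    return aggregated
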