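"""Set-overlap analysis and the training/test partition that seeds scoring.

The prioritization pipeline compares an "aging" gene set against an
"exercise" gene set.  Candidates (the test set) are the genes in the
intersection; the training (seed) genes default to the aging-unique
genes, matching the arithmetic training = |aging| - |overlap|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from effectorank.geneset_io import GeneSet, ValidationError

TrainingRule = Literal["aging_unique", "symmetric_difference"]


@dataclass
class OverlapResult:
    """Intersections, uniques, exclusive-region counts, and Jaccard matrix."""

    set_names: list[str]
    intersection: GeneSet
    unique_to_each: dict[str, GeneSet]
    upset_counts: dict[str, int]
    jaccard: pd.DataFrame
    clustering_order: list[str]


@dataclass
class TrainTestPartition:
    """Seed (training) genes and candidate (test) genes for prioritization."""

    training: GeneSet
    test: GeneSet


def jaccard_matrix(sets: Sequence[GeneSet]) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Jaccard similarity matrix plus a hierarchical-clustering order.

    ``J(i, j) = |Si & Sj| / |Si | Sj|``; the diagonal is 1 and an empty
    set scores 0 against every other set (with a warning).  The order is
    the leaf order of an average-linkage clustering of ``1 - J``; ties
    fall back to input order.
    """
    if len(sets) < 2:
        raise ValidationError("jaccard_matrix requires at least 2 gene sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValidationError(f"gene-set names must be unique, got {names}")
    if any(len(s) == 0 for s in sets):
        warnings.warn("empty gene set in Jaccard computation; entries set to 0")
    n = len(sets)
    mat = np.eye(n)
    for i, j in combinations(range(n), 2):
        union = len(sets[i].genes | sets[j].genes)
        mat[i, j] = mat[j, i] = (
            len(sets[i].genes & sets[j].genes) / union if union else 0.0
        )
    frame = pd.DataFrame(mat, index=names, columns=names)
    dist = squareform(1.0 - mat, checks=False)
    order = [names[i] for i in leaves_list(linkage(dist, method="average"))]
    return frame, order


def upset_counts(sets: Sequence[GeneSet]) -> dict[str, int]:
    """Exclusive-region counts over every non-empty membership pattern.

    Region labels join the member set names with ``&``; counts sum to
    the cardinality of the union.
    """
    if len(sets) < 2:
        raise ValidationError("upset_counts requires at least 2 gene sets")
    names = [s.name for s in sets]
    counts: dict[str, int] = {}
    n = len(sets)
    for r in range(1, n + 1):
        for idx in combinations(range(n), r):
            inside = frozenset.intersection(*(sets[i].genes for i in idx))
            outside: set[str] = set()
            for i in range(n):
                if i not in idx:
                    outside |= sets[i].genes
            counts["&".join(names[i] for i in idx)] = len(inside - outside)
    return counts


def intersect_and_partition(
    aging: GeneSet,
    exercise: GeneSet,
    training_rule: TrainingRule = "aging_unique",
) -> tuple[OverlapResult, TrainTestPartition]:
    """Intersect the two input sets and derive the training/test partition.

    The test set is always ``aging & exercise``.  Training genes are the
    aging-unique genes under the default rule, or the full symmetric
    difference under ``training_rule="symmetric_difference"``.  Empty
    intersections and identical inputs raise warnings but still return.
    """
    if len(aging) == 0 or len(exercise) == 0:
        raise ValidationError("both input gene sets must be non-empty")
    test = aging.intersection(exercise, name="test")
    if len(test) == 0:
        warnings.warn(
            "the two gene sets are disjoint; prioritization has no candidates"
        )
    if aging.genes == exercise.genes:
        warnings.warn("the two gene sets are identical; training set is empty")
    if training_rule == "aging_unique":
        training_genes = aging.genes - test.genes
    elif training_rule == "symmetric_difference":
        training_genes = (aging.genes | exercise.genes) - test.genes
    else:
        raise ValidationError(f"unknown training_rule {training_rule!r}")
    partition = TrainTestPartition(
        training=GeneSet("training", frozenset(training_genes)), test=test
    )
    jac, order = jaccard_matrix([aging, exercise])
    result = OverlapResult(
        set_names=[aging.name, exercise.name],
        intersection=test,
        unique_to_each={
            aging.name: aging.difference(exercise, name=f"{aging.name}_only"),
            exercise.name: exercise.difference(aging, name=f"{exercise.name}_only"),
        },
        upset_counts=upset_counts([aging, exercise]),
        jaccard=jac,
        clustering_order=order,
    )
    return result, partition
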