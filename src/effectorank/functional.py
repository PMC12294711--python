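"""Annotation-based candidate scoring against a training-gene profile.

The training (seed) genes define, per annotation category, a
representative profile: for categorical annotations (e.g. GO terms) the
fraction of training genes carrying each term; for quantitative
annotations (e.g. expression vectors) the coordinate-wise mean.  Each
candidate is scored by its similarity to that profile — cosine
similarity of its binary term vector against the term-frequency profile
(a parameter-free fuzzy reading; a best-match Jaccard alternative is
selectable), or Pearson correlation for quantitative vectors.

Similarities are converted to empirical p-values by comparing against
the similarities of genes sampled at random from the annotation
universe (training genes excluded), with the add-one estimator
``p = (1 + #{null >= observed}) / (M + 1)`` so p is never zero.  The
per-category p-values are merged with Fisher's inverse chi-square
method: ``X = -2 * sum(ln p_i)`` referred to a chi-square distribution
with 2n degrees of freedom, and the combined score is
``S_combined = 1 - P_fisher`` (higher = more training-like).

Genes missing from a category receive similarity 0 and p = 1 rather
than being dropped, so the number of combined categories — and hence
the scale of S_combined — is identical for every candidate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from effectorank.geneset_io import GeneSet, GeneSetLibrary, ValidationError, normalize_symbol

_TINY = np.finfo(float).tiny

SimilarityMethod = Literal["cosine", "best_jaccard"]


@dataclass
class AnnotationCategory:
    """One annotation source, either categorical or quantitative.

    Exactly one payload is populated: ``terms_by_gene`` maps a gene to
    its set of term identifiers; ``vectors`` maps a gene to a real
    vector of fixed dimension.
    """

    name: str
    kind: Literal["categorical", "quantitative"]
    terms_by_gene: dict[str, frozenset[str]] | None = None
    vectors: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if self.terms_by_gene is None or self.vectors is not None:
                raise ValidationError(
                    f"category {self.name!r}: categorical kind requires exactly "
                    "the terms_by_gene payload"
                )
        elif self.kind == "quantitative":
            if self.vectors is None or self.terms_by_gene is not None:
                raise ValidationError(
                    f"category {self.name!r}: quantitative kind requires exactly "
                    "the vectors payload"
                )
            dims = {np.asarray(v).shape for v in self.vectors.values()}
            if len(dims) > 1:
                raise ValidationError(
                    f"category {self.name!r}: vectors have mixed dimensions {dims}"
                )
        else:
            raise ValidationError(f"category {self.name!r}: unknown kind {self.kind!r}")

    def annotated_genes(self) -> frozenset[str]:
        payload = self.terms_by_gene if self.kind == "categorical" else self.vectors
        assert payload is not None
        return frozenset(payload)

    @classmethod
    def from_library(cls, library: GeneSetLibrary) -> "AnnotationCategory":
        """Invert a term -> members library into a categorical category."""
        terms_by_gene: dict[str, set[str]] = {}
        for term, members in library.terms.items():
            for gene in members.genes:
                terms_by_gene.setdefault(gene, set()).add(term)
        return cls(
            name=library.name,
            kind="categorical",
            terms_by_gene={g: frozenset(t) for g, t in terms_by_gene.items()},
        )


@dataclass
class CategoricalProfile:
    """Term-frequency weights among training genes (plus their term sets)."""

    term_weights: dict[str, float]
    training_term_sets: tuple[frozenset[str], ...]


@dataclass
class QuantitativeProfile:
    """Coordinate-wise mean vector over annotated training genes."""

    mean_vector: np.ndarray


@dataclass
class TrainingProfile:
    """Per-category representative profile built from the training genes."""

    training_genes: frozenset[str]
    categorical: dict[str, CategoricalProfile] = field(default_factory=dict)
    quantitative: dict[str, QuantitativeProfile] = field(default_factory=dict)


@dataclass
class FunctionalScore:
    """Per-candidate similarities, empirical p-values, and combined score."""

    gene: str
    per_category_similarity: dict[str, float]
    per_category_p: dict[str, float]
    fisher_statistic: float
    p_fisher: float
    s_combined: float
    n_categories: int


def build_training_profile(
    training: GeneSet, categories: Sequence[AnnotationCategory]
) -> TrainingProfile:
    """Summarize the training genes in every annotation category.

    Categorical: weight(term) = fraction of training genes annotated
    with the term.  Quantitative: mean vector over annotated training
    genes.  A category annotating zero training genes is dropped with a
    warning.
    """
    if len(training) == 0:
        raise ValidationError("training gene set is empty")
    profile = TrainingProfile(training_genes=training.genes)
    for category in categories:
        annotated = [g for g in training if g in category.annotated_genes()]
        if not annotated:
            warnings.warn(
                f"category {category.name!r} annotates no training gene; dropped"
            )
            continue
        if category.kind == "categorical":
            assert category.terms_by_gene is not None
            counts: dict[str, int] = {}
            term_sets = []
            for gene in annotated:
                terms = category.terms_by_gene[gene]
                term_sets.append(terms)
                for term in terms:
                    counts[term] = counts.get(term, 0) + 1
            weights = {t: c / len(training) for t, c in counts.items()}
            profile.categorical[category.name] = CategoricalProfile(
                term_weights=weights, training_term_sets=tuple(term_sets)
            )
        else:
            assert category.vectors is not None
            stacked = np.vstack([np.asarray(category.vectors[g], float) for g in annotated])
            profile.quantitative[category.name] = QuantitativeProfile(
                mean_vector=stacked.mean(axis=0)
            )
    return profile


def category_similarity(
    gene: str,
    profile: TrainingProfile,
    category: AnnotationCategory,
    method: SimilarityMethod = "cosine",
) -> float:
    """Similarity of one gene to the training profile in one category.

    Returns 0 for genes unannotated in the category, for zero-variance
    quantitative vectors (with a warning), and for genes whose terms are
    all absent from the profile.
    """
    if category.kind == "categorical":
        cat_profile = profile.categorical.get(category.name)
        if cat_profile is None:
            return 0.0
        assert category.terms_by_gene is not None
        terms = category.terms_by_gene.get(gene)
        if not terms:
            return 0.0
        return _categorical_similarity(terms, cat_profile, method)
    quant_profile = profile.quantitative.get(category.name)
    if quant_profile is None:
        return 0.0
    assert category.vectors is not None
    vector = category.vectors.get(gene)
    if vector is None:
        return 0.0
    return _pearson(np.asarray(vector, float), quant_profile.mean_vector)


def _categorical_similarity(
    terms: frozenset[str], cat_profile: CategoricalProfile, method: SimilarityMethod
) -> float:
    if method == "cosine":
        weights = cat_profile.term_weights
        dot = sum(weights.get(t, 0.0) for t in terms)
        if dot == 0.0:
            return 0.0
        norm_gene = math.sqrt(len(terms))
        norm_profile = math.sqrt(sum(w * w for w in weights.values()))
        return dot / (norm_gene * norm_profile)
    if method == "best_jaccard":
        best = 0.0
        for train_terms in cat_profile.training_term_sets:
            union = len(terms | train_terms)
            if union:
                best = max(best, len(terms & train_terms) / union)
        return best
    raise ValidationError(f"unknown similarity method {method!r}")


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if x.std() == 0.0 or y.std() == 0.0:
        warnings.warn("zero-variance vector in Pearson similarity; returning 0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def empirical_pvalue(observed: float, null_similarities: np.ndarray) -> float:
    """Add-one empirical p: ``(1 + #{null >= observed}) / (M + 1)``."""
    null_similarities = np.asarray(null_similarities, float)
    m = null_similarities.size
    if m == 0:
        raise ValidationError("empty null similarity sample")
    return float((1 + int(np.sum(null_similarities >= observed))) / (m + 1))


def sample_null_genes(
    universe: Iterable[str],
    training: frozenset[str],
    n_samples: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw genes for the null similarity distribution.

    Sampling is without replacement from the universe minus the
    training genes; if the pool is smaller than ``n_samples`` sampling
    falls back to with-replacement with a warning.
    """
    pool = sorted(set(universe) - training)
    if not pool:
        raise ValidationError("null-sampling universe is empty after removing training genes")
    if len(pool) < n_samples:
        warnings.warn(
            f"universe ({len(pool)}) smaller than requested null sample "
            f"({n_samples}); sampling with replacement"
        )
        idx = rng.integers(0, len(pool), size=n_samples)
    else:
        idx = rng.choice(len(pool), size=n_samples, replace=False)
    return [pool[i] for i in idx]


def fisher_combine(p_values: Sequence[float]) -> tuple[float, float, float]:
    """Fisher's inverse chi-square combination of per-category p-values.

    Returns ``(X, P_fisher, S_combined)`` with ``X = -2 sum(ln p_i)``,
    ``P_fisher`` the chi-square(2n) upper tail at X, and
    ``S_combined = 1 - P_fisher``.  Zero p-values are clamped to the
    smallest positive float with a warning.
    """
    ps = np.asarray(p_values, dtype=float)
    if ps.size == 0:
        raise ValidationError("fisher_combine requires at least one p-value")
    if np.any(ps > 1) or np.any(ps < 0):
        raise ValidationError("p-values must lie in (0, 1]")
    if np.any(ps == 0):
        warnings.warn("p-value of 0 clamped to the smallest positive float")
        ps = np.maximum(ps, _TINY)
    statistic = float(-2.0 * np.sum(np.log(ps)))
    p_fisher = float(chi2.sf(statistic, df=2 * ps.size))
    return statistic, p_fisher, 1.0 - p_fisher


def score_candidates_functional(
    candidates: Iterable[str],
    training: GeneSet,
    categories: Sequence[AnnotationCategory],
    universe: Iterable[str],
    n_null_samples: int = 999,
    rng: np.random.Generator | int | None = None,
    method: SimilarityMethod = "cosine",
) -> list[FunctionalScore]:
    """Score candidate genes against the training profile.

    For each retained category one null sample of ``n_null_samples``
    genes is drawn (shared across candidates, deterministic given the
    RNG state) and every candidate's similarity is converted to an
    empirical p-value against it; the per-category p-values are then
    Fisher-combined.  Output is sorted by descending S_combined, ties
    by gene symbol.
    """
    if n_null_samples < 99:
        raise ValidationError("n_null_samples must be at least 99")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    universe_list = sorted(set(universe))
    profile = build_training_profile(training, categories)
    retained = [
        c
        for c in categories
        if c.name in profile.categorical or c.name in profile.quantitative
    ]
    candidate_list = sorted(set(normalize_symbol(c) for c in candidates))
    null_sims: dict[str, np.ndarray] = {}
    for category in retained:
        null_genes = sample_null_genes(
            universe_list, training.genes, n_null_samples, rng
        )
        null_sims[category.name] = np.array(
            [category_similarity(g, profile, category, method) for g in null_genes]
        )
    scores: list[FunctionalScore] = []
    for gene in candidate_list:
        sims: dict[str, float] = {}
        ps: dict[str, float] = {}
        for category in retained:
            annotated = gene in category.annotated_genes()
            sim = (
                category_similarity(gene, profile, category, method)
                if annotated
                else 0.0
            )
            sims[category.name] = sim
            # Unannotated genes are kept with an uninformative p so the
            # combined score has the same degrees of freedom for everyone.
            ps[category.name] = (
                empirical_pvalue(sim, null_sims[category.name]) if annotated else 1.0
            )
        statistic, p_fisher, s_combined = fisher_combine(list(ps.values()))
        scores.append(
            FunctionalScore(
                gene=gene,
                per_category_similarity=sims,
                per_category_p=ps,
                fisher_statistic=statistic,
                p_fisher=p_fisher,
                s_combined=s_combined,
                n_categories=len(retained),
            )
        )
    scores.sort(key=lambda s: (-s.s_combined, s.gene))
    return scores


def read_quantitative_tsv(path: str | Path, name: str | None = None) -> AnnotationCategory:
    """Read a quantitative category from a TSV matrix with gene rows."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    vectors = {
        normalize_symbol(str(gene)): row.to_numpy(dtype=float)
        for gene, row in frame.iterrows()
    }
    return AnnotationCategory(name=name or path.stem, kind="quantitative", vectors=vectors)


def write_quantitative_tsv(category: AnnotationCategory, path: str | Path) -> None:
    """Write a quantitative category as a TSV matrix with gene rows."""
    if category.kind != "quantitative" or category.vectors is None:
        raise ValidationError("write_quantitative_tsv requires a quantitative category")
    genes = sorted(category.vectors)
    frame = pd.DataFrame(
        [np.asarray(category.vectors[g], float) for g in genes],
        index=pd.Index(genes, name="gene"),
        columns=[f"dim{i}" for i in range(len(next(iter(category.vectors.values()))))],
    )
    frame.to_csv(path, sep="\t", float_format="%.10g")
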