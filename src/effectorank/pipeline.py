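"""End-to-end orchestration: overlap -> enrichment -> regulators ->
functional scoring -> network scoring -> integration.

Each stage writes its TSV artifact before the next stage starts, so a
run can be resumed or inspected stage by stage.  A run manifest records
the configuration echo, per-stage row counts, and captured warnings;
re-running with the same configuration and seed reproduces every output
byte-identically (the manifest carries no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import effectorank
from effectorank.enrichment import enrich_library
from effectorank.functional import (
    AnnotationCategory,
    read_quantitative_tsv,
    score_candidates_functional,
)
from effectorank.geneset_io import (
    GeneSet,
    ValidationError,
    parse_gene_list,
    parse_gmt,
    write_gene_list,
)
from effectorank.integration import IntegrationParams, rank_candidates
from effectorank.network import (
    NetworkParams,
    NetStatistic,
    PPINetwork,
    score_candidates_network,
)
from effectorank.overlap import intersect_and_partition
from effectorank.regulators import RegulatorLibrary, aggregate_regulators
from effectorank.synthetic import SyntheticBundle

logger = logging.getLogger(__name__)

STAGES = (
    "overlap",
    "enrichment",
    "regulators",
    "functional",
    "network",
    "integration",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run; JSON-serializable."""

    aging_path: str
    exercise_path: str
    network_path: str
    out_dir: str
    annotation_gmt_paths: list[str] = field(default_factory=list)
    quantitative_tsv_paths: list[str] = field(default_factory=list)
    regulator_gmt_paths: list[str] = field(default_factory=list)
    universe_path: str | None = None
    universe_size: int | None = None
    training_rule: str = "aging_unique"
    similarity_method: str = "cosine"
    net_statistic: str = "pagerank"
    sampling_m: int = 999
    rng_seed: int = 0
    integration: IntegrationParams = field(default_factory=IntegrationParams)
    network_params: NetworkParams = field(default_factory=NetworkParams)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        integration = IntegrationParams(**data.pop("integration", {}))
        network_params = NetworkParams(**data.pop("network_params", {}))
        return cls(integration=integration, network_params=network_params, **data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )

    def validate_paths(self) -> None:
        missing = [
            p
            for p in [
                self.aging_path,
                self.exercise_path,
                self.network_path,
                self.universe_path,
                *self.annotation_gmt_paths,
                *self.quantitative_tsv_paths,
                *self.regulator_gmt_paths,
            ]
            if p is not None and not Path(p).exists()
        ]
        if missing:
            raise ValidationError(f"configured paths do not exist: {missing}")


@dataclass
class RunManifest:
    """Deterministic record of one completed run."""

    config: dict
    version: str
    stage_order: list[str]
    row_counts: dict[str, int]
    warnings: list[str]

    def write(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n",
            encoding="utf-8",
        )


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_all(config: RunConfig) -> RunManifest:
    """Execute every stage on the configured inputs.

    Raises :class:`PipelineError` naming the failing stage; an empty
    intersection stops the pipeline after the overlap stage.
    """
    config.validate_paths()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    row_counts: dict[str, int] = {}
    captured: list[str] = []

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # --- overlap -------------------------------------------------
        stage = "overlap"
        try:
            aging = parse_gene_list(config.aging_path, name="aging")
            exercise = parse_gene_list(config.exercise_path, name="exercise")
            overlap_result, partition = intersect_and_partition(
                aging, exercise, training_rule=config.training_rule  # type: ignore[arg-type]
            )
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
        regions = pd.DataFrame(
            [
                {
                    "region": region,
                    "count": count,
                    "genes": ",".join(
                        sorted(_region_genes(region, aging, exercise))
                    ),
                }
                for region, count in sorted(overlap_result.upset_counts.items())
            ]
        )
        _write_tsv(regions, out_dir / "overlap_regions.tsv")
        overlap_result.jaccard.to_csv(out_dir / "jaccard.tsv", sep="\t", float_format="%.10g")
        write_gene_list(partition.training, out_dir / "training_genes.txt")
        write_gene_list(partition.test, out_dir / "test_genes.txt")
        row_counts["overlap"] = len(regions)
        logger.info("[overlap] test=%d training=%d", len(partition.test), len(partition.training))
        if len(partition.test) == 0:
            raise PipelineError(
                "stage overlap: the two input sets share no genes; there are no "
                "candidates to prioritize"
            )

        # --- enrichment ----------------------------------------------
        stage = "enrichment"
        try:
            for gmt_path in config.annotation_gmt_paths:
                library = parse_gmt(gmt_path, universe_size=config.universe_size)
                for query in (aging, exercise):
                    records = enrich_library(query, library, universe_size=config.universe_size)
                    frame = pd.DataFrame(
                        [
                            {
                                "term": r.term,
                                "K": r.K,
                                "n": r.n,
                                "k": r.k,
                                "p": r.p,
                                "p_bonferroni": r.p_bonferroni,
                                "p_bh": r.p_bh,
                                "neglog10_p": r.neglog10_p,
                                "member_genes": ",".join(r.overlap_genes),
                            }
                            for r in records
                        ]
                    )
                    out = out_dir / f"enrichment_{query.name}_{library.name}.tsv"
                    _write_tsv(frame, out)
                    row_counts[f"enrichment_{query.name}_{library.name}"] = len(frame)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # --- regulators ----------------------------------------------
        stage = "regulators"
        try:
            if config.regulator_gmt_paths:
                libraries = []
                for gmt_path in config.regulator_gmt_paths:
                    lib = parse_gmt(gmt_path, universe_size=config.universe_size)
                    libraries.append(
                        RegulatorLibrary(
                            source_name=lib.name, regulators=dict(lib.terms)
                        )
                    )
                for query in (aging, exercise):
                    aggregated = aggregate_regulators(
                        query, libraries, universe_size=config.universe_size
                    )
                    sources = [lib.source_name for lib in libraries]
                    frame = pd.DataFrame(
                        [
                            {
                                "regulator": a.regulator,
                                "mean_rank": a.mean_rank,
                                "best_scaled_rank": a.best_scaled_rank,
                                **{
                                    f"rank_{s}": a.per_source_rank.get(s, "")
                                    for s in sources
                                },
                                **{
                                    f"p_bh_{s}": a.per_source_p.get(s, "")
                                    for s in sources
                                },
                            }
                            for a in aggregated
                        ]
                    )
                    _write_tsv(frame, out_dir / f"regulators_{query.name}.tsv")
                    row_counts[f"regulators_{query.name}"] = len(frame)
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

        # --- functional ----------------------------------------------
        stage = "functional"
        try:
            categories: list[AnnotationCategory] = []
            for gmt_path in config.annotation_gmt_paths:
                categories.append(
                    AnnotationCategory.from_library(
                        parse_gmt(gmt_path, universe_size=config.universe_size)
                    )
                )
            for tsv_path in config.quantitative_tsv_paths:
                categories.append(read_quantitative_tsv(tsv_path))
            if config.universe_path is not None:
                universe = set(parse_gene_list(config.universe_path, name="universe").genes)
            else:
                universe = set()
                for category in categories:
                    universe |= category.annotated_genes()
            functional_scores = score_candidates_functional(
                partition.test.genes,
                partition.training,
                categories,
                universe,
                n_null_samples=config.sampling_m,
                rng=np.random.default_rng(config.rng_seed),
                method=config.similarity_method,  # type: ignore[arg-type]
            )
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
        category_names = sorted(functional_scores[0].per_category_p) if functional_scores else []
        frame = pd.DataFrame(
            [
                {
                    "gene": s.gene,
                    **{f"sim_{c}": s.per_category_similarity[c] for c in category_names},
                    **{f"p_{c}": s.per_category_p[c] for c in category_names},
                    "fisher_statistic": s.fisher_statistic,
                    "p_fisher": s.p_fisher,
                    "s_combined": s.s_combined,
                }
                for s in functional_scores
            ]
        )
        _write_tsv(frame, out_dir / "functional_scores.tsv")
        row_counts["functional"] = len(frame)

        # --- network -------------------------------------------------
        stage = "network"
        try:
            network = PPINetwork.from_edgelist_file(config.network_path)
            network_scores = score_candidates_network(
                network,
                partition.training,
                partition.test.genes,
                params=config.network_params,
                net_statistic=config.net_statistic,  # type: ignore[arg-type]
            )
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
        frame = pd.DataFrame(
            [
                {
                    "gene": s.gene,
                    "pagerank_prior": s.pagerank_prior,
                    "kstep_mass": s.kstep_mass,
                    "degree": s.degree,
                    "betweenness": s.betweenness,
                    "net_score": s.net_score,
                }
                for s in network_scores
            ]
        )
        _write_tsv(frame, out_dir / "network_scores.tsv")
        row_counts["network"] = len(frame)

        # --- integration ---------------------------------------------
        stage = "integration"
        try:
            ranking = rank_candidates(functional_scores, network_scores, config.integration)
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc
        frame = pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "gene_scaled": r.gene_scaled,
                    "net_scaled": r.net_scaled,
                    "is_top_net": r.is_top_net,
                    "final_score": r.final_score,
                    "rank": r.rank,
                }
                for r in ranking
            ]
        )
        _write_tsv(frame, out_dir / "ranking.tsv")
        row_counts["integration"] = len(frame)

        captured = sorted({str(w.message) for w in caught})

    manifest = RunManifest(
        config=dataclasses.asdict(config),
        version=effectorank.__version__,
        stage_order=list(STAGES),
        row_counts=row_counts,
        warnings=captured,
    )
    manifest.write(out_dir / "manifest.json")
    return manifest


def _region_genes(region: str, aging: GeneSet, exercise: GeneSet) -> frozenset[str]:
    by_name = {aging.name: aging.genes, exercise.name: exercise.genes}
    inside = frozenset.intersection(
        *(frozenset(by_name[n]) for n in region.split("&"))
    )
    outside: set[str] = set()
    for name, genes in by_name.items():
        if name not in region.split("&"):
            outside |= genes
    return frozenset(inside - outside)


def prioritize_bundle(
    bundle: SyntheticBundle,
    sampling_m: int = 999,
    rng_seed: int = 0,
    integration: IntegrationParams | None = None,
    network_params: NetworkParams | None = None,
    net_statistic: NetStatistic = "pagerank",
):
    """In-memory prioritization of a synthetic bundle (no file I/O).

    Runs overlap -> functional -> network -> integration and returns
    ``(ranking, partition)``.  Used by validation experiments where the
    per-stage TSV artifacts are not needed.
    """
    _, partition = intersect_and_partition(bundle.aging_set, bundle.exercise_set)
    functional_scores = score_candidates_functional(
        partition.test.genes,
        partition.training,
        bundle.categories,
        bundle.universe,
        n_null_samples=sampling_m,
        rng=np.random.default_rng(rng_seed),
    )
    network_scores = score_candidates_network(
        bundle.network,
        partition.training,
        partition.test.genes,
        params=network_params,
        net_statistic=net_statistic,
        include_centralities=False,
    )
    ranking = rank_candidates(functional_scores, network_scores, integration)
    return ranking, partition
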