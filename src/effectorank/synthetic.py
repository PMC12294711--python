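"""Synthetic study-condition generator with planted ground truth.

The generator emulates the statistical shape of the real inputs — two
gene sets of 243 and 634 genes sharing a 37-gene intersection over a
common universe, annotation categories in which the training genes
share high-frequency "profile" terms, regulator libraries with one
strongly supported regulator per source, and a scale-free
protein-interaction network in which a few planted effector genes are
preferentially wired to the training genes.  Planted effectors live in
the intersection, so a correct pipeline should surface them at the top
of the final ranking; a truth manifest records everything planted.

All randomness flows from the single ``rng_seed`` through one
``numpy.random.Generator``, making every bundle bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from effectorank.functional import AnnotationCategory, write_quantitative_tsv
from effectorank.geneset_io import (
    GeneSet,
    GeneSetLibrary,
    ValidationError,
    write_gene_list,
    write_gmt,
)
from effectorank.network import PPINetwork
from effectorank.regulators import RegulatorLibrary

# Generator shape constants: three shared "profile" terms per
# categorical category against ten decoys keeps the training signal
# concentrated; 70% per-term annotation of training genes makes each
# profile term a clear majority feature; the 8-dimensional quantitative
# category with sd-0.5 noise around the profile mean gives planted
# genes a Pearson correlation well separated from the independent
# standard-normal background.
N_PROFILE_TERMS = 3
N_DECOY_TERMS = 10
TRAINING_ANNOTATION_RATE = 0.7
QUANT_DIM = 8
QUANT_NOISE_SD = 0.5
N_REGULATOR_SOURCES = 2
N_DECOY_REGULATORS = 20
PLANTED_TARGET_COVERAGE = 0.6


@dataclass
class SyntheticConfig:
    """Sizes, rates, and seed of one synthetic study bundle.

    Defaults mirror the real study conditions: 243 aging genes, 634
    exercise genes, a forced 37-gene overlap, and a scale-free network;
    the universe is 2,000 genes so the full pipeline runs in seconds.
    """

    universe_size: int = 2_000
    aging_size: int = 243
    exercise_size: int = 634
    overlap_size: int = 37
    n_categories: int = 5
    planted_effectors: int = 3
    enrichment_strength: float = 0.9
    background_annotation_rate: float = 0.1
    network_nodes: int = 1_500
    attachment_edges: int = 3
    seed_wiring: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.overlap_size > min(self.aging_size, self.exercise_size):
            raise ValidationError(
                "violated: overlap_size <= min(aging_size, exercise_size) "
                f"({self.overlap_size} > min({self.aging_size}, {self.exercise_size}))"
            )
        if self.aging_size + self.exercise_size - self.overlap_size > self.universe_size:
            raise ValidationError(
                "violated: aging_size + exercise_size - overlap_size <= universe_size "
                f"({self.aging_size} + {self.exercise_size} - {self.overlap_size} > "
                f"{self.universe_size})"
            )
        if self.planted_effectors > self.overlap_size:
            raise ValidationError(
                "violated: planted_effectors <= overlap_size "
                f"({self.planted_effectors} > {self.overlap_size})"
            )
        if not 0.0 < self.enrichment_strength <= 1.0:
            raise ValidationError("enrichment_strength must be in (0, 1]")
        if not 0.0 <= self.background_annotation_rate < 1.0:
            raise ValidationError("background_annotation_rate must be in [0, 1)")
        training_size = self.aging_size - self.overlap_size
        if self.seed_wiring > training_size:
            raise ValidationError(
                f"violated: seed_wiring <= training size ({self.seed_wiring} > "
                f"{training_size})"
            )
        if self.network_nodes < self.aging_size + self.exercise_size - self.overlap_size:
            raise ValidationError(
                "violated: network_nodes >= |aging union exercise| "
                f"({self.network_nodes} < "
                f"{self.aging_size + self.exercise_size - self.overlap_size})"
            )
        if self.n_categories < 1 or self.attachment_edges < 1:
            raise ValidationError("n_categories and attachment_edges must be >= 1")


@dataclass
class SyntheticBundle:
    """All inputs of one pipeline run plus the planted-truth manifest."""

    config: SyntheticConfig
    universe: list[str]
    aging_set: GeneSet
    exercise_set: GeneSet
    categories: list[AnnotationCategory]
    regulator_libraries: list[RegulatorLibrary]
    network: PPINetwork
    truth: dict = field(default_factory=dict)


def _universe_symbols(size: int) -> list[str]:
    return [f"G{i:06d}" for i in range(1, size + 1)]


def generate_overlapping_sets(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[GeneSet, GeneSet]:
    """Two gene sets of the configured sizes with an exact forced overlap."""
    universe = _universe_symbols(config.universe_size)
    total = config.aging_size + config.exercise_size - config.overlap_size
    picked = rng.choice(config.universe_size, size=total, replace=False)
    symbols = [universe[i] for i in picked]
    shared = symbols[: config.overlap_size]
    aging_only = symbols[config.overlap_size : config.aging_size]
    exercise_only = symbols[config.aging_size :]
    aging = GeneSet("aging", frozenset(shared + aging_only))
    exercise = GeneSet("exercise", frozenset(shared + exercise_only))
    return aging, exercise


def _assign_terms(
    genes: Sequence[str], rate: float, rng: np.random.Generator
) -> list[str]:
    mask = rng.random(len(genes)) < rate
    return [g for g, hit in zip(genes, mask) if hit]


def generate_annotation_categories(
    config: SyntheticConfig,
    training: GeneSet,
    planted: Sequence[str],
    universe: Sequence[str],
    rng: np.random.Generator,
) -> tuple[list[AnnotationCategory], list[str]]:
    """Annotation categories with training-profile structure.

    All but the last category are categorical: each holds profile terms
    annotating ~70% of training genes each, carried by planted
    effectors with probability ``enrichment_strength`` and by any other
    gene at ``background_annotation_rate``, plus decoy terms annotating
    all genes at the background rate.  The last category (when 2+ are
    requested) is quantitative: training genes scatter around a profile
    mean vector; planted/background genes follow it with probability
    ``enrichment_strength`` / ``background_annotation_rate`` and are
    independent standard normal otherwise.  Returns the categories and
    the planted profile-term identifiers.
    """
    training_list = sorted(training.genes)
    planted_list = sorted(planted)
    background = sorted(set(universe) - training.genes - set(planted_list))
    n_categorical = config.n_categories - 1 if config.n_categories >= 2 else 1
    categories: list[AnnotationCategory] = []
    profile_terms: list[str] = []
    for c in range(n_categorical):
        name = f"CAT{c + 1}"
        terms_by_gene: dict[str, set[str]] = {}

        def add(genes: Sequence[str], term: str) -> None:
            for g in genes:
                terms_by_gene.setdefault(g, set()).add(term)

        for t in range(N_PROFILE_TERMS):
            term = f"{name}_PROFILE{t + 1}"
            profile_terms.append(term)
            add(_assign_terms(training_list, TRAINING_ANNOTATION_RATE, rng), term)
            add(_assign_terms(planted_list, config.enrichment_strength, rng), term)
            add(_assign_terms(background, config.background_annotation_rate, rng), term)
        for t in range(N_DECOY_TERMS):
            term = f"{name}_DECOY{t + 1}"
            add(_assign_terms(list(universe), config.background_annotation_rate, rng), term)
        categories.append(
            AnnotationCategory(
                name=name,
                kind="categorical",
                terms_by_gene={g: frozenset(t) for g, t in sorted(terms_by_gene.items())},
            )
        )
    if config.n_categories >= 2:
        mean = rng.normal(0.0, 1.0, QUANT_DIM)
        vectors: dict[str, np.ndarray] = {}
        for gene in sorted(universe):
            if gene in training.genes:
                follows = True
            elif gene in planted_list:
                follows = rng.random() < config.enrichment_strength
            else:
                follows = rng.random() < config.background_annotation_rate
            noise = rng.normal(0.0, QUANT_NOISE_SD if follows else 1.0, QUANT_DIM)
            vectors[gene] = mean + noise if follows else noise
        categories.append(
            AnnotationCategory(name="QUANT", kind="quantitative", vectors=vectors)
        )
    return categories, profile_terms


def generate_regulator_libraries(
    config: SyntheticConfig,
    aging: GeneSet,
    universe: Sequence[str],
    rng: np.random.Generator,
) -> tuple[list[RegulatorLibrary], list[str]]:
    """Regulator sources with one planted regulator each plus decoys.

    The planted regulator of each source targets 60% of the aging set
    (plus a few random genes); decoys target random universe genes.
    """
    libraries: list[RegulatorLibrary] = []
    planted_names: list[str] = []
    aging_list = sorted(aging.genes)
    universe_list = sorted(universe)
    n_covered = math.ceil(PLANTED_TARGET_COVERAGE * len(aging_list))
    for s in range(N_REGULATOR_SOURCES):
        source = f"SRC{s + 1}"
        regulators: dict[str, GeneSet] = {}
        planted_name = f"REG_PLANTED_{source}"
        planted_names.append(planted_name)
        covered_idx = rng.choice(len(aging_list), size=n_covered, replace=False)
        extra_idx = rng.choice(len(universe_list), size=40, replace=False)
        targets = {aging_list[i] for i in covered_idx} | {
            universe_list[i] for i in extra_idx
        }
        regulators[planted_name] = GeneSet(planted_name, frozenset(targets))
        for d in range(N_DECOY_REGULATORS):
            decoy = f"REG_{source}_D{d + 1:02d}"
            n_targets = int(rng.integers(20, 80))
            idx = rng.choice(len(universe_list), size=n_targets, replace=False)
            regulators[decoy] = GeneSet(
                decoy, frozenset(universe_list[i] for i in idx)
            )
        libraries.append(RegulatorLibrary(source_name=source, regulators=regulators))
    return libraries, planted_names


def generate_ppi(
    config: SyntheticConfig,
    training: GeneSet,
    planted: Sequence[str],
    member_genes: Sequence[str],
    universe: Sequence[str],
    rng: np.random.Generator,
) -> PPINetwork:
    """Scale-free PPI network with planted effectors wired to seed genes.

    The topology is preferential-attachment growth; node labels are a
    random assignment of genes (all set members plus random filler from
    the universe).  Each planted effector then gains ``seed_wiring``
    extra edges to distinct training genes.
    """
    members = sorted(set(member_genes))
    if config.network_nodes < len(members):
        raise ValidationError(
            f"network_nodes {config.network_nodes} < member genes {len(members)}"
        )
    filler_pool = sorted(set(universe) - set(members))
    n_filler = config.network_nodes - len(members)
    if n_filler > len(filler_pool):
        raise ValidationError("universe too small to fill the network")
    filler_idx = rng.choice(len(filler_pool), size=n_filler, replace=False)
    node_genes = members + [filler_pool[i] for i in filler_idx]
    node_genes = [node_genes[i] for i in rng.permutation(len(node_genes))]
    topology = nx.barabasi_albert_graph(
        config.network_nodes,
        config.attachment_edges,
        seed=int(rng.integers(2**31)),
    )
    graph = nx.relabel_nodes(topology, dict(enumerate(node_genes)))
    training_list = sorted(training.genes)
    for effector in sorted(planted) if config.seed_wiring > 0 else []:
        order = rng.permutation(len(training_list))
        wired = 0
        for i in order:
            seed_gene = training_list[i]
            if seed_gene != effector and not graph.has_edge(effector, seed_gene):
                graph.add_edge(seed_gene, effector)
                wired += 1
                if wired == config.seed_wiring:
                    break
        if wired < config.seed_wiring:
            raise ValidationError(
                f"could not wire effector {effector} to {config.seed_wiring} "
                "distinct training genes"
            )
    nx.set_edge_attributes(graph, 1.0, "weight")
    return PPINetwork(graph)


def generate_bundle(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Generate a complete, reproducible synthetic study bundle."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.rng_seed)
    universe = _universe_symbols(config.universe_size)
    aging, exercise = generate_overlapping_sets(config, rng)
    overlap = sorted(aging.genes & exercise.genes)
    training = GeneSet("training", aging.genes - exercise.genes)
    planted_idx = rng.choice(len(overlap), size=config.planted_effectors, replace=False)
    planted = sorted(overlap[i] for i in planted_idx)
    categories, profile_terms = generate_annotation_categories(
        config, training, planted, universe, rng
    )
    regulator_libraries, planted_regulators = generate_regulator_libraries(
        config, aging, universe, rng
    )
    network = generate_ppi(
        config, training, planted, sorted(aging.genes | exercise.genes), universe, rng
    )
    truth = {
        "planted_effectors": planted,
        "planted_regulators": planted_regulators,
        "planted_terms": profile_terms,
        "training_size": len(training),
        "test_size": len(overlap),
    }
    return SyntheticBundle(
        config=config,
        universe=universe,
        aging_set=aging,
        exercise_set=exercise,
        categories=categories,
        regulator_libraries=regulator_libraries,
        network=network,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle component in the pipeline's input formats.

    Emits gene lists, one GMT per categorical category and regulator
    source, a TSV matrix for the quantitative category, the edge-list
    network, the truth manifest, and a ready-to-run pipeline
    configuration.  Returns the path of every written file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["aging"] = out_dir / "aging.txt"
    write_gene_list(bundle.aging_set, paths["aging"])
    paths["exercise"] = out_dir / "exercise.txt"
    write_gene_list(bundle.exercise_set, paths["exercise"])
    paths["universe"] = out_dir / "universe.txt"
    write_gene_list(GeneSet("universe", frozenset(bundle.universe)), paths["universe"])
    annotation_gmts: list[str] = []
    quantitative_tsvs: list[str] = []
    for category in bundle.categories:
        if category.kind == "categorical":
            assert category.terms_by_gene is not None
            members: dict[str, set[str]] = {}
            for gene, terms in category.terms_by_gene.items():
                for term in terms:
                    members.setdefault(term, set()).add(gene)
            library = GeneSetLibrary(
                category.name,
                {t: GeneSet(t, frozenset(g)) for t, g in sorted(members.items())},
                universe_size=bundle.config.universe_size,
            )
            path = out_dir / f"category_{category.name}.gmt"
            write_gmt(library, path)
            annotation_gmts.append(str(path))
            paths[f"category_{category.name}"] = path
        else:
            path = out_dir / f"category_{category.name}.tsv"
            write_quantitative_tsv(category, path)
            quantitative_tsvs.append(str(path))
            paths[f"category_{category.name}"] = path
    regulator_gmts: list[str] = []
    for library in bundle.regulator_libraries:
        as_library = GeneSetLibrary(
            library.source_name,
            dict(sorted(library.regulators.items())),
            universe_size=bundle.config.universe_size,
        )
        path = out_dir / f"regulators_{library.source_name}.gmt"
        write_gmt(as_library, path)
        regulator_gmts.append(str(path))
        paths[f"regulators_{library.source_name}"] = path
    paths["network"] = out_dir / "ppi_edges.tsv"
    bundle.network.write_edgelist(paths["network"])
    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(
        json.dumps(bundle.truth, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    run_config = {
        "aging_path": str(paths["aging"]),
        "exercise_path": str(paths["exercise"]),
        "universe_path": str(paths["universe"]),
        "annotation_gmt_paths": annotation_gmts,
        "quantitative_tsv_paths": quantitative_tsvs,
        "regulator_gmt_paths": regulator_gmts,
        "network_path": str(paths["network"]),
        "out_dir": str(out_dir / "results"),
        "universe_size": bundle.config.universe_size,
        "rng_seed": bundle.config.rng_seed,
    }
    paths["run_config"] = out_dir / "run_config.json"
    paths["run_config"].write_text(
        json.dumps(run_config, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return paths
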