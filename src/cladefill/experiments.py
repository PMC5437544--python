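"""Self-contained removal/recovery experiments on synthetic clades.

These helpers wire a generated clade, the mock or library-backed adapters,
the pipeline and the recovery scoring together, mirroring the published
evaluation protocol: deplete the target annotation, rerun discovery, and
score each removed gene's best recovery by protein and orthogroup F-score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .adapters import AdapterSet, PyhmmerEngine
from .evaluation import RecoveryReport, recovery_report, simulate_removal
from .genome_io import Annotation, GeneModel
from .orthogroups import Member, discoverable_genes
from .pipeline import InputData, PipelineConfig, PipelineResult, run_pipeline
from .synthetic import (
    Clade,
    MockAligner,
    MockGenePredictor,
    MockOrthogroupInferrer,
    PredictorNoise,
)


def mock_adapters(
    clade: Clade,
    noise: PredictorNoise = PredictorNoise(),
    hmm_engine=None,
) -> AdapterSet:
    """Adapter set for clade fixtures: truth-backed mocks around a real or
    mock HMM engine (default: the pyhmmer-backed engine)."""
    return AdapterSet(
        inferrer=MockOrthogroupInferrer(clade),
        aligner=MockAligner(),
        hmm_engine=hmm_engine or PyhmmerEngine(),
        predictor=MockGenePredictor(clade.full_annotations, noise),
    )


def _base_config(clade: Clade, **overrides) -> PipelineConfig:
    defaults = dict(min_genes=1, min_n_fit=20, max_iterations=2)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@dataclass
class HiddenGeneRun:
    """Result of running discovery against a clade's deliberately hidden genes."""

    clade: Clade
    result: PipelineResult
    report: RecoveryReport


def run_hidden_gene_discovery(
    clade: Clade,
    noise: PredictorNoise = PredictorNoise(),
    hmm_engine=None,
    **config_overrides,
) -> HiddenGeneRun:
    """Run the pipeline on a clade and score recovery of its hidden genes."""
    config = _base_config(clade, **config_overrides)
    adapters = mock_adapters(clade, noise, hmm_engine)
    data = InputData(clade.genomes, dict(clade.annotations))
    result = run_pipeline(config, adapters, data)
    report = score_recovery(clade, clade.hidden_genes, result)
    return HiddenGeneRun(clade, result, report)


def score_recovery(
    clade: Clade,
    removed: Sequence[GeneModel],
    result: PipelineResult,
    depleted_target: Annotation | None = None,
) -> RecoveryReport:
    """Score a pipeline run against a set of removed/hidden truth genes."""
    target = clade.target_species
    found = result.novel.get(target, [])
    membership_full = clade.orthogroups_full.membership_index()
    og_before = {}
    for gene in removed:
        og_id = membership_full.get((target, gene.gene_id))
        if og_id:
            og_before[gene.gene_id] = clade.orthogroups_full.groups[og_id]
    og_after = {}
    for gene in found:
        og_id = result.assigned_og.get((target, gene.gene_id))
        og_after[gene.gene_id] = (
            result.final_orthogroups.groups.get(og_id)
            if result.final_orthogroups is not None and og_id
            else None
        )
    annotations = dict(clade.annotations)
    if depleted_target is not None:
        annotations[target] = depleted_target
    universe: set[Member] = {
        (sp, gid) for sp, ann in annotations.items() for gid in ann.genes
    }
    return recovery_report(list(removed), list(found), og_before, og_after, universe)


@dataclass
class RemovalRun:
    removed_ids: frozenset[str]
    result: PipelineResult
    report: RecoveryReport


def run_removal_experiment(
    clade: Clade,
    fraction: float,
    n_reps: int,
    seed: int,
    noise: PredictorNoise = PredictorNoise(),
    hmm_engine=None,
    **config_overrides,
) -> list[RemovalRun]:
    """Remove disjoint random fractions of discoverable target genes and
    measure recovery, one pipeline run per replicate.

    The clade should be generated with ``n_hidden=0`` so that removal is the
    only source of missing genes.
    """
    target = clade.target_species
    discoverable = discoverable_genes(clade.orthogroups, target)
    experiment = simulate_removal(
        clade.annotations[target], discoverable, fraction, n_reps, seed
    )
    runs: list[RemovalRun] = []
    for removed_ids in experiment.replicates:
        depleted = clade.annotations[target].without(removed_ids)
        data = InputData(
            clade.genomes,
            {**clade.annotations, target: depleted},
        )
        config = _base_config(clade, **config_overrides)
        adapters = mock_adapters(clade, noise, hmm_engine)
        result = run_pipeline(config, adapters, data)
        removed_genes = [clade.annotations[target].genes[g] for g in sorted(removed_ids)]
        report = score_recovery(clade, removed_genes, result, depleted_target=depleted)
        runs.append(RemovalRun(removed_ids, result, report))
    return runs
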