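"""End-to-end orchestration of the missing-gene discovery pipeline.

One iteration runs: orthogroup inference (or a user table) → per-orthogroup
protein MSA → back-translation to codon alignments → nucleotide HMM build
and genome search → hit classification and score-model fitting → posterior
filtering of candidate hits → hint export → hint-driven gene prediction →
hint F-score filter → joint orthogroup re-inference → orthogroup-assignment
filter → acceptance. Iterations repeat while new genes are accepted, up to
``max_iterations`` (default one pass).
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path

from .adapters import AdapterSet
from .gene_filter import (
    apply_hint_filter,
    build_hint_regions,
    drop_overlapping_predictions,
    orthogroup_assignment_filter,
    write_hints,
)
from .genome_io import (
    Annotation,
    GeneModel,
    coding_without_stop,
    extract_sequences,
    parse_gtf,
    read_fasta,
    backtranslate_alignment,
    write_outputs,
)
from .hit_scoring import (
    InsufficientHitsError,
    fit_score_model,
    filter_candidates,
    pooled_score_model,
    split_scores_by_class,
)
from .orthogroups import Member, OrthogroupSet, parse_orthogroup_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpeciesFiles:
    genome: Path
    gtf: Path


@dataclass
class PipelineConfig:
    species: dict[str, SpeciesFiles] = field(default_factory=dict)
    translation_table: int = 1
    min_genes: int = 100
    min_n_fit: int = 50
    hint_threshold: float = 0.8
    max_iterations: int = 1
    n_cpus: int = 1
    seed: int = 0
    allow_two_species: bool = False
    orthogroup_table: Path | None = None
    workdir: Path | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.hint_threshold <= 1.0):
            raise ValueError("hint_threshold must lie in (0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class InputData:
    genomes: dict[str, dict[str, str]]
    annotations: dict[str, Annotation]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


@dataclass
class StageCounts:
    """Per-species hit/gene counts for one iteration (stage accounting)."""

    n_hits: int = 0
    n_good: int = 0
    n_bad: int = 0
    n_candidates: int = 0
    n_retained: int = 0
    n_predicted: int = 0
    n_predicted_novel: int = 0
    n_hint_kept: int = 0
    n_accepted: int = 0
    score_model_pooled: bool = False
    score_model_skipped: bool = False


@dataclass
class RunState:
    iterations: list[dict[str, StageCounts]] = field(default_factory=list)

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "iteration", "species", "hits", "good", "bad", "candidates",
            "retained", "predicted", "predicted_novel", "hint_kept", "accepted",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for i, per_species in enumerate(self.iterations, start=1):
                for sp, c in sorted(per_species.items()):
                    fh.write(
                        "\t".join(
                            map(str, [
                                i, sp, c.n_hits, c.n_good, c.n_bad, c.n_candidates,
                                c.n_retained, c.n_predicted, c.n_predicted_novel,
                                c.n_hint_kept, c.n_accepted,
                            ])
                        )
                        + "\n"
                    )


@dataclass
class PipelineResult:
    novel: dict[str, list[GeneModel]]
    state: RunState
    #: orthogroup set from the final joint re-inference (None if none ran)
    final_orthogroups: OrthogroupSet | None
    #: accepted gene_id -> orthogroup id assigned on re-inference
    assigned_og: dict[tuple[str, str], str] = field(default_factory=dict)


def load_inputs(config: PipelineConfig) -> InputData:
    genomes: dict[str, dict[str, str]] = {}
    annotations: dict[str, Annotation] = {}
    for sp, files in config.species.items():
        genomes[sp] = read_fasta(files.genome)
        ann = parse_gtf(files.gtf, sp)
        annotations[sp] = extract_sequences(ann, genomes[sp], config.translation_table)
    return InputData(genomes, annotations)


def validate_inputs(config: PipelineConfig, data: InputData | None = None) -> ValidationReport:
    """Check the inputs carry enough annotation for the method to work.

    Each genome needs a basic level of annotation (default: at least 100
    annotated genes). Two-species input is known to behave poorly and is
    refused unless explicitly overridden; a single species is never enough.
    """
    report = ValidationReport()
    if data is None:
        for sp, files in config.species.items():
            if not Path(files.genome).exists():
                report.errors.append(f"{sp}: genome file {files.genome} missing")
            if not Path(files.gtf).exists():
                report.errors.append(f"{sp}: annotation file {files.gtf} missing")
        if report.errors:
            return report
        try:
            data = load_inputs(config)
        except Exception as exc:
            report.errors.append(f"unreadable input: {exc}")
            return report
    n_species = len(data.annotations)
    if n_species < 2:
        report.errors.append("at least two species are required")
    elif n_species == 2:
        msg = (
            "only two species supplied; the method performs poorly below three "
            "species — at least three are recommended"
        )
        if config.allow_two_species:
            report.warnings.append(msg)
        else:
            report.errors.append(msg + " (set allow_two_species to override)")
    for sp, ann in data.annotations.items():
        if len(ann) < config.min_genes:
            report.errors.append(
                f"{sp}: {len(ann)} annotated genes, below the required "
                f"minimum of {config.min_genes}"
            )
    return report


def _build_codon_alignments(
    ogs: OrthogroupSet,
    annotations: dict[str, Annotation],
    aligner,
) -> dict[str, dict[str, str]]:
    """Per-orthogroup codon alignments keyed ``species|gene_id``."""
    out: dict[str, dict[str, str]] = {}
    for og_id in sorted(ogs.groups):
        og = ogs.groups[og_id]
        prots: dict[str, str] = {}
        codings: dict[str, str] = {}
        for sp, gid in sorted(og.members):
            gene = annotations.get(sp, Annotation(sp)).genes.get(gid)
            if gene is None or not gene.protein:
                continue
            key = f"{sp}|{gid}"
            prots[key] = gene.protein
            codings[key] = coding_without_stop(gene)
        if len(prots) < 2:
            continue
        msa = aligner.align(prots)
        out[og_id] = backtranslate_alignment(msa, codings)
    return out


def run_pipeline(
    config: PipelineConfig,
    adapters: AdapterSet,
    data: InputData | None = None,
) -> PipelineResult:
    """Run the full pipeline; returns accepted novel genes per species.

    ``data`` may be supplied directly (tests, library use) or loaded from
    the configured file paths. All randomness downstream of the adapters is
    deterministic; adapters are expected to be deterministic too.
    """
    if data is None:
        data = load_inputs(config)
    report = validate_inputs(config, data)
    for w in report.warnings:
        logger.warning("%s", w)
    if not report.ok:
        raise ValueError("input validation failed:\n" + "\n".join(report.errors))
    if adapters.inferrer is None and config.orthogroup_table is None:
        raise ValueError("need an orthogroup inferrer or a precomputed table")

    workdir = config.workdir
    tmp_ctx = None
    if workdir is None:
        tmp_ctx = tempfile.TemporaryDirectory()
        workdir = Path(tmp_ctx.name)
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)

    annotations = dict(data.annotations)
    input_universe: set[Member] = {
        (sp, gid) for sp, ann in annotations.items() for gid in ann.genes
    }
    novel: dict[str, list[GeneModel]] = {sp: [] for sp in annotations}
    counters = {sp: 0 for sp in annotations}
    state = RunState()
    final_ogs: OrthogroupSet | None = None
    assigned_og: dict[tuple[str, str], str] = {}

    try:
        for iteration in range(1, config.max_iterations + 1):
            iter_dir = workdir / f"iteration_{iteration}"
            iter_dir.mkdir(exist_ok=True)
            counts = {sp: StageCounts() for sp in annotations}

            proteomes = {
                sp: {g.gene_id: g.protein for g in ann if g.protein}
                for sp, ann in annotations.items()
            }
            if iteration == 1 and config.orthogroup_table is not None:
                ogs = parse_orthogroup_table(
                    config.orthogroup_table, known_species=list(annotations)
                )
            else:
                ogs = adapters.inferrer.infer(proteomes)
            if not ogs.groups:
                raise RuntimeError("orthogroup inference produced zero orthogroups")
            logger.info(
                "iteration %d: %d orthogroups, %d singletons",
                iteration, len(ogs.groups), len(ogs.singletons),
            )

            codon_msas = _build_codon_alignments(ogs, annotations, adapters.aligner)

            hits_by_species: dict[str, list] = {sp: [] for sp in annotations}
            for sp, hits in adapters.hmm_engine.search_many(
                codon_msas, data.genomes, workdir=iter_dir
            ).items():
                hits_by_species[sp].extend(hits)

            class_by_species = {}
            for sp in sorted(annotations):
                good, bad, candidates = split_scores_by_class(
                    hits_by_species[sp], annotations[sp], ogs.groups
                )
                class_by_species[sp] = (good, bad, candidates)
                counts[sp].n_hits = len(hits_by_species[sp])
                counts[sp].n_good = len(good)
                counts[sp].n_bad = len(bad)
                counts[sp].n_candidates = len(candidates)

            total_bad = sum(len(b) for _, b, _ in class_by_species.values())
            retained_by_species: dict[str, list] = {}
            score_pool = {
                sp: (good, bad) for sp, (good, bad, _) in class_by_species.items()
            }
            for sp in sorted(annotations):
                good, bad, candidates = class_by_species[sp]
                model = fit_score_model(good, bad, config.min_n_fit, species=sp)
                if model is None:
                    if total_bad == 0:
                        # Degenerate input: no HMM ever hit a wrong gene, so there
                        # is no noise distribution to estimate; with no evidence
                        # of mistakes every candidate is retained.
                        logger.warning(
                            "%s: no bad hits anywhere; retaining all %d candidates",
                            sp, len(candidates),
                        )
                        counts[sp].score_model_skipped = True
                        retained_by_species[sp] = list(candidates)
                        counts[sp].n_retained = len(candidates)
                        continue
                    model = pooled_score_model(score_pool, sp, config.min_n_fit)
                    counts[sp].score_model_pooled = True
                retained, _rejected = filter_candidates(candidates, model)
                retained_by_species[sp] = retained
                counts[sp].n_retained = len(retained)
                assert len(retained) <= len(candidates)

            accepted_this_iteration = 0
            kept_by_species: dict[str, Annotation] = {}
            predictors_by_species: dict[str, dict[str, tuple[str, ...]]] = {}
            for sp in sorted(annotations):
                retained = retained_by_species[sp]
                hints_path = iter_dir / f"{sp}.hints.gff"
                write_hints(retained, hints_path)
                if not retained:
                    kept_by_species[sp] = Annotation(sp)
                    predictors_by_species[sp] = {}
                    continue
                predicted = adapters.predictor.predict(
                    sp, data.genomes[sp], hints_path
                )
                counts[sp].n_predicted = len(predicted)
                novel_preds = drop_overlapping_predictions(predicted, annotations[sp])
                regions = {
                    g.gene_id: build_hint_regions(retained, g) for g in novel_preds
                }
                novel_preds = [g for g in novel_preds if regions[g.gene_id]]
                counts[sp].n_predicted_novel = len(novel_preds)
                result = apply_hint_filter(
                    novel_preds, regions, config.hint_threshold
                )
                counts[sp].n_hint_kept = len(result.kept)
                assert len(result.kept) <= len(novel_preds)
                kept_ann = Annotation(sp)
                for gene in result.kept:
                    kept_ann.add(gene)
                kept_by_species[sp] = extract_sequences(
                    kept_ann, data.genomes[sp], config.translation_table
                )
                predictors_by_species[sp] = dict(result.predictors)

            # joint re-inference over original plus surviving new genes
            any_kept = any(len(a) for a in kept_by_species.values())
            if any_kept:
                combined = {
                    sp: dict(proteomes[sp]) for sp in proteomes
                }
                for sp, kept_ann in kept_by_species.items():
                    for gene in kept_ann:
                        combined[sp][gene.gene_id] = gene.protein
                if adapters.inferrer is None:
                    raise ValueError(
                        "orthogroup re-inference needs an inferrer adapter"
                    )
                final_ogs = adapters.inferrer.infer(combined)
                membership = final_ogs.membership_index()

                for sp in sorted(annotations):
                    for gene in kept_by_species[sp]:
                        og_id = membership.get((sp, gene.gene_id))
                        assigned = final_ogs.groups.get(og_id) if og_id else None
                        predicting = [
                            ogs.groups[p]
                            for p in predictors_by_species[sp].get(gene.gene_id, ())
                            if p in ogs.groups
                        ]
                        if orthogroup_assignment_filter(
                            gene.gene_id, assigned, predicting, input_universe
                        ):
                            counters[sp] += 1
                            new_id = f"cladefill_g{counters[sp]}.t1"
                            accepted = replace(gene, gene_id=new_id)
                            novel[sp].append(accepted)
                            annotations[sp] = Annotation(
                                sp, {**annotations[sp].genes, new_id: accepted}
                            )
                            assigned_og[(sp, new_id)] = assigned.og_id
                            accepted_this_iteration += 1
                            counts[sp].n_accepted += 1

            for sp, c in counts.items():
                assert c.n_accepted <= c.n_hint_kept <= c.n_predicted_novel
            state.iterations.append(counts)
            logger.info(
                "iteration %d accepted %d gene(s)", iteration, accepted_this_iteration
            )
            if accepted_this_iteration == 0:
                break

        results_dir = workdir / "results"
        results_dir.mkdir(exist_ok=True)
        for sp, genes in novel.items():
            write_outputs(
                genes,
                results_dir / f"{sp}.novel.gtf",
                results_dir / f"{sp}.novel.faa",
            )
        state.to_tsv(workdir / "stage_counts.tsv")
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()

    return PipelineResult(novel, state, final_ogs, assigned_og)
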