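"""Hint construction and the two validation filters for predicted genes.

Retained candidate hits become *hints* (exon-part evidence) for the gene
predictor. Each predicted gene is then compared against the hint regions
that informed it: the hint F-score is the harmonic mean of base-level
precision and recall between a merged same-orthogroup hint region H and the
gene's CDS G,

    hP = |H ∩ G| / |H|,  hR = |H ∩ G| / |G|,  hf = 2 hP hR / (hP + hR),

which is algebraically the Dice coefficient 2|H∩G| / (|H| + |G|). Genes
whose best hint region scores below the 0.8 threshold are discarded.
Survivors must additionally be clustered, on orthogroup re-inference over
original plus new genes, into a group sharing at least one *input* gene with
an orthogroup that predicted them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import Annotation, GeneModel
from .intervals import (
    GenomicInterval,
    any_overlap,
    intersection_length,
    merge_intervals,
    total_length,
)
from .orthogroups import Member, Orthogroup, orthogroup_overlap

HINT_FSCORE_THRESHOLD = 0.8


@dataclass(frozen=True)
class HintRegion:
    """Merged intervals of all same-orthogroup hints overlapping one gene."""

    og_id: str
    intervals: tuple[GenomicInterval, ...]

    @property
    def length(self) -> int:
        return total_length(self.intervals)


@dataclass(frozen=True)
class HintScore:
    gene_id: str
    og_id: str
    hP: float
    hR: float
    hf: float


def build_hint_regions(retained_hits, gene: GeneModel) -> list[HintRegion]:
    """Group gene-overlapping hits by orthogroup and merge each group.

    Hits overlap the gene when they share at least one base with a CDS
    interval (hints are exon-part evidence). Regions are returned sorted by
    orthogroup id; a gene with no overlapping hint yields an empty list.
    """
    by_og: dict[str, list[GenomicInterval]] = {}
    for hit in retained_hits:
        if any_overlap([hit.location], gene.cds):
            by_og.setdefault(hit.og_id, []).append(hit.location)
    return [
        HintRegion(og_id, tuple(merge_intervals(ivs)))
        for og_id, ivs in sorted(by_og.items())
    ]


def hint_fscore(region: HintRegion, gene: GeneModel) -> HintScore:
    """Base-level precision/recall F-score between a hint region and a gene.

    |G| is the gene's total CDS length (hints carry exon-part, not genomic
    span, evidence).
    """
    h_len = region.length
    g_len = gene.cds_length
    if h_len == 0 or g_len == 0:
        raise ValueError("hint region and gene must both have positive length")
    inter = intersection_length(region.intervals, gene.cds)
    hp = inter / h_len
    hr = inter / g_len
    hf = 0.0 if inter == 0 else 2.0 * hp * hr / (hp + hr)
    return HintScore(gene.gene_id, region.og_id, hp, hr, hf)


@dataclass
class HintFilterResult:
    kept: list[GeneModel]
    discarded: list[GeneModel]
    #: gene_id -> orthogroup ids whose regions passed the threshold
    predictors: dict[str, tuple[str, ...]] = field(default_factory=dict)
    #: gene_id -> best HintScore
    best_scores: dict[str, HintScore] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.kept, self.discarded))


def apply_hint_filter(
    genes: Sequence[GeneModel],
    regions: Mapping[str, Sequence[HintRegion]],
    threshold: float = HINT_FSCORE_THRESHOLD,
) -> HintFilterResult:
    """Keep genes whose best hint region reaches the threshold F-score.

    A gene informed by several orthogroups passes if any region passes, and
    every passing orthogroup is recorded as a predictor for the subsequent
    orthogroup-assignment filter. The threshold is inclusive: scores below
    it are discarded, a score exactly at it is kept.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    result = HintFilterResult([], [])
    for gene in genes:
        scores = [hint_fscore(r, gene) for r in regions.get(gene.gene_id, [])]
        passing = [s for s in scores if s.hf >= threshold]
        if passing:
            result.kept.append(gene)
            result.predictors[gene.gene_id] = tuple(s.og_id for s in passing)
        else:
            result.discarded.append(gene)
        if scores:
            result.best_scores[gene.gene_id] = max(scores, key=lambda s: s.hf)
    return result


def orthogroup_assignment_filter(
    new_gene: str,
    assigned_og: Orthogroup | None,
    predicting_ogs: Sequence[Orthogroup],
    input_universe: set[Member],
) -> bool:
    """Accept a new gene iff its re-inferred orthogroup shares at least one
    input gene with some orthogroup that predicted it.

    Orthogroup membership may fluctuate between runs, so only non-zero
    overlap is required — but the overlap counts input genes only, never
    newly discovered ones. An unclustered gene (assigned_og None) fails.
    """
    if assigned_og is None:
        return False
    return any(
        orthogroup_overlap(assigned_og, og, input_universe) > 0
        for og in predicting_ogs
    )


def drop_overlapping_predictions(
    predicted: Iterable[GeneModel], annotation: Annotation
) -> list[GeneModel]:
    """Discard predictions overlapping a pre-existing annotated gene.

    The method only adds genes absent from the annotation; anything touching
    a known gene (>= 1 shared CDS base, strand-agnostic) is not novel.
    """
    kept = []
    for gene in predicted:
        clash = any(
            existing.seq_id == gene.seq_id
            and any_overlap(gene.cds, existing.cds)
            for existing in annotation
        )
        if not clash:
            kept.append(gene)
    return kept


def write_hints(hits, path: str | Path, source: str = "cladefill", priority: int = 4) -> None:
    """Write retained hits as an exon-part hint file (predictor dialect)."""
    with open(path, "w") as fh:
        for hit in hits:
            iv = hit.location
            attrs = f"grp={hit.og_id};src=M;pri={priority}"
            fh.write(
                "\t".join(
                    [
                        iv.seq_id, source, "exonpart", str(iv.start + 1), str(iv.end),
                        f"{hit.bit_score:.2f}", iv.strand, ".", attrs,
                    ]
                )
                + "\n"
            )


def parse_hints(path: str | Path):
    """Read a hint file back as (interval, og_id) pairs."""
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            seq_id, _src, _type, start_s, end_s, _score, strand, _frame, attrs = fields
            og_id = ""
            for part in attrs.split(";"):
                if part.startswith("grp="):
                    og_id = part[4:]
            out.append(
                (GenomicInterval(seq_id, int(start_s) - 1, int(end_s), strand), og_id)
            )
    return out
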