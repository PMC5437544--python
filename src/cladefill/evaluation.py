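"""Removal/recovery evaluation: simulate missing genes and score recoveries.

The evaluation removes a random fraction of a species' *discoverable* genes
(those sharing an orthogroup with another species), reruns the pipeline on
the depleted annotation, and measures how well removed genes are recovered.
A removed gene counts as recovered when a newly predicted gene overlaps it
(non-zero genomic overlap). Recovery quality is scored two ways:

* protein F-score pF — harmonic mean of pP = |S∩S'|/|S| and pR = |S∩S'|/|S'|
  where |S∩S'| is the number of identical aligned residues in a global
  pairwise alignment of the removed (S) and recovered (S') proteins;
* orthogroup F-score oF — harmonic mean of the analogous overlap fractions
  between the gene's original orthogroup and the orthogroup it lands in on
  re-inference, counting only genes from the original input annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import Annotation, GeneModel
from .intervals import any_overlap
from .orthogroups import Member, Orthogroup

HIGH_QUALITY_PF = 0.95


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


_ALIGNER = _make_aligner()


@dataclass(frozen=True)
class RemovalExperiment:
    """Disjoint random removal sets drawn from the discoverable genes."""

    species: str
    fraction: float
    replicates: tuple[frozenset[str], ...]
    seed: int


def removal_set_size(n_discoverable: int, fraction: float) -> int:
    """Round half up: 10% of 5129 discoverable genes is 513 per replicate."""
    return int(n_discoverable * fraction + 0.5)


def simulate_removal(
    annotation: Annotation,
    discoverable: set[str],
    fraction: float,
    n_reps: int,
    seed: int,
) -> RemovalExperiment:
    """Draw ``n_reps`` pairwise-disjoint removal sets of the given fraction.

    Deterministic for a given seed: one permutation of the discoverable
    genes is sliced into consecutive blocks, so replicates are disjoint by
    construction. Rounding half-up can make ``n_reps`` full-size blocks
    exceed the pool by a gene or two even when the fractions sum to one
    (10 x round(0.1 x 5129) = 5130); in that case the final replicate simply
    takes whatever remains of the permutation.
    """
    if not discoverable:
        raise ValueError("no discoverable genes to remove")
    missing = discoverable - set(annotation.genes)
    if missing:
        raise ValueError(f"discoverable genes absent from annotation: {sorted(missing)[:5]}")
    if fraction * n_reps > 1.0 + 1e-9:
        raise ValueError(
            f"cannot draw {n_reps} disjoint fractions of {fraction:g} "
            f"(total exceeds the discoverable pool)"
        )
    size = removal_set_size(len(discoverable), fraction)
    rng = np.random.default_rng(seed)
    order = rng.permutation(sorted(discoverable))
    replicates = tuple(
        frozenset(order[i * size : (i + 1) * size]) for i in range(n_reps)
    )
    return RemovalExperiment(annotation.species, fraction, replicates, seed)


def write_depleted_gtf(
    annotation: Annotation, removed: Iterable[str], path: str | Path
) -> Annotation:
    from .genome_io import write_gtf

    depleted = annotation.without(removed)
    write_gtf(depleted, path)
    return depleted


def aligned_identity_count(s: str, s_prime: str) -> int:
    """Identical residues in the best global pairwise alignment."""
    alignment = _ALIGNER.align(s, s_prime)[0]
    count = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        count += sum(x == y for x, y in zip(s[a0:a1], s_prime[b0:b1]))
    return count


def protein_fscore(s: str, s_prime: str) -> float:
    """Harmonic mean of aligned-identity precision and recall of two proteins.

    Among co-optimal global alignments the identity count can depend on the
    argument order; both orders are aligned and the larger count is used, so
    the score is symmetric by construction.
    """
    if not s or not s_prime:
        raise ValueError("protein F-score requires two non-empty sequences")
    inter = max(
        aligned_identity_count(s, s_prime), aligned_identity_count(s_prime, s)
    )
    if inter == 0:
        return 0.0
    pp = inter / len(s)
    pr = inter / len(s_prime)
    return 2.0 * pp * pr / (pp + pr)


def orthogroup_fscore(
    og: Orthogroup, og_prime: Orthogroup, input_universe: set[Member]
) -> float:
    """Harmonic mean of orthogroup overlap fractions, on input genes only."""
    o = og.members & input_universe
    o_prime = og_prime.members & input_universe
    if not o:
        raise ValueError(
            f"orthogroup {og.og_id} has no members in the input universe"
        )
    if not o_prime:
        return 0.0
    inter = len(o & o_prime)
    if inter == 0:
        return 0.0
    op = inter / len(o)
    orc = inter / len(o_prime)
    return 2.0 * op * orc / (op + orc)


@dataclass
class GeneMatch:
    removed_gene: GeneModel
    found_genes: list[GeneModel]
    pF: float
    oF: float

    @property
    def split(self) -> bool:
        return len(self.found_genes) >= 2


@dataclass
class RecoveryReport:
    """Per-run recovery accounting in the layout of the published tables."""

    n_removed: int
    n_found: int
    n_found_overlapping: int
    n_recovered: int
    n_split: int
    mean_pF: float
    mean_oF: float
    n_high_quality: int
    n_low_quality: int
    mean_pF_low: float
    pct_low_with_low_oF: float
    matches: list[GeneMatch] = field(default_factory=list, repr=False)

    def rows(self) -> list[tuple[str, float]]:
        return [
            ("No. genes removed", self.n_removed),
            ("Total genes found", self.n_found),
            ("Found genes which overlap removed genes", self.n_found_overlapping),
            ("Total recovered genes", self.n_recovered),
            ("Number of split genes", self.n_split),
            ("Mean pF-score of found genes", self.mean_pF),
            ("Mean oF-score of found genes", self.mean_oF),
            ("High-quality found genes (pF-score >= 0.95)", self.n_high_quality),
            ("Lower-quality found genes (pF-score < 0.95)", self.n_low_quality),
            ("Mean pF-score of lower-quality genes", self.mean_pF_low),
            ("% of lower-quality genes with oF-score < 0.95", self.pct_low_with_low_oF),
        ]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, value in self.rows():
                fh.write(f"{name}\t{value:g}\n")

    def gene_scores_tsv(self, path: str | Path) -> None:
        """Per-gene (gene_id, pF, oF) table, suitable for density plots."""
        with open(path, "w") as fh:
            fh.write("gene_id\tpF\toF\n")
            for m in self.matches:
                fh.write(f"{m.removed_gene.gene_id}\t{m.pF:g}\t{m.oF:g}\n")


def _genes_overlap(a: GeneModel, b: GeneModel) -> bool:
    return a.seq_id == b.seq_id and any_overlap(a.cds, b.cds)


def recovery_report(
    removed: Sequence[GeneModel],
    found: Sequence[GeneModel],
    og_before: Mapping[str, Orthogroup],
    og_after: Mapping[str, Orthogroup | None],
    universe: set[Member],
) -> RecoveryReport:
    """Score a recovery run.

    ``og_before`` maps removed gene_ids to their full-annotation orthogroup;
    ``og_after`` maps found gene_ids to the orthogroup assigned on
    re-inference (None when unclustered). When several found genes overlap
    one removed gene the best-pF match is reported, the gene counts once
    toward recovery, and the gene is flagged as split.
    """
    matches: list[GeneMatch] = []
    overlapping_found: set[str] = set()
    for gene in removed:
        overlapping = [g for g in found if _genes_overlap(gene, g)]
        overlapping_found.update(g.gene_id for g in overlapping)
        if not overlapping:
            continue
        scored = []
        for g in overlapping:
            if gene.protein and g.protein:
                scored.append((protein_fscore(gene.protein, g.protein), g))
            else:
                scored.append((0.0, g))
        best_pf, best_gene = max(scored, key=lambda t: t[0])
        assigned = og_after.get(best_gene.gene_id)
        original = og_before.get(gene.gene_id)
        if original is not None and assigned is not None:
            of = orthogroup_fscore(original, assigned, universe)
        else:
            of = 0.0
        matches.append(GeneMatch(gene, overlapping, best_pf, of))

    n_recovered = len(matches)
    n_split = sum(m.split for m in matches)
    pfs = np.array([m.pF for m in matches]) if matches else np.array([])
    ofs = np.array([m.oF for m in matches]) if matches else np.array([])
    low = pfs[pfs < HIGH_QUALITY_PF] if matches else np.array([])
    low_of = ofs[pfs < HIGH_QUALITY_PF] if matches else np.array([])
    return RecoveryReport(
        n_removed=len(removed),
        n_found=len(found),
        n_found_overlapping=len(overlapping_found),
        n_recovered=n_recovered,
        n_split=int(n_split),
        mean_pF=float(pfs.mean()) if pfs.size else 0.0,
        mean_oF=float(ofs.mean()) if ofs.size else 0.0,
        n_high_quality=int(np.sum(pfs >= HIGH_QUALITY_PF)),
        n_low_quality=int(np.sum(pfs < HIGH_QUALITY_PF)),
        mean_pF_low=float(low.mean()) if low.size else 0.0,
        pct_low_with_low_oF=(
            100.0 * float(np.mean(low_of < HIGH_QUALITY_PF)) if low_of.size else 0.0
        ),
        matches=matches,
    )
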