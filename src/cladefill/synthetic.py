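"""Synthetic clade generator and mock external tools.

Emulates the removal/recovery experimental setup on a toy scale: a small
clade of related genomes sharing mutated gene families, with some genes of a
target species present in its genome sequence but deliberately absent from
its annotation. Every stage of the pipeline is exercisable against known
truth without any external downloads.

Families descend from random ancestral CDSs (start codon, in-frame non-stop
codons, stop codon); species copies differ by per-site substitutions only
(no indels), so family proteins stay column-comparable and protein F-scores
on fixtures are exactly computable. Genes are placed on one contig per
species with random intergenic spacers; a random-sequence decoy region with
no homology to any family is always planted in the target genome.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import (
    Annotation,
    GeneModel,
    extract_sequences,
    write_genome_fasta,
    write_gtf,
)
from .gene_filter import parse_hints
from .hit_scoring import HmmHit
from .intervals import GenomicInterval
from .orthogroups import (
    Member,
    Orthogroup,
    OrthogroupSet,
    build_orthogroup_set,
    write_orthogroup_table,
)
from .skewt import SkewTParams

BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = [
    "".join(c) for c in itertools.product(BASES, repeat=3)
    if "".join(c) not in STOP_CODONS
]
SPECIES_NAMES = ["alpha", "beta", "gamma", "delta", "epsilon"]


@dataclass(frozen=True)
class CladeSpec:
    """Study conditions for one synthetic clade."""

    n_species: int = 3
    n_families: int = 20
    family_size_range: tuple[int, int] = (1, 2)
    mutation_rate: float = 0.05
    n_hidden: int = 5
    intergenic_length: int = 200
    max_introns: int = 0
    decoy_length: int = 600
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if not (0.0 <= self.mutation_rate < 0.5):
            raise ValueError("mutation_rate must lie in [0, 0.5)")
        lo, hi = self.family_size_range
        if not (1 <= lo <= hi):
            raise ValueError("family_size_range must satisfy 1 <= min <= max")
        if self.n_hidden > self.n_families * lo:
            raise ValueError("n_hidden exceeds the guaranteed gene count")


@dataclass
class Clade:
    """A generated clade with full ground truth."""

    spec: CladeSpec
    species: list[str]
    target_species: str
    genomes: dict[str, dict[str, str]]
    #: per-species annotations as the pipeline sees them (target depleted)
    annotations: dict[str, Annotation]
    #: per-species annotations including the hidden genes
    full_annotations: dict[str, Annotation]
    hidden_genes: list[GeneModel]
    #: orthogroups over the annotated (visible) genes only
    orthogroups: OrthogroupSet
    #: orthogroups over all genes including hidden ones
    orthogroups_full: OrthogroupSet
    family_of: dict[Member, str] = field(default_factory=dict)
    decoy_region: GenomicInterval | None = None


def _random_spacer(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _ancestral_cds(rng: np.random.Generator) -> str:
    n_codons = int(rng.integers(100, 501))  # 300-1503 nt total with start+stop
    middle = rng.choice(NON_STOP_CODONS, size=n_codons)
    return "ATG" + "".join(middle) + "TAA"


def _mutate(cds: str, rate: float, rng: np.random.Generator) -> str:
    """Per-site substitution preserving start/stop and avoiding internal stops."""
    seq = list(cds)
    for i in range(3, len(seq) - 3):
        if rng.random() < rate:
            current = seq[i]
            seq[i] = BASES[(BASES.index(current) + int(rng.integers(1, 4))) % 4]
    # repair any internal stop codon the substitutions created
    for c in range(1, len(seq) // 3 - 1):
        codon = "".join(seq[3 * c : 3 * c + 3])
        if codon in STOP_CODONS:
            seq[3 * c : 3 * c + 3] = list(
                NON_STOP_CODONS[int(rng.integers(len(NON_STOP_CODONS)))]
            )
    return "".join(seq)


def _intervals_for_gene(
    cds: str,
    offset: int,
    seq_id: str,
    strand: str,
    n_introns: int,
    rng: np.random.Generator,
) -> tuple[list[GenomicInterval], str]:
    """Lay a CDS down at ``offset``, optionally interrupted by introns.

    Returns the CDS intervals (genome coordinates) and the genomic sequence
    of the locus (CDS segments plus introns, already strand-oriented).
    """
    from Bio.Seq import Seq

    oriented = cds if strand == "+" else str(Seq(cds).reverse_complement())
    if n_introns == 0:
        iv = GenomicInterval(seq_id, offset, offset + len(cds), strand)
        return [iv], oriented
    # split points at codon boundaries in genomic orientation
    cuts = sorted(
        int(x) * 3
        for x in rng.choice(np.arange(1, len(cds) // 3), size=n_introns, replace=False)
    )
    pieces = []
    prev = 0
    for cut in cuts:
        pieces.append(oriented[prev:cut])
        prev = cut
    pieces.append(oriented[prev:])
    intervals = []
    locus_parts = []
    pos = offset
    for i, piece in enumerate(pieces):
        intervals.append(GenomicInterval(seq_id, pos, pos + len(piece), strand))
        locus_parts.append(piece)
        pos += len(piece)
        if i < len(pieces) - 1:
            intron = "GT" + _random_spacer(rng, int(rng.integers(40, 80))) + "AG"
            locus_parts.append(intron)
            pos += len(intron)
    return intervals, "".join(locus_parts)


def generate_clade(spec: CladeSpec) -> Clade:
    """Generate genomes, annotations, hidden genes and truth orthogroups.

    Deterministic given the seed. Hidden genes always belong to families
    with at least one annotated member in another species, so they are all
    discoverable by construction.
    """
    rng = np.random.default_rng(spec.seed)
    species = [
        SPECIES_NAMES[i] if i < len(SPECIES_NAMES) else f"sp{i + 1}"
        for i in range(spec.n_species)
    ]
    target = species[0]

    # family -> species -> list of member CDS strings
    lo, hi = spec.family_size_range
    family_cds: dict[str, dict[str, list[str]]] = {}
    for f in range(spec.n_families):
        og_id = f"FAM{f:04d}"
        ancestor = _ancestral_cds(rng)
        family_cds[og_id] = {}
        for sp in species:
            k = int(rng.integers(lo, hi + 1))
            family_cds[og_id][sp] = [
                _mutate(ancestor, spec.mutation_rate, rng) for _ in range(k)
            ]

    genomes: dict[str, dict[str, str]] = {}
    gene_models: dict[str, list[GeneModel]] = {sp: [] for sp in species}
    family_of: dict[Member, str] = {}
    decoy_region: GenomicInterval | None = None

    for sp in species:
        contig = f"{sp}_chr1"
        entries = []  # (og_id, member_index, cds)
        for og_id in sorted(family_cds):
            for m, cds in enumerate(family_cds[og_id][sp], start=1):
                entries.append((og_id, m, cds))
        order = rng.permutation(len(entries))
        # the decoy occupies a random slot in the target genome's gene order
        decoy_slot = int(rng.integers(len(entries) + 1)) if sp == target else -1

        parts = []
        pos = 0
        for slot, idx in enumerate(order):
            if slot == decoy_slot:
                spacer = _random_spacer(rng, spec.intergenic_length)
                decoy = _random_spacer(rng, spec.decoy_length)
                parts.extend([spacer, decoy])
                pos += len(spacer)
                decoy_region = GenomicInterval(contig, pos, pos + len(decoy))
                pos += len(decoy)
            og_id, m, cds = entries[idx]
            spacer = _random_spacer(rng, spec.intergenic_length)
            parts.append(spacer)
            pos += len(spacer)
            strand = "+" if rng.random() < 0.5 else "-"
            n_introns = (
                int(rng.integers(1, spec.max_introns + 1)) if spec.max_introns else 0
            )
            intervals, locus_seq = _intervals_for_gene(
                cds, pos, contig, strand, n_introns, rng
            )
            parts.append(locus_seq)
            pos += len(locus_seq)
            gene_id = f"{sp}_{og_id}_{m}"
            gene_models[sp].append(GeneModel(gene_id, sp, intervals))
            family_of[(sp, gene_id)] = og_id
        if sp == target and decoy_slot == len(entries):
            spacer = _random_spacer(rng, spec.intergenic_length)
            decoy = _random_spacer(rng, spec.decoy_length)
            parts.extend([spacer, decoy])
            pos += len(spacer)
            decoy_region = GenomicInterval(contig, pos, pos + len(decoy))
            pos += len(decoy)
        parts.append(_random_spacer(rng, spec.intergenic_length))
        genomes[sp] = {contig: "".join(parts)}

    full_annotations: dict[str, Annotation] = {}
    for sp in species:
        ann = Annotation(sp)
        for gene in gene_models[sp]:
            ann.add(gene)
        full_annotations[sp] = extract_sequences(ann, genomes[sp])

    # hide n_hidden target genes whose family has a member in another species
    eligible = [
        g.gene_id
        for g in full_annotations[target]
        if any(
            family_cds[family_of[(target, g.gene_id)]][sp2]
            for sp2 in species
            if sp2 != target
        )
    ]
    hidden_ids = list(rng.choice(eligible, size=spec.n_hidden, replace=False))
    hidden_genes = [full_annotations[target].genes[g] for g in sorted(hidden_ids)]

    annotations = dict(full_annotations)
    annotations[target] = full_annotations[target].without(hidden_ids)

    def og_set(include_hidden: bool) -> OrthogroupSet:
        raw: dict[str, list[Member]] = {og_id: [] for og_id in sorted(family_cds)}
        hidden = {(target, g) for g in hidden_ids}
        for member, og_id in family_of.items():
            if include_hidden or member not in hidden:
                raw[og_id].append(member)
        return build_orthogroup_set({k: v for k, v in raw.items() if v})

    return Clade(
        spec=spec,
        species=species,
        target_species=target,
        genomes=genomes,
        annotations=annotations,
        full_annotations=full_annotations,
        hidden_genes=hidden_genes,
        orthogroups=og_set(include_hidden=False),
        orthogroups_full=og_set(include_hidden=True),
        family_of=family_of,
        decoy_region=decoy_region,
    )


def write_clade(clade: Clade, outdir: str | Path) -> None:
    """Write the clade in the formats the pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for sp in clade.species:
        write_genome_fasta(clade.genomes[sp], outdir / f"{sp}.genome.fa")
        write_gtf(clade.annotations[sp], outdir / f"{sp}.gtf")
    write_gtf(clade.hidden_genes, outdir / "hidden_truth.gtf")
    write_orthogroup_table(
        clade.orthogroups, outdir / "orthogroups.tsv", clade.species
    )


def generate_score_samples(
    good_params: SkewTParams,
    bad_params: SkewTParams,
    n_good: int,
    n_bad: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Labelled adjusted-score samples from two skew-t distributions."""
    rng = np.random.default_rng(seed)
    good = good_params.rvs(n_good, rng) if n_good else np.empty(0)
    bad = bad_params.rvs(n_bad, rng) if n_bad else np.empty(0)
    return good, bad


@dataclass(frozen=True)
class PredictorNoise:
    """Boundary jitter / gene splitting applied by the mock predictor."""

    jitter: int = 0
    split: bool = False
    seed: int = 0


class MockGenePredictor:
    """Stand-in gene predictor: emits the truth model under each hint.

    Synthetic oracle, not a trained predictor — it looks up the known truth
    gene overlapping each hint and optionally degrades it (boundary jitter,
    or splitting one gene into two abutting halves) to exercise the hint
    filter and the split-gene accounting.
    """

    def __init__(
        self,
        truth: Annotation | Mapping[str, Annotation],
        noise: PredictorNoise = PredictorNoise(),
    ):
        self.truth_by_species: dict[str, Annotation]
        if isinstance(truth, Annotation):
            self.truth_by_species = {truth.species: truth}
        else:
            self.truth_by_species = dict(truth)
        self.noise = noise

    def predict(
        self, species: str, genome: Mapping[str, str], hints_path: str | Path
    ) -> Annotation:
        if species not in self.truth_by_species:
            raise ValueError(f"no truth annotation registered for {species}")
        truth = self.truth_by_species[species]
        rng = np.random.default_rng(self.noise.seed)
        hints = parse_hints(hints_path)
        for iv, _og in hints:
            if iv.seq_id not in genome:
                raise ValueError(f"hint on unknown contig {iv.seq_id}")
        hit_genes: list[GeneModel] = []
        seen: set[str] = set()
        for gene in sorted(truth, key=lambda g: (g.seq_id, g.cds[0].start)):
            if gene.gene_id in seen:
                continue
            if any(
                iv.seq_id == gene.seq_id and any(iv.overlaps(c) for c in gene.cds)
                for iv, _og in hints
            ):
                hit_genes.append(gene)
                seen.add(gene.gene_id)

        predicted = Annotation(species)
        counter = itertools.count(1)
        for gene in hit_genes:
            models = [gene]
            if self.noise.split:
                models = _split_gene(gene)
            if self.noise.jitter:
                models = [_jitter_gene(m, self.noise.jitter, rng, genome) for m in models]
            for model in models:
                predicted.add(
                    replace(
                        model,
                        gene_id=f"pred_g{next(counter)}",
                        coding_seq=None,
                        protein=None,
                    )
                )
        return predicted


def _split_gene(gene: GeneModel) -> list[GeneModel]:
    """Split a gene into two abutting halves at a codon boundary."""
    half = 3 * ((gene.cds_length // 2) // 3)
    if half < 3 or gene.cds_length - half < 3:
        return [gene]
    first: list[GenomicInterval] = []
    second: list[GenomicInterval] = []
    used = 0
    for iv in gene.cds:
        if used >= half:
            second.append(iv)
        elif used + iv.length <= half:
            first.append(iv)
        else:
            cut = iv.start + (half - used)
            first.append(GenomicInterval(iv.seq_id, iv.start, cut, iv.strand))
            second.append(GenomicInterval(iv.seq_id, cut, iv.end, iv.strand))
        used += iv.length
    return [
        replace(gene, gene_id=gene.gene_id + "_a", cds=first),
        replace(gene, gene_id=gene.gene_id + "_b", cds=second),
    ]


def _jitter_gene(
    gene: GeneModel,
    jitter: int,
    rng: np.random.Generator,
    genome: Mapping[str, str],
) -> GeneModel:
    limit = len(genome[gene.seq_id])
    new_cds = []
    for iv in gene.cds:
        start = iv.start + int(rng.integers(-jitter, jitter + 1))
        end = iv.end + int(rng.integers(-jitter, jitter + 1))
        start = max(0, min(start, iv.end - 3))
        end = min(limit, max(end, start + 3))
        new_cds.append(GenomicInterval(iv.seq_id, start, end, iv.strand))
    try:
        return replace(gene, cds=new_cds)
    except ValueError:  # jitter made intervals collide; keep the original
        return gene


class MockOrthogroupInferrer:
    """Stand-in orthogroup inference backed by the clade's ground truth.

    Input genes are assigned to their true family; unseen genes (the
    pipeline's newly predicted ones) are matched by exact protein identity
    against the truth, falling back to 6-mer similarity, else left as
    singletons. Deterministic.
    """

    KMER = 6
    MIN_JACCARD = 0.3

    def __init__(self, clade: Clade):
        self.clade = clade
        self._protein_to_family: dict[str, str] = {}
        self._family_kmers: dict[str, set[str]] = {}
        for sp in clade.species:
            for gene in clade.full_annotations[sp]:
                fam = clade.family_of[(sp, gene.gene_id)]
                if gene.protein:
                    self._protein_to_family.setdefault(gene.protein, fam)
                    self._family_kmers.setdefault(fam, set()).update(
                        self._kmers(gene.protein)
                    )

    @classmethod
    def _kmers(cls, protein: str) -> set[str]:
        k = cls.KMER
        return {protein[i : i + k] for i in range(max(1, len(protein) - k + 1))}

    def _assign(self, species: str, gene_id: str, protein: str) -> str | None:
        fam = self.clade.family_of.get((species, gene_id))
        if fam:
            return fam
        fam = self._protein_to_family.get(protein)
        if fam:
            return fam
        mine = self._kmers(protein)
        best, best_j = None, 0.0
        for fam, kmers in sorted(self._family_kmers.items()):
            j = len(mine & kmers) / len(mine | kmers)
            if j > best_j:
                best, best_j = fam, j
        return best if best_j >= self.MIN_JACCARD else None

    def infer(self, proteomes: Mapping[str, Mapping[str, str]]) -> OrthogroupSet:
        raw: dict[str, list[Member]] = {}
        unassigned: list[Member] = []
        for species in sorted(proteomes):
            for gene_id in sorted(proteomes[species]):
                fam = self._assign(species, gene_id, proteomes[species][gene_id])
                if fam is None:
                    unassigned.append((species, gene_id))
                else:
                    raw.setdefault(fam, []).append((species, gene_id))
        ogs = build_orthogroup_set(raw)
        ogs.singletons |= set(unassigned)
        return ogs


class MockAligner:
    """Stand-in protein MSA: fixtures have no indels, so equal-length family
    proteins are already column-aligned; unequal lengths get trailing gaps."""

    def align(self, seqs: Mapping[str, str]) -> dict[str, str]:
        if not seqs:
            return {}
        width = max(len(s) for s in seqs.values())
        return {gid: s + "-" * (width - len(s)) for gid, s in seqs.items()}


class MockHmmEngine:
    """Stand-in HMM search: emits hits at known gene loci with sampled scores.

    For each orthogroup, every truth member locus (annotated or hidden) in
    every genome receives a hit whose per-base score is drawn from
    ``good_dist``. Optional noise adds cross-orthogroup hits over other
    genes (bad hits) and intergenic hits (low-scoring candidates), both
    drawn from ``bad_dist`` — enough of these lets the score-model fitting
    path run on fixtures.
    """

    def __init__(
        self,
        clade: Clade,
        good_dist: SkewTParams = SkewTParams(1.5, 0.25, 2.0, 8.0),
        bad_dist: SkewTParams = SkewTParams(0.3, 0.15, 2.0, 8.0),
        n_bad_per_og: int = 0,
        n_decoy_candidates: int = 0,
        seed: int = 0,
    ):
        self.clade = clade
        self.good_dist = good_dist
        self.bad_dist = bad_dist
        self.n_bad_per_og = n_bad_per_og
        self.n_decoy_candidates = n_decoy_candidates
        self.rng = np.random.default_rng(seed)

    def search_many(
        self,
        nuc_msas: Mapping[str, Mapping[str, str]],
        genomes: Mapping[str, Mapping[str, str]],
        workdir=None,
    ) -> dict[str, list[HmmHit]]:
        out: dict[str, list[HmmHit]] = {sp: [] for sp in genomes}
        for og_id in sorted(nuc_msas):
            for sp, hits in self.search_orthogroup(
                og_id, nuc_msas[og_id], genomes, workdir
            ).items():
                out[sp].extend(hits)
        return out

    def search_orthogroup(
        self,
        og_id: str,
        nuc_msa: Mapping[str, str],
        genomes: Mapping[str, Mapping[str, str]],
        workdir=None,
    ) -> dict[str, list[HmmHit]]:
        out: dict[str, list[HmmHit]] = {sp: [] for sp in genomes}
        for sp in genomes:
            ann = self.clade.full_annotations[sp]
            members = [
                g for g in ann
                if self.clade.family_of[(sp, g.gene_id)] == og_id
            ]
            others = [
                g for g in ann
                if self.clade.family_of[(sp, g.gene_id)] != og_id
            ]
            for gene in members:
                span = gene.span
                score = float(self.good_dist.rvs(1, self.rng)[0]) * span.length
                out[sp].append(HmmHit(og_id, span, score, sp))
            for _ in range(self.n_bad_per_og):
                gene = others[int(self.rng.integers(len(others)))]
                span = gene.span
                score = float(self.bad_dist.rvs(1, self.rng)[0]) * span.length
                out[sp].append(HmmHit(og_id, span, score, sp))
            for _ in range(self.n_decoy_candidates):
                contig = next(iter(genomes[sp]))
                length = int(self.rng.integers(150, 400))
                start = int(self.rng.integers(0, len(genomes[sp][contig]) - length))
                iv = GenomicInterval(contig, start, start + length)
                score = float(self.bad_dist.rvs(1, self.rng)[0]) * length
                out[sp].append(HmmHit(og_id, iv, score, sp))
        return out
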