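"""Reading and writing genomes, annotations and alignments.

GTF input is restricted to CDS features (the only features the method uses);
coordinates are converted between GTF's 1-based inclusive convention and the
internal 0-based half-open one at this boundary and nowhere else.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, total_length

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")


class GtfParseError(ValueError):
    """A malformed GTF line; message names the offending line number."""


@dataclass
class GeneModel:
    """A strand-aware set of CDS intervals with derived sequences.

    ``cds`` intervals are sorted by start, non-overlapping, and share one
    seq_id and strand. ``coding_seq`` is the spliced, strand-corrected
    nucleotide sequence; ``protein`` its translation (terminal stop trimmed).
    """

    gene_id: str
    species: str
    cds: list[GenomicInterval]
    coding_seq: str | None = None
    protein: str | None = None
    internal_stop: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.cds:
            raise ValueError(f"gene {self.gene_id}: needs at least one CDS interval")
        seq_ids = {iv.seq_id for iv in self.cds}
        strands = {iv.strand for iv in self.cds}
        if len(seq_ids) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {self.gene_id}: CDS intervals mix seq_ids or strands"
            )
        self.cds = sorted(self.cds, key=lambda iv: iv.start)
        for a, b in zip(self.cds, self.cds[1:]):
            if b.start < a.end:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")

    @property
    def seq_id(self) -> str:
        return self.cds[0].seq_id

    @property
    def strand(self) -> str:
        return self.cds[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.seq_id, self.cds[0].start, self.cds[-1].end, self.strand
        )

    @property
    def cds_length(self) -> int:
        return total_length(self.cds)


@dataclass
class Annotation:
    """All gene models of one species, keyed by gene_id."""

    species: str
    genes: dict[str, GeneModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes.values())

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self.genes[gene.gene_id] = gene

    def subset(self, gene_ids: Iterable[str]) -> "Annotation":
        keep = set(gene_ids)
        return Annotation(
            self.species, {g: m for g, m in self.genes.items() if g in keep}
        )

    def without(self, gene_ids: Iterable[str]) -> "Annotation":
        drop = set(gene_ids)
        return Annotation(
            self.species, {g: m for g, m in self.genes.items() if g not in drop}
        )


def _parse_attributes(raw: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(raw))
    if "gene_id" not in attrs:
        raise GtfParseError(f"line {lineno}: missing gene_id attribute")
    return attrs


def parse_gtf(path: str | Path, species: str) -> Annotation:
    """Read CDS features from a GTF file into one GeneModel per gene.

    Multi-transcript genes are collapsed to the transcript with the longest
    total CDS (ties broken by transcript_id) so that each gene contributes a
    single protein. Genes whose chosen transcript mixes strands or sequences
    are skipped with a warning rather than aborting the whole file.
    """
    # (gene_id, transcript_id) -> list of intervals
    groups: dict[tuple[str, str], list[GenomicInterval]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            seq_id, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature != "CDS":
                continue
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError as exc:
                raise GtfParseError(f"line {lineno}: non-integer coordinates") from exc
            if strand not in ("+", "-"):
                raise GtfParseError(f"line {lineno}: bad strand {strand!r}")
            if end_1 < start_1:
                raise GtfParseError(f"line {lineno}: end < start")
            attrs = _parse_attributes(attrs_s, lineno)
            gene_id = attrs["gene_id"]
            transcript_id = attrs.get("transcript_id", gene_id)
            groups.setdefault((gene_id, transcript_id), []).append(
                GenomicInterval(seq_id, start_1 - 1, end_1, strand)
            )

    by_gene: dict[str, dict[str, list[GenomicInterval]]] = {}
    for (gene_id, tx_id), ivs in groups.items():
        by_gene.setdefault(gene_id, {})[tx_id] = ivs

    annotation = Annotation(species)
    for gene_id, transcripts in by_gene.items():
        # longest total CDS wins; lexicographic transcript_id breaks ties
        tx_id = max(
            sorted(transcripts), key=lambda t: total_length(transcripts[t])
        )
        try:
            gene = GeneModel(gene_id, species, list(transcripts[tx_id]))
        except ValueError as exc:
            logger.warning("skipping gene %s: %s", gene_id, exc)
            continue
        annotation.add(gene)
    return annotation


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file; IDs are the first whitespace-delimited header token."""
    seqs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seqs[record.id] = str(record.seq).upper()
    return seqs


def _splice(gene: GeneModel, genome: Mapping[str, str]) -> str:
    if gene.seq_id not in genome:
        raise KeyError(f"gene {gene.gene_id}: sequence {gene.seq_id} not in genome")
    seq = genome[gene.seq_id]
    for iv in gene.cds:
        if iv.end > len(seq):
            raise ValueError(
                f"gene {gene.gene_id}: interval [{iv.start}, {iv.end}) exceeds "
                f"length {len(seq)} of sequence {iv.seq_id}"
            )
    spliced = "".join(seq[iv.start : iv.end] for iv in gene.cds)
    if gene.strand == "-":
        spliced = str(Seq(spliced).reverse_complement())
    return spliced


def extract_sequences(
    annotation: Annotation,
    genome: Mapping[str, str],
    table_id: int = 1,
) -> Annotation:
    """Fill coding and protein sequences for every gene from the genome.

    Minus-strand genes are reverse-complemented after splicing. A coding
    length that is not a multiple of three is trimmed of its trailing bases
    with a warning (partial terminal exons are common in draft annotations).
    A terminal stop codon is trimmed from the protein; internal stops are
    translated as '*', flagged and kept — downstream filtration is score
    based, so user genes are never silently dropped here.
    """
    out = Annotation(annotation.species)
    for gene in annotation:
        coding = _splice(gene, genome)
        if len(coding) % 3:
            logger.warning(
                "gene %s: coding length %d not a multiple of 3; trimming %d trailing nt",
                gene.gene_id, len(coding), len(coding) % 3,
            )
            coding = coding[: len(coding) - len(coding) % 3]
        protein = str(Seq(coding).translate(table=table_id))
        if protein.endswith("*"):
            protein = protein[:-1]
        internal_stop = "*" in protein
        if internal_stop:
            logger.warning("gene %s: internal stop codon in translation", gene.gene_id)
        out.add(
            replace(gene, coding_seq=coding, protein=protein, internal_stop=internal_stop)
        )
    return out


def coding_without_stop(gene: GeneModel) -> str:
    """Coding sequence trimmed of its terminal stop codon, matched to the protein."""
    if gene.coding_seq is None or gene.protein is None:
        raise ValueError(f"gene {gene.gene_id}: sequences not extracted")
    expected = 3 * len(gene.protein)
    if len(gene.coding_seq) == expected:
        return gene.coding_seq
    if len(gene.coding_seq) == expected + 3:
        return gene.coding_seq[:-3]
    raise ValueError(
        f"gene {gene.gene_id}: coding length {len(gene.coding_seq)} does not match "
        f"protein length {len(gene.protein)}"
    )


def backtranslate_alignment(
    protein_msa: Mapping[str, str],
    coding_seqs: Mapping[str, str],
) -> dict[str, str]:
    """Thread nucleotide sequences back through a protein alignment.

    Each amino-acid column becomes a codon column; '-' becomes '---'.
    Ungapping any output row reproduces the input coding sequence exactly.
    """
    out: dict[str, str] = {}
    for gene_id, row in protein_msa.items():
        if gene_id not in coding_seqs:
            raise KeyError(f"no coding sequence for {gene_id}")
        coding = coding_seqs[gene_id]
        bad = set(row) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"gene {gene_id}: characters {sorted(bad)} outside amino-acid alphabet"
            )
        n_res = len(row) - row.count("-")
        if 3 * n_res != len(coding):
            raise ValueError(
                f"gene {gene_id}: {n_res} aligned residues need {3 * n_res} nt, "
                f"coding sequence has {len(coding)}"
            )
        codons = []
        pos = 0
        for aa in row:
            if aa == "-":
                codons.append("---")
            else:
                codons.append(coding[pos : pos + 3])
                pos += 3
        out[gene_id] = "".join(codons)
    return out


def _gtf_lines(gene: GeneModel, source: str) -> list[str]:
    tx_id = gene.gene_id if ".t" in gene.gene_id else f"{gene.gene_id}.t1"
    coding_order = gene.cds if gene.strand == "+" else list(reversed(gene.cds))
    lines = []
    cum = 0
    frames = {}
    for iv in coding_order:
        frames[iv] = (3 - cum % 3) % 3
        cum += iv.length
    for iv in gene.cds:
        attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}";'
        lines.append(
            "\t".join(
                [
                    iv.seq_id, source, "CDS", str(iv.start + 1), str(iv.end),
                    ".", iv.strand, str(frames[iv]), attrs,
                ]
            )
        )
    return lines


def write_gtf(
    genes: Iterable[GeneModel], path: str | Path, source: str = "cladefill"
) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            for line in _gtf_lines(gene, source):
                fh.write(line + "\n")


def write_outputs(
    new_genes: Iterable[GeneModel],
    path_gtf: str | Path,
    path_faa: str | Path,
) -> None:
    """Write novel genes as a GTF annotation and a protein FASTA."""
    genes = list(new_genes)
    write_gtf(genes, path_gtf)
    records = []
    for gene in genes:
        if gene.protein is None:
            raise ValueError(f"gene {gene.gene_id}: no protein sequence to write")
        records.append(
            SeqRecord(Seq(gene.protein), id=gene.gene_id, description="")
        )
    SeqIO.write(records, str(path_faa), "fasta")


def write_genome_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=seq_id, description="")
        for seq_id, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")
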