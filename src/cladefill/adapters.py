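"""Adapters wrapping the external tools the pipeline orchestrates.

Each adapter is a pure in/out contract so tests can substitute mocks:

* orthogroup inference  — proteomes in, OrthogroupSet out (OrthoFinder-style
  executable, or a user-supplied table upstream);
* protein MSA           — sequences in, aligned sequences out (MAFFT);
* nucleotide HMM search — per-orthogroup codon alignment in, per-species hit
  lists out (pyhmmer build + nhmmer; the standard per-target table text is
  written and re-parsed, so file contracts stay honest);
* gene prediction       — genome + hint file in, GTF gene models out
  (AUGUSTUS with extrinsic exon-part hints).
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import pyhmmer

from .genome_io import Annotation, parse_gtf, read_fasta, write_genome_fasta
from .hit_scoring import HmmHit, parse_hmm_hits
from .orthogroups import OrthogroupSet, parse_orthogroup_table


class AdapterError(RuntimeError):
    """An external tool failed or is unavailable; message carries its output."""


def _require_executable(name: str) -> str:
    path = shutil.which(name)
    if path is None:
        raise AdapterError(
            f"executable {name!r} not found on PATH; install it or register a mock"
        )
    return path


def _run(cmd: Sequence[str], **kwargs) -> subprocess.CompletedProcess:
    proc = subprocess.run(cmd, capture_output=True, text=True, **kwargs)
    if proc.returncode != 0:
        raise AdapterError(
            f"command {' '.join(cmd)} exited {proc.returncode}:\n{proc.stderr[-2000:]}"
        )
    return proc


class ProteinAligner(Protocol):
    def align(self, seqs: Mapping[str, str]) -> dict[str, str]: ...


class OrthogroupInferrer(Protocol):
    def infer(self, proteomes: Mapping[str, Mapping[str, str]]) -> OrthogroupSet: ...


class HmmEngine(Protocol):
    def search_many(
        self,
        nuc_msas: Mapping[str, Mapping[str, str]],
        genomes: Mapping[str, Mapping[str, str]],
        workdir: Path | None = None,
    ) -> dict[str, list[HmmHit]]: ...


class GenePredictor(Protocol):
    def predict(
        self, species: str, genome: Mapping[str, str], hints_path: str | Path
    ) -> Annotation: ...


class MafftAligner:
    """High-accuracy protein MSA via MAFFT (L-INS-i by default)."""

    def __init__(self, executable: str = "mafft", accurate: bool = True):
        self.executable = executable
        self.accurate = accurate

    def align(self, seqs: Mapping[str, str]) -> dict[str, str]:
        exe = _require_executable(self.executable)
        if len(seqs) == 1:
            return dict(seqs)
        with tempfile.TemporaryDirectory() as tmp:
            infile = Path(tmp) / "in.faa"
            with open(infile, "w") as fh:
                for gid in sorted(seqs):
                    fh.write(f">{gid}\n{seqs[gid]}\n")
            args = [exe]
            if self.accurate:
                args += ["--localpair", "--maxiterate", "1000"]
            args += ["--anysymbol", "--quiet", str(infile)]
            proc = _run(args)
        out: dict[str, str] = {}
        gid = None
        for line in proc.stdout.splitlines():
            if line.startswith(">"):
                gid = line[1:].split()[0]
                out[gid] = ""
            elif gid is not None:
                out[gid] += line.strip().upper()
        return out


class PyhmmerEngine:
    """Nucleotide profile-HMM build and genome search via pyhmmer.

    Builds one DNA HMM from the per-orthogroup codon alignment and runs an
    nhmmer search against every genome; the per-target hit table is written
    as text (when a workdir is given) and parsed by ``parse_hmm_hits``.
    """

    def __init__(self, cpus: int = 1):
        self.cpus = cpus
        self.alphabet = pyhmmer.easel.Alphabet.dna()
        self.background = pyhmmer.plan7.Background(self.alphabet)

    def _build_hmm(self, og_id: str, nuc_msa: Mapping[str, str]):
        seqs = [
            pyhmmer.easel.TextSequence(name=gid.encode(), sequence=row)
            for gid, row in sorted(nuc_msa.items())
        ]
        msa = pyhmmer.easel.TextMSA(name=og_id.encode(), sequences=seqs)
        builder = pyhmmer.plan7.Builder(self.alphabet)
        hmm, _, _ = builder.build_msa(msa.digitize(self.alphabet), self.background)
        return hmm

    def _collect(
        self, top_hits, og_id: str, species: str, workdir: Path | None
    ) -> list[HmmHit]:
        if workdir is not None:
            og_dir = Path(workdir) / "hits" / og_id
            og_dir.mkdir(parents=True, exist_ok=True)
            table = og_dir / f"{species}.tbl"
            with open(table, "wb") as fh:
                top_hits.write(fh, format="targets")
            return parse_hmm_hits(table, og_id, species)
        with tempfile.NamedTemporaryFile(suffix=".tbl") as tmp:
            top_hits.write(tmp, format="targets")
            tmp.flush()
            return parse_hmm_hits(tmp.name, og_id, species)

    def search_many(
        self,
        nuc_msas: Mapping[str, Mapping[str, str]],
        genomes: Mapping[str, Mapping[str, str]],
        workdir: Path | None = None,
    ) -> dict[str, list[HmmHit]]:
        """Search every orthogroup HMM against every genome.

        HMMs are built once and searched in one batched call per genome,
        which amortises the search-pipeline setup over all orthogroups.
        """
        og_ids = sorted(nuc_msas)
        hmms = [self._build_hmm(og_id, nuc_msas[og_id]) for og_id in og_ids]
        out: dict[str, list[HmmHit]] = {}
        for species, genome in genomes.items():
            targets = [
                pyhmmer.easel.TextSequence(
                    name=seq_id.encode(), sequence=seq
                ).digitize(self.alphabet)
                for seq_id, seq in genome.items()
            ]
            hits_per_query = pyhmmer.hmmer.nhmmer(hmms, targets, cpus=self.cpus)
            species_hits: list[HmmHit] = []
            for og_id, top_hits in zip(og_ids, hits_per_query):
                species_hits.extend(self._collect(top_hits, og_id, species, workdir))
            out[species] = species_hits
        return out

    def search_orthogroup(
        self,
        og_id: str,
        nuc_msa: Mapping[str, str],
        genomes: Mapping[str, Mapping[str, str]],
        workdir: Path | None = None,
    ) -> dict[str, list[HmmHit]]:
        return self.search_many({og_id: nuc_msa}, genomes, workdir)


class OrthoFinderInferrer:
    """Shell adapter for an OrthoFinder-compatible orthogroup inferrer."""

    def __init__(self, executable: str = "orthofinder", extra_args: Sequence[str] = ()):
        self.executable = executable
        self.extra_args = tuple(extra_args)

    def infer(self, proteomes: Mapping[str, Mapping[str, str]]) -> OrthogroupSet:
        exe = _require_executable(self.executable)
        with tempfile.TemporaryDirectory() as tmp:
            fastadir = Path(tmp) / "proteomes"
            fastadir.mkdir()
            for species, prots in proteomes.items():
                with open(fastadir / f"{species}.fa", "w") as fh:
                    for gid in sorted(prots):
                        fh.write(f">{gid}\n{prots[gid]}\n")
            _run([exe, "-f", str(fastadir), *self.extra_args])
            tables = sorted(fastadir.glob("OrthoFinder/*/Orthogroups/Orthogroups.tsv"))
            if not tables:
                raise AdapterError("orthogroup inferrer produced no Orthogroups.tsv")
            return parse_orthogroup_table(tables[-1])


class AugustusPredictor:
    """Shell adapter for an AUGUSTUS-compatible hint-driven gene predictor."""

    def __init__(
        self,
        species_model: str,
        executable: str = "augustus",
        extra_args: Sequence[str] = (),
    ):
        self.species_model = species_model
        self.executable = executable
        self.extra_args = tuple(extra_args)

    def predict(
        self, species: str, genome: Mapping[str, str], hints_path: str | Path
    ) -> Annotation:
        exe = _require_executable(self.executable)
        with tempfile.TemporaryDirectory() as tmp:
            genome_fa = Path(tmp) / "genome.fa"
            write_genome_fasta(genome, genome_fa)
            out_gtf = Path(tmp) / "predicted.gtf"
            proc = _run(
                [
                    exe,
                    f"--species={self.species_model}",
                    f"--hintsfile={hints_path}",
                    "--gff3=off",
                    *self.extra_args,
                    str(genome_fa),
                ]
            )
            out_gtf.write_text(proc.stdout)
            return parse_gtf(out_gtf, species)


@dataclass
class AdapterSet:
    """The four external-tool adapters the pipeline needs."""

    inferrer: OrthogroupInferrer | None
    aligner: ProteinAligner
    hmm_engine: HmmEngine
    predictor: GenePredictor
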