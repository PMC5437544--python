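"""Orthogroups: named sets of (species, gene_id) members.

An orthogroup is the set of genes descended from one ancestral gene in the
last common ancestor of the species considered; it may contain paralogues.
Genes not grouped with at least one other sequence are singletons and are
excluded from search and evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

Member = tuple[str, str]  # (species, gene_id)


@dataclass(frozen=True)
class Orthogroup:
    og_id: str
    members: frozenset[Member]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.og_id} has no members")

    def species_of(self, species: str) -> set[str]:
        return {g for s, g in self.members if s == species}

    def species_set(self) -> set[str]:
        return {s for s, _ in self.members}


@dataclass
class OrthogroupSet:
    """Partition of input genes into multi-member groups and singletons."""

    groups: dict[str, Orthogroup] = field(default_factory=dict)
    singletons: set[Member] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.groups)

    def group_of(self, species: str, gene_id: str) -> Orthogroup | None:
        key = (species, gene_id)
        for og in self.groups.values():
            if key in og.members:
                return og
        return None

    def membership_index(self) -> dict[Member, str]:
        index: dict[Member, str] = {}
        for og in self.groups.values():
            for member in og.members:
                index[member] = og.og_id
        return index

    def all_members(self) -> set[Member]:
        out = set(self.singletons)
        for og in self.groups.values():
            out |= og.members
        return out


def build_orthogroup_set(raw: Mapping[str, Iterable[Member]]) -> OrthogroupSet:
    """Assemble an OrthogroupSet, moving single-gene groups to singletons."""
    ogs = OrthogroupSet()
    seen: dict[Member, str] = {}
    for og_id, members in raw.items():
        members = frozenset(members)
        for member in members:
            if member in seen:
                raise ValueError(
                    f"gene {member[1]} ({member[0]}) appears in both "
                    f"{seen[member]} and {og_id}"
                )
            seen[member] = og_id
        if len(members) == 1:
            ogs.singletons |= members
        elif members:
            ogs.groups[og_id] = Orthogroup(og_id, members)
    return ogs


def parse_orthogroup_table(
    path: str | Path, known_species: Iterable[str] | None = None
) -> OrthogroupSet:
    """Parse a tab-separated orthogroup table (OrthoFinder-style dialect).

    Header row: group-id column then one column per species; each cell is a
    comma-separated list of gene IDs. Groups with a single gene in total are
    reclassified as singletons.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError("orthogroup table needs a group column and species columns")
        species_cols = header[1:]
        if known_species is not None:
            unknown = set(species_cols) - set(known_species)
            if unknown:
                raise ValueError(f"unknown species column(s): {sorted(unknown)}")
        raw: dict[str, list[Member]] = {}
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            cells = line.split("\t")
            og_id = cells[0]
            members: list[Member] = []
            for species, cell in zip(species_cols, cells[1:]):
                for gene_id in cell.split(","):
                    gene_id = gene_id.strip()
                    if gene_id:
                        members.append((species, gene_id))
            raw[og_id] = members
    return build_orthogroup_set(raw)


def write_orthogroup_table(
    ogs: OrthogroupSet, path: str | Path, species_order: list[str]
) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(species_order) + "\n")
        for og_id in sorted(ogs.groups):
            og = ogs.groups[og_id]
            cells = [
                ", ".join(sorted(og.species_of(species)))
                for species in species_order
            ]
            fh.write(og_id + "\t" + "\t".join(cells) + "\n")


def discoverable_genes(ogs: OrthogroupSet, species: str) -> set[str]:
    """Gene IDs of ``species`` whose orthogroup has a member from another species.

    Only such genes can, in principle, be recovered by the method; genes in
    single-species groups or singletons are excluded.
    """
    out: set[str] = set()
    for og in ogs.groups.values():
        own = og.species_of(species)
        if own and og.species_set() - {species}:
            out |= own
    return out


def orthogroup_overlap(
    og: Orthogroup, og_prime: Orthogroup, input_universe: set[Member]
) -> int:
    """|og ∩ og'| counting only genes present in the input set.

    Newly discovered genes are never counted; cardinalities refer to the
    originally annotated genes only.
    """
    return len((og.members & og_prime.members) & input_universe)
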