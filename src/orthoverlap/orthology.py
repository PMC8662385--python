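"""Orthogroup tables, single-copy restriction, and gene-set projection.

Orthogroups — sets of genes across species descended from one ancestral
gene — arrive as a tab-separated table in the OrthoFinder
``Orthogroups.tsv`` dialect: a header row ``Orthogroup<TAB>speciesA<TAB>
speciesB``, one row per orthogroup, each species cell a ``", "``-joined
gene list (empty cell = no genes in that species).

The pipeline restricts to single-copy orthogroups (exactly one gene per
species), which form a bijection between the two species' gene subsets
and hence a common universe in which gene sets from either species can
be compared. ``project`` translates a gene set into that orthogroup
space; genes not in any single-copy orthogroup are dropped from the
projection and counted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import InputFormatError, ParameterError
from .expression import GeneSet

__all__ = [
    "OrthogroupTable",
    "SingleCopyMap",
    "Projection",
    "parse_orthogroups",
    "single_copy",
    "project",
]


@dataclass
class OrthogroupTable:
    """Orthogroup -> species -> gene list relation for two (or more) species."""

    species_labels: tuple[str, ...]
    membership: dict[str, dict[str, tuple[str, ...]]]

    def __post_init__(self) -> None:
        seen: dict[tuple[str, str], str] = {}
        for og, by_species in self.membership.items():
            for sp, genes in by_species.items():
                for g in genes:
                    if not g:
                        raise InputFormatError(f"empty gene ID in orthogroup {og}")
                    key = (sp, g)
                    if key in seen:
                        raise InputFormatError(
                            f"gene {g!r} ({sp}) appears in orthogroups {seen[key]} and {og}"
                        )
                    seen[key] = og

    def __len__(self) -> int:
        return len(self.membership)

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.membership)

    def genes(self, species: str) -> list[str]:
        """All genes of one species across the table, in row order."""
        if species not in self.species_labels:
            raise ParameterError(f"unknown species {species!r}; table has {self.species_labels}")
        return [g for by_sp in self.membership.values() for g in by_sp.get(species, ())]


@dataclass
class SingleCopyMap:
    """One-gene-per-species restriction of an orthogroup table.

    ``pairs`` maps orthogroup ID -> (gene of first species, gene of
    second species); the reverse indices are bijections onto the
    orthogroup set.
    """

    species_labels: tuple[str, str]
    pairs: dict[str, tuple[str, str]]
    _gene_to_og: dict[str, dict[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._gene_to_og = {sp: {} for sp in self.species_labels}
        for og, genes in self.pairs.items():
            for sp, g in zip(self.species_labels, genes):
                if g in self._gene_to_og[sp]:
                    raise InputFormatError(f"gene {g!r} ({sp}) maps to two orthogroups")
                self._gene_to_og[sp][g] = og

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self, species: str) -> list[str]:
        idx = self._species_index(species)
        return [pair[idx] for pair in self.pairs.values()]

    def orthogroup_of(self, gene: str, species: str) -> str | None:
        self._species_index(species)
        return self._gene_to_og[species].get(gene)

    def genes_of(self, orthogroups: Iterable[str], species: str) -> list[str]:
        idx = self._species_index(species)
        return [self.pairs[og][idx] for og in orthogroups]

    def _species_index(self, species: str) -> int:
        try:
            return self.species_labels.index(species)
        except ValueError:
            raise ParameterError(
                f"unknown species {species!r}; map has {self.species_labels}"
            ) from None


@dataclass(frozen=True)
class Projection:
    """Result of projecting a gene set into single-copy orthogroup space."""

    orthogroups: frozenset[str]
    n_input: int
    n_unmapped: int

    @property
    def n_mapped(self) -> int:
        return self.n_input - self.n_unmapped


def parse_orthogroups(path: str | Path) -> OrthogroupTable:
    """Read an OrthoFinder-dialect ``Orthogroups.tsv`` file.

    Gene IDs are compared as exact strings after trimming surrounding
    whitespace. Duplicate orthogroup IDs or a gene listed in two
    orthogroups raise :class:`InputFormatError`.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise InputFormatError(f"{path}: empty orthogroups file") from None
        if len(header) < 3 or header[0].strip() != "Orthogroup":
            raise InputFormatError(
                f"{path}: malformed header {header!r}; expected "
                "'Orthogroup<TAB>species1<TAB>species2[...]'"
            )
        species = tuple(h.strip() for h in header[1:])
        membership: dict[str, dict[str, tuple[str, ...]]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            og = row[0].strip()
            if og in membership:
                raise InputFormatError(f"{path}:{lineno}: duplicate orthogroup ID {og!r}")
            cells = row[1:]
            if len(cells) < len(species):
                cells = list(cells) + [""] * (len(species) - len(cells))
            by_species: dict[str, tuple[str, ...]] = {}
            for sp, cell in zip(species, cells):
                cell = cell.strip()
                genes = tuple(g.strip() for g in cell.split(", ")) if cell else ()
                by_species[sp] = genes
            membership[og] = by_species
    return OrthogroupTable(species_labels=species, membership=membership)


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    """Write a table back to the ``Orthogroups.tsv`` dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["Orthogroup", *table.species_labels])
        for og, by_sp in table.membership.items():
            writer.writerow([og, *(", ".join(by_sp.get(sp, ())) for sp in table.species_labels)])


def single_copy(table: OrthogroupTable) -> SingleCopyMap:
    """Keep orthogroups with exactly one gene in each of the two species."""
    if len(table.species_labels) != 2:
        raise ParameterError(
            f"single-copy restriction needs exactly 2 species, got {len(table.species_labels)}"
        )
    sp1, sp2 = table.species_labels
    pairs = {
        og: (by_sp[sp1][0], by_sp[sp2][0])
        for og, by_sp in table.membership.items()
        if len(by_sp.get(sp1, ())) == 1 and len(by_sp.get(sp2, ())) == 1
    }
    return SingleCopyMap(species_labels=(sp1, sp2), pairs=pairs)


def project(gene_set: GeneSet | Iterable[str], sc_map: SingleCopyMap, species: str) -> Projection:
    """Translate a gene set into single-copy orthogroup IDs.

    Returns the orthogroups whose gene for ``species`` lies in the set.
    Genes absent from the map (multi-copy, species-specific, or simply
    unknown) are not an error: they are dropped and counted in
    ``n_unmapped``.
    """
    ids: Iterable[str] = gene_set.ids if isinstance(gene_set, GeneSet) else gene_set
    ids = set(ids)
    idx = sc_map._gene_to_og[species] if species in sc_map.species_labels else None
    if idx is None:
        raise ParameterError(f"unknown species {species!r}; map has {sc_map.species_labels}")
    hit = {idx[g] for g in ids if g in idx}
    return Projection(orthogroups=frozenset(hit), n_input=len(ids), n_unmapped=len(ids) - len(hit))


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list; ``#`` starts a comment."""
    out: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        entry = line.split("#", 1)[0].strip()
        if entry and entry not in seen:
            seen.add(entry)
            out.append(entry)
    return out
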