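"""Ortholog groups from cross-species gene links.

Groups are the connected components of the undirected gene-link graph, so a
zebrafish paralog pair sharing one mouse and one human ortholog is a single
group. Two tables are derived: table one holds the strict 1-1-1 triples
(used for cross-species PCA on a common gene space), table two additionally
keeps every group with at least one member in each species (used for
conservation accounting, where paralog expansions must count as one signal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .dataio import OrthologyLinkTable
from .errors import ContractError


@dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, list[str]]  # species -> sorted gene ids
    relationship_class: str  # "one2one_triple" | "many"

    @property
    def size(self) -> int:
        return sum(len(v) for v in self.members.values())


@dataclass
class OrthologyTables:
    """table_one: strict 1-1-1 triples; table_two: all three-species groups."""

    species: tuple[str, str, str]
    table_one: list[OrthologGroup]
    table_two: list[OrthologGroup]
    _gene_index: dict[tuple[str, str], str] = field(default_factory=dict)
    _by_id: dict[str, OrthologGroup] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for grp in self.table_two:
            self._by_id[grp.group_id] = grp
            for sp, genes in grp.members.items():
                for g in genes:
                    self._gene_index[(sp, g)] = grp.group_id

    def select(self, which: str) -> list[OrthologGroup]:
        if which == "one":
            return self.table_one
        if which == "two":
            return self.table_two
        raise ContractError(f"unknown table selector {which!r}; use 'one' or 'two'")

    def group_of(self, species: str, gene: str) -> OrthologGroup | None:
        gid = self._gene_index.get((species, gene))
        return self._by_id.get(gid) if gid is not None else None


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def build_groups(
    links: OrthologyLinkTable, species: tuple[str, str, str]
) -> list[OrthologGroup]:
    """Connected components of the gene-link graph, deterministically labelled.

    The group id derives from the lexicographically smallest (species, gene)
    member; a component is ``one2one_triple`` when it holds exactly one gene
    of each declared species and every link in it is annotated one-to-one.
    """
    declared = set(species)
    undeclared = links.species - declared
    if undeclared:
        raise ContractError(f"links reference undeclared species: {sorted(undeclared)}")

    uf = _UnionFind()
    for a, b in links.links():
        uf.union(a, b)

    nodes: dict = {}
    for node in uf.parent:
        nodes.setdefault(uf.find(node), []).append(node)

    one2one_root: dict = {}
    for row in links.table.itertuples(index=False):
        root = uf.find((row.species_a, row.gene_a))
        is_one = "one2one" in row.homology_type
        one2one_root[root] = one2one_root.get(root, True) and is_one

    groups = []
    for root, members in nodes.items():
        per_species: dict[str, list[str]] = {}
        for sp, gene in members:
            per_species.setdefault(sp, []).append(gene)
        for sp in per_species:
            per_species[sp].sort()
        smallest = min(members)
        triple = (
            set(per_species) == declared
            and all(len(v) == 1 for v in per_species.values())
            and one2one_root.get(root, False)
        )
        groups.append(
            OrthologGroup(
                group_id=f"grp:{smallest[0]}:{smallest[1]}",
                members=per_species,
                relationship_class="one2one_triple" if triple else "many",
            )
        )
    groups.sort(key=lambda g: g.group_id)
    return groups


def build_tables(
    groups: list[OrthologGroup], species: tuple[str, str, str]
) -> OrthologyTables:
    """Split groups into the strict-triple table and the all-species table."""
    declared = set(species)
    table_two = [g for g in groups if declared <= set(g.members)]
    table_one = [g for g in table_two if g.relationship_class == "one2one_triple"]
    return OrthologyTables(tuple(species), table_one, table_two)


@dataclass
class GeneSetMapping:
    """Ortholog groups hit by a gene set, with full member lists per group."""

    group_ids: set[str]
    groups: dict[str, OrthologGroup]
    unmapped: set[str]  # input genes with no group in the selected table


def map_gene_set(
    genes: set[str],
    species: str,
    tables: OrthologyTables,
    which: str = "two",
) -> GeneSetMapping:
    """Groups with at least one member of ``species`` in the input set.

    The full member lists of every hit group are returned because bracketed
    conservation counts need the orthologs of the *other* species, including
    paralogs the input set never mentions.
    """
    if species not in tables.species:
        raise ContractError(f"species {species!r} not in {tables.species}")
    selected = tables.select(which)
    hit: dict[str, OrthologGroup] = {}
    mapped_genes: set[str] = set()
    for grp in selected:
        members = set(grp.members.get(species, ()))
        inter = members & genes
        if inter:
            hit[grp.group_id] = grp
            mapped_genes |= inter
    return GeneSetMapping(set(hit), hit, genes - mapped_genes)
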