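"""Three-species conservation partition of enriched gene sets.

Conservation is scored at the ortholog-group level: a group counts as
enriched in a species as soon as *any* of its members there is enriched, so a
zebrafish paralog pair is one conserved signal. Each group touched by any
species' enriched set falls into exactly one of the seven Venn regions (the
exact set of species hitting it); enriched genes with no three-species
ortholog group fall into their species' singleton region and are labelled
"N-orth". Region counts follow the published convention: a primary count of
anchor-species genes plus bracketed totals of the other species' orthologous
genes in the same groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ContractError
from .orthology import OrthologGroup, OrthologyTables, map_gene_set

#: single-letter species codes and the label order of the study's tables
SPECIES_CODES = {"zebrafish": "Z", "human": "H", "mouse": "M"}
CODE_ORDER = ("Z", "H", "M")


def region_label(species: frozenset, codes: dict[str, str] | None = None) -> str:
    """Canonical label of a region, e.g. {zebrafish, human, mouse} -> "ZHM"."""
    codes = codes or SPECIES_CODES
    present = {codes.get(sp, sp[0].upper()) for sp in species}
    ordered = [c for c in CODE_ORDER if c in present]
    ordered += sorted(present - set(CODE_ORDER))
    return "".join(ordered)


@dataclass
class RegionSummary:
    species: frozenset
    group_ids: set[str] = field(default_factory=set)
    #: per species in the region: enriched genes of that species in the
    #: region's groups (the primary, non-bracketed count)
    enriched_genes: dict[str, set[str]] = field(default_factory=dict)
    #: per species in the region: all orthologous genes in the region's
    #: groups, enriched or not (the bracketed count)
    ortholog_genes: dict[str, set[str]] = field(default_factory=dict)
    #: enriched genes with no ortholog group (singleton regions only)
    unlinked_genes: dict[str, set[str]] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return region_label(self.species)

    @property
    def anchor(self) -> str:
        """Zebrafish where it participates, else alphabetically first."""
        return "zebrafish" if "zebrafish" in self.species else min(self.species)

    @property
    def primary_count(self) -> int:
        anchor = self.anchor
        return len(self.enriched_genes.get(anchor, set())) + len(
            self.unlinked_genes.get(anchor, set())
        )

    def bracket_counts(self) -> dict[str, int]:
        """Total orthologous genes of each non-anchor species in the region."""
        return {
            sp: len(genes)
            for sp, genes in sorted(self.ortholog_genes.items())
            if sp != self.anchor
        }


@dataclass
class ConservationPartition:
    regions: dict[frozenset, RegionSummary]
    enriched: dict[str, set[str]]
    tables: OrthologyTables

    def region_of_group(self, group_id: str) -> frozenset | None:
        for sps, summary in self.regions.items():
            if group_id in summary.group_ids:
                return sps
        return None

    def group_counts(self) -> dict[str, int]:
        """Number of ortholog groups per region label (unlinked genes excluded)."""
        return {s.label: len(s.group_ids) for s in self.regions.values()}

    def summary_table(self) -> pd.DataFrame:
        """One row per region: label, group/primary/bracket counts."""
        rows = []
        for summary in self.regions.values():
            brackets = summary.bracket_counts()
            rows.append(
                {
                    "region": summary.label,
                    "n_groups": len(summary.group_ids),
                    "anchor_species": summary.anchor,
                    "primary_count": summary.primary_count,
                    "bracket_counts": ";".join(
                        f"{SPECIES_CODES.get(sp, sp)}={n}" for sp, n in brackets.items()
                    ),
                }
            )
        return pd.DataFrame(
            rows, columns=["region", "n_groups", "anchor_species", "primary_count", "bracket_counts"]
        ).sort_values("region", ignore_index=True)


def partition_conserved(
    enriched: dict[str, set[str]], tables: OrthologyTables
) -> ConservationPartition:
    """Partition enriched gene sets into the seven conservation regions.

    ``enriched`` maps each of the three species to its enriched gene set;
    mapping onto groups uses orthology table two. A group's region is the
    exact set of species whose enriched set contains at least one of its
    members there; enriched genes outside any table-two group land in their
    species' singleton region as unlinked genes.
    """
    unknown = set(enriched) - set(tables.species)
    if unknown:
        raise ContractError(f"species {sorted(unknown)} not in orthology tables {tables.species}")

    mappings = {
        sp: map_gene_set(genes, sp, tables, which="two") for sp, genes in enriched.items()
    }
    group_hits: dict[str, set[str]] = {}
    group_obj: dict[str, OrthologGroup] = {}
    for sp, mapping in mappings.items():
        for gid, grp in mapping.groups.items():
            group_hits.setdefault(gid, set()).add(sp)
            group_obj[gid] = grp

    regions: dict[frozenset, RegionSummary] = {}

    def get_region(sps: frozenset) -> RegionSummary:
        if sps not in regions:
            regions[sps] = RegionSummary(species=sps)
        return regions[sps]

    for gid, sps in group_hits.items():
        summary = get_region(frozenset(sps))
        summary.group_ids.add(gid)
        grp = group_obj[gid]
        for sp in sps:
            members = set(grp.members.get(sp, ()))
            summary.enriched_genes.setdefault(sp, set()).update(members & enriched[sp])
            summary.ortholog_genes.setdefault(sp, set()).update(members)
        # bracketed counts also cover region species' full membership; species
        # outside the region do not appear in the region's accounting
    for sp, mapping in mappings.items():
        if mapping.unmapped:
            summary = get_region(frozenset({sp}))
            summary.unlinked_genes.setdefault(sp, set()).update(mapping.unmapped)

    return ConservationPartition(regions=regions, enriched=dict(enriched), tables=tables)


def label_genes(partition: ConservationPartition, anchor_species: str) -> pd.DataFrame:
    """Per-gene conservation labels for one species' enriched genes.

    Linked genes inherit their group's region label ("ZHM", "ZM", ...,
    "Z"); enriched genes without a three-species ortholog group are labelled
    "N-orth". Sorted by gene_id.
    """
    if anchor_species not in partition.tables.species:
        raise ContractError(f"unknown anchor species {anchor_species!r}")
    rows = []
    for summary in partition.regions.values():
        for gene in summary.enriched_genes.get(anchor_species, ()):
            rows.append((gene, summary.label))
        for gene in summary.unlinked_genes.get(anchor_species, ()):
            rows.append((gene, "N-orth"))
    return pd.DataFrame(rows, columns=["gene_id", "conservation"]).sort_values(
        "gene_id", ignore_index=True
    )


def conserved_subtype_signature(
    subtype_enriched: dict[str, dict[str, set[str]]],
    tables: OrthologyTables,
) -> dict[str, ConservationPartition]:
    """Conservation partitions of alpha- and beta-enriched sets, independently.

    ``subtype_enriched`` maps subtype -> species -> enriched gene set (from
    identical per-species alpha-versus-beta contrasts).
    """
    return {
        subtype: partition_conserved(per_species, tables)
        for subtype, per_species in subtype_enriched.items()
    }


def conserved_gene_table(
    partition: ConservationPartition,
    log2fc: dict[str, pd.Series],
    region: frozenset | None = None,
) -> pd.DataFrame:
    """Fully conserved genes with per-species log2 fold changes.

    One row per (group, member-gene combination is avoided): for each group of
    the selected region (default: the all-species region), the enriched genes
    of each species are listed with the log2 fold change of the supporting
    contrast, in the layout of published conserved-signature tables.
    """
    region = region or frozenset(partition.tables.species)
    summary = partition.regions.get(region)
    rows = []
    if summary is not None:
        for gid in sorted(summary.group_ids):
            grp = partition.tables._by_id[gid]
            row: dict[str, object] = {"group_id": gid}
            for sp in sorted(partition.tables.species):
                genes = sorted(set(grp.members.get(sp, ())) & partition.enriched.get(sp, set()))
                row[f"{sp}_genes"] = ";".join(genes)
                fcs = [log2fc[sp].get(g) for g in genes if sp in log2fc]
                row[f"{sp}_log2fc"] = ";".join(
                    f"{v:.2f}" for v in fcs if v is not None and pd.notna(v)
                )
            rows.append(row)
    cols = ["group_id"] + [
        f"{sp}_{suffix}" for sp in sorted(partition.tables.species) for suffix in ("genes", "log2fc")
    ]
    return pd.DataFrame(rows, columns=cols)
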