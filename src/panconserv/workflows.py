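"""End-to-end analysis flows shared by the CLI, the examples and the tests.

The comparison runs the same selection rule in every species (fold > 4,
BH-adjusted p < 0.05 by default) but the endocrine/exocrine proxy differs by
what can be sorted: zebrafish contrasts in-silico pooled endocrine libraries
(alpha+beta+delta) against acinar and duct in a three-tissue Venn, while
mouse and human contrast purified islets against whole pancreas. Subtype
signatures always come from direct alpha-versus-beta contrasts on the
purified libraries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import signatures
from .conservation import ConservationPartition, partition_conserved
from .dataio import CountMatrix, OrthologyLinkTable, ThresholdConfig
from .de import (
    DispersionEstimates,
    estimate_dispersions,
    estimate_size_factors,
    pool_insilico,
    standard_endocrine_recipe,
    wald_test,
)
from .errors import ContractError
from .multivariate import PCAResult, cross_species_pca, vst
from .orthology import OrthologyTables, build_groups, build_tables

ENDOCRINE_COMPARTMENT = {"endocrine", "islet", "alpha", "beta", "delta"}
EXOCRINE_COMPARTMENT = {"acinar", "duct", "pancreas"}


def compartment_of(cell_type: str) -> str:
    if cell_type in ENDOCRINE_COMPARTMENT:
        return "endocrine"
    if cell_type in EXOCRINE_COMPARTMENT:
        return "exocrine"
    return "other"


@dataclass
class SpeciesAnalysis:
    """Per-species enrichment calls and the intermediates behind them."""

    species: str
    size_factors: pd.Series
    dispersions: DispersionEstimates
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    tissue_calls: pd.DataFrame | None = None
    subtype_calls: pd.DataFrame | None = None
    endocrine: set[str] = field(default_factory=set)
    exocrine: set[str] = field(default_factory=set)
    alpha: set[str] = field(default_factory=set)
    beta: set[str] = field(default_factory=set)
    vst_matrix: pd.DataFrame | None = None
    vst_samples: pd.DataFrame | None = None
    embryo_overlap: tuple[int, float] | None = None


def _two_sided_sets(de: pd.DataFrame, cfg: ThresholdConfig) -> tuple[set[str], set[str]]:
    """(up-in-A, up-in-B) gene sets at the fold/significance rule."""
    sig = de["p_adj"] < cfg.alpha_adj
    up = de.loc[sig & (de["log2fc"] > cfg.log2fc_threshold), "gene_id"]
    down = de.loc[sig & (de["log2fc"] < -cfg.log2fc_threshold), "gene_id"]
    return set(up), set(down)


def analyze_zebrafish(
    cm: CountMatrix,
    cfg: ThresholdConfig | None = None,
    subtypes: tuple[str, ...] = ("alpha", "beta", "delta"),
    exocrine_tissues: tuple[str, ...] = ("acinar", "duct"),
) -> SpeciesAnalysis:
    """Tissue Venn on pooled endocrine vs acinar vs duct, plus subtype calls.

    Endocrine libraries are built in silico by summing same-numbered
    replicates of the sorted subtypes; the endocrine signature is the
    singleton {endocrine} Venn region and the exocrine signature is every
    gene whose region lies within the exocrine tissues. Embryonic-stage
    samples are excluded from all contrasts; when present, the overlap of the
    adult endocrine signature with genes expressed in the embryonic sample is
    reported.
    """
    cfg = cfg or ThresholdConfig()
    species = cm.samples["species"].iloc[0]
    adult_ids = [s for s in cm.sample_ids if cm.samples.at[s, "stage"] == "adult"]
    adult = cm.subset_samples(adult_ids)

    pooled = pool_insilico(adult, standard_endocrine_recipe(adult, subtypes=subtypes))
    sf_pool = estimate_size_factors(pooled)
    disp_pool = estimate_dispersions(pooled, sf_pool)
    tissues = ["endocrine", *exocrine_tissues]
    groups = pooled.group_samples("cell_type")
    missing = [t for t in tissues if t not in groups]
    if missing:
        raise ContractError(f"zebrafish design lacks tissues {missing}")
    de_tables: dict[str, pd.DataFrame] = {}
    pair_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for i, t in enumerate(tissues):
        for u in tissues[i + 1 :]:
            table = wald_test(pooled, sf_pool, disp_pool, (groups[t], groups[u]), cfg)
            de_tables[f"{t}_vs_{u}"] = table
            pair_tables[(t, u)] = table
    calls = signatures.call_tissue_enriched(pair_tables, tissues, cfg)

    result = SpeciesAnalysis(
        species=species,
        size_factors=sf_pool,
        dispersions=disp_pool,
        de_tables=de_tables,
        tissue_calls=calls,
        endocrine=signatures.enriched_set(calls, "endocrine"),
        exocrine=signatures.region_subset(calls, set(exocrine_tissues)),
        vst_matrix=vst(pooled, sf_pool, disp_pool),
        vst_samples=pooled.samples,
    )

    # subtype contrasts on the unpooled adult matrix
    sf = estimate_size_factors(adult)
    disp = estimate_dispersions(adult, sf)
    sub_groups = adult.group_samples("cell_type")
    sub_pairs: dict[tuple[str, str], pd.DataFrame] = {}
    for i, t in enumerate(subtypes):
        for u in subtypes[i + 1 :]:
            table = wald_test(adult, sf, disp, (sub_groups[t], sub_groups[u]), cfg)
            de_tables[f"{t}_vs_{u}"] = table
            sub_pairs[(t, u)] = table
    result.alpha, result.beta = _two_sided_sets(de_tables["alpha_vs_beta"], cfg)
    result.subtype_calls = signatures.call_subtype_venn(
        result.endocrine, sub_pairs, list(subtypes), cfg
    )

    embryonic_ids = [s for s in cm.sample_ids if cm.samples.at[s, "stage"] == "embryonic"]
    if embryonic_ids:
        sf_all = estimate_size_factors(cm)
        embryo = cm.subset_samples(embryonic_ids)
        expressed = signatures.expressed_genes(embryo, sf_all.loc[embryonic_ids], cfg)
        result.embryo_overlap = signatures.overlap_fraction(result.endocrine, expressed)
    return result


def analyze_mammal(
    cm: CountMatrix,
    cfg: ThresholdConfig | None = None,
    endocrine_tissue: str = "islet",
    exocrine_tissue: str = "pancreas",
) -> SpeciesAnalysis:
    """Islet-versus-pancreas endocrine/exocrine calls plus alpha/beta calls."""
    cfg = cfg or ThresholdConfig()
    species = cm.samples["species"].iloc[0]
    adult_ids = [s for s in cm.sample_ids if cm.samples.at[s, "stage"] == "adult"]
    adult = cm.subset_samples(adult_ids)
    sf = estimate_size_factors(adult)
    disp = estimate_dispersions(adult, sf)
    groups = adult.group_samples("cell_type")
    for t in (endocrine_tissue, exocrine_tissue):
        if t not in groups:
            raise ContractError(f"{species} design lacks tissue {t!r}")
    de_tables = {
        "islet_vs_pancreas": wald_test(
            adult, sf, disp, (groups[endocrine_tissue], groups[exocrine_tissue]), cfg
        )
    }
    endocrine, exocrine = _two_sided_sets(de_tables["islet_vs_pancreas"], cfg)
    result = SpeciesAnalysis(
        species=species,
        size_factors=sf,
        dispersions=disp,
        de_tables=de_tables,
        endocrine=endocrine,
        exocrine=exocrine,
        vst_matrix=vst(adult, sf, disp),
        vst_samples=adult.samples,
    )
    if "alpha" in groups and "beta" in groups:
        de_tables["alpha_vs_beta"] = wald_test(
            adult, sf, disp, (groups["alpha"], groups["beta"]), cfg
        )
        result.alpha, result.beta = _two_sided_sets(de_tables["alpha_vs_beta"], cfg)
    return result


def analyze_species(cm: CountMatrix, cfg: ThresholdConfig | None = None) -> SpeciesAnalysis:
    """Dispatch on the library design found in the sample metadata."""
    cell_types = set(cm.samples["cell_type"])
    if {"islet", "pancreas"} <= cell_types:
        return analyze_mammal(cm, cfg)
    if {"alpha", "beta", "delta"} <= cell_types:
        return analyze_zebrafish(cm, cfg)
    raise ContractError(
        f"cannot infer a design from cell types {sorted(cell_types)}; "
        "expected islet/pancreas or alpha/beta/delta libraries"
    )


@dataclass
class FullAnalysis:
    """Everything the three-species comparison produces."""

    per_species: dict[str, SpeciesAnalysis]
    tables: OrthologyTables
    endocrine_partition: ConservationPartition
    exocrine_partition: ConservationPartition
    alpha_partition: ConservationPartition
    beta_partition: ConservationPartition
    pca: PCAResult | None

    def alpha_beta_log2fc(self, orient: str = "alpha") -> dict[str, pd.Series]:
        """Per-species subtype log2 fold changes, gene-indexed.

        ``orient="alpha"`` gives alpha-over-beta; ``orient="beta"`` negates,
        so conserved-signature tables show positive values for the cell type
        they describe.
        """
        sign = 1.0 if orient == "alpha" else -1.0
        out = {}
        for sp, ana in self.per_species.items():
            table = ana.de_tables.get("alpha_vs_beta")
            if table is not None:
                out[sp] = sign * table.set_index("gene_id")["log2fc"]
        return out


def analyze_dataset(
    counts: dict[str, CountMatrix],
    links: OrthologyLinkTable,
    cfg: ThresholdConfig | None = None,
    run_pca: bool = True,
) -> FullAnalysis:
    """Per-species enrichment, orthology grouping, conservation and joint PCA."""
    cfg = cfg or ThresholdConfig()
    species = tuple(counts)
    if len(species) != 3:
        raise ContractError(f"expected three species, got {species}")
    per_species = {sp: analyze_species(cm, cfg) for sp, cm in counts.items()}
    tables = build_tables(build_groups(links, species), species)

    def sets(attr: str) -> dict[str, set[str]]:
        return {sp: getattr(ana, attr) for sp, ana in per_species.items()}

    endocrine = partition_conserved(sets("endocrine"), tables)
    exocrine = partition_conserved(sets("exocrine"), tables)
    alpha = partition_conserved(sets("alpha"), tables)
    beta = partition_conserved(sets("beta"), tables)

    pca_result = None
    if run_pca:
        pca_result = cross_species_pca(
            {sp: ana.vst_matrix for sp, ana in per_species.items()}, tables
        )
    return FullAnalysis(
        per_species=per_species,
        tables=tables,
        endocrine_partition=endocrine,
        exocrine_partition=exocrine,
        alpha_partition=alpha,
        beta_partition=beta,
        pca=pca_result,
    )


def pca_sample_labels(analysis: FullAnalysis) -> pd.DataFrame:
    """Species and compartment labels for the joint-PCA samples.

    The joint PCA columns are the samples behind each species' VST matrix
    (for zebrafish that includes the pooled in-silico endocrine libraries),
    so labels come straight from the stored metadata.
    """
    meta = pd.concat(
        [ana.vst_samples for ana in analysis.per_species.values() if ana.vst_samples is not None]
    )
    if analysis.pca is not None:
        meta = meta.loc[analysis.pca.coordinates.index]
    meta = meta.copy()
    meta["compartment"] = meta["cell_type"].map(compartment_of)
    return meta[["species", "cell_type", "compartment"]]
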