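"""Three-species synthetic count data with planted, orthology-aware markers.

The generator emulates the structure of a FACS-sorted pancreatic cell-type
study: zebrafish alpha/beta/delta/acinar/duct libraries plus one embryonic
endocrine sample, mouse and human islet versus whole-pancreas libraries and
purified alpha/beta preparations. Ortholog groups link the species (a stated
fraction strictly 1-1-1, the rest with zebrafish paralog expansions), and
marker patterns are planted *on groups*, so conserved enrichment is shared
across species exactly the way orthology-aware conservation accounting
expects to find it.

Counts are negative binomial with ``Var = mu + alpha * mu^2``; per-sample
sequencing depth is a multiplicative factor on the mean (log-uniform within
``libsize_range``), which keeps the NB form exact. Species-level expression
divergence of orthologs is modelled as a per-gene, per-species log2 baseline
offset; it cancels from every within-species contrast and only shapes the
cross-species covariance structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd

from .dataio import CountMatrix, OrthologyLinkTable
from .errors import ContractError, ValidationError

SPECIES = ("zebrafish", "mouse", "human")

#: concrete cell types belonging to each species' endocrine / exocrine
#: compartment (islets are the mammalian endocrine proxy; whole pancreas,
#: being >90% exocrine, is the exocrine proxy)
ENDOCRINE_TYPES = {
    "zebrafish": ("alpha", "beta", "delta", "endocrine"),
    "mouse": ("islet", "alpha", "beta"),
    "human": ("islet", "alpha", "beta"),
}
EXOCRINE_TYPES = {
    "zebrafish": ("acinar", "duct"),
    "mouse": ("pancreas",),
    "human": ("pancreas",),
}

ZEBRAFISH_SUBTYPES = ("alpha", "beta", "delta")

MARKER_CLASSES = (
    "conserved_endocrine",
    "conserved_exocrine",
    "conserved_alpha",
    "conserved_beta",
    "species_specific",
)

#: default per-species library design: (cell_type, n_replicates, stage),
#: mirroring the sample inventory of the study this generator emulates
DEFAULT_CELL_DESIGN = {
    "zebrafish": [
        ("alpha", 3, "adult"),
        ("beta", 3, "adult"),
        ("delta", 3, "adult"),
        ("acinar", 4, "adult"),
        ("duct", 3, "adult"),
        ("endocrine", 1, "embryonic"),
    ],
    "mouse": [
        ("islet", 3, "adult"),
        ("pancreas", 2, "adult"),
        ("alpha", 2, "adult"),
        ("beta", 2, "adult"),
    ],
    "human": [
        ("islet", 7, "adult"),
        ("pancreas", 5, "adult"),
        ("alpha", 6, "adult"),
        ("beta", 6, "adult"),
    ],
}


@dataclass(frozen=True)
class PlantedMarker:
    """One planted marker pattern occupying ``n_groups`` ortholog groups.

    ``marker_class`` fixes which compartment is elevated; for
    ``species_specific`` the ``cell_type`` names the elevated compartment
    ("endocrine"/"exocrine") or a single concrete cell type, and
    ``target_species`` must name exactly one species.
    """

    marker_class: str
    target_species: tuple[str, ...]
    log2_effect: float = 4.0
    cell_type: str | None = None
    n_groups: int = 1

    def __post_init__(self) -> None:
        if self.marker_class not in MARKER_CLASSES:
            raise ValidationError(f"unknown marker class {self.marker_class!r}")
        if not self.target_species:
            raise ValidationError("planted marker needs at least one target species")
        if self.marker_class == "species_specific":
            if len(self.target_species) != 1:
                raise ValidationError("species_specific markers target exactly one species")
            if not self.cell_type:
                raise ValidationError("species_specific markers need a cell_type")
        if not np.isfinite(self.log2_effect):
            raise ValidationError("log2_effect must be finite")
        if self.n_groups < 1:
            raise ValidationError("n_groups must be >= 1")

    def elevated_types(self, species: str) -> tuple[str, ...]:
        """Concrete cell types elevated in ``species`` (empty if untargeted)."""
        if species not in self.target_species:
            return ()
        if self.marker_class == "conserved_endocrine":
            return ENDOCRINE_TYPES[species]
        if self.marker_class == "conserved_exocrine":
            return EXOCRINE_TYPES[species]
        if self.marker_class == "conserved_alpha":
            return ("alpha",)
        if self.marker_class == "conserved_beta":
            return ("beta",)
        if self.cell_type == "endocrine" and species != "zebrafish":
            return ENDOCRINE_TYPES[species]
        if self.cell_type == "endocrine":
            return ENDOCRINE_TYPES["zebrafish"]
        if self.cell_type == "exocrine":
            return EXOCRINE_TYPES[species]
        return (self.cell_type,)

    @property
    def compartment(self) -> str:
        if self.marker_class == "conserved_endocrine":
            return "endocrine"
        if self.marker_class == "conserved_exocrine":
            return "exocrine"
        if self.marker_class == "conserved_alpha":
            return "alpha"
        if self.marker_class == "conserved_beta":
            return "beta"
        return self.cell_type or "unknown"


def default_planted_design(log2_effect: float = 4.0) -> list[PlantedMarker]:
    """Endocrine and exocrine conservation patterns across the 7 Venn regions.

    Counts are modest fractions of the default 500 groups, proportioned like
    the published endocrine signature (a conserved core, two-species overlaps
    and a species-specific majority is the qualitative pattern emulated).
    """
    z, m, h = SPECIES
    e = log2_effect
    return [
        PlantedMarker("conserved_endocrine", (z, m, h), e, n_groups=25),
        PlantedMarker("conserved_endocrine", (z, m), e, n_groups=10),
        PlantedMarker("conserved_endocrine", (z, h), e, n_groups=10),
        PlantedMarker("conserved_endocrine", (m, h), e, n_groups=8),
        PlantedMarker("species_specific", (z,), e, cell_type="endocrine", n_groups=12),
        PlantedMarker("species_specific", (m,), e, cell_type="endocrine", n_groups=8),
        PlantedMarker("species_specific", (h,), e, cell_type="endocrine", n_groups=8),
        PlantedMarker("conserved_exocrine", (z, m, h), e, n_groups=15),
        PlantedMarker("conserved_exocrine", (z, m), e, n_groups=5),
        PlantedMarker("conserved_exocrine", (z, h), e, n_groups=5),
        PlantedMarker("conserved_exocrine", (m, h), e, n_groups=4),
        PlantedMarker("species_specific", (z,), e, cell_type="exocrine", n_groups=8),
        PlantedMarker("species_specific", (m,), e, cell_type="exocrine", n_groups=5),
        PlantedMarker("species_specific", (h,), e, cell_type="exocrine", n_groups=5),
    ]


def subtype_planted_design(log2_effect: float = 4.0,
                           n_alpha: int = 5, n_beta: int = 2) -> list[PlantedMarker]:
    """Conserved alpha- and beta-cell marker groups (all three species)."""
    return [
        PlantedMarker("conserved_alpha", SPECIES, log2_effect, n_groups=n_alpha),
        PlantedMarker("conserved_beta", SPECIES, log2_effect, n_groups=n_beta),
    ]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic three-species dataset."""

    n_groups: int = 500
    frac_one2one: float = 0.8
    max_paralogs: int = 2
    cell_design: dict = field(default_factory=lambda: {
        sp: list(rows) for sp, rows in DEFAULT_CELL_DESIGN.items()
    })
    planted: tuple[PlantedMarker, ...] = field(
        default_factory=lambda: tuple(default_planted_design())
    )
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.5, 2.0)
    species_effect_sd: float = 0.7
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups == 0:
            raise ContractError("empty design: n_groups must be positive")
        if not 0 <= self.frac_one2one <= 1:
            raise ValidationError("frac_one2one must lie in [0, 1]")
        if self.max_paralogs < 1:
            raise ValidationError("max_paralogs must be >= 1")
        if self.max_paralogs == 1 and self.frac_one2one < 1:
            raise ValidationError("max_paralogs=1 forbids non-1-1-1 groups")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be positive")
        lo, hi = self.libsize_range
        if not (0 < lo <= hi):
            raise ValidationError("libsize_range bounds must be positive and ordered")
        if self.species_effect_sd < 0:
            raise ValidationError("species_effect_sd must be >= 0")
        n_planted = sum(p.n_groups for p in self.planted)
        if n_planted > self.n_groups:
            raise ValidationError(
                f"{n_planted} planted groups exceed n_groups={self.n_groups}"
            )

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.cell_design)

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, rng_seed=seed)


TRUTH_COLUMNS = [
    "species", "gene_id", "group_id", "marker_class",
    "cell_type", "log2_effect", "elevated_cell_types",
]


def _venn_region(factors: dict[str, float], fold_threshold: float) -> frozenset:
    """Region of the mutually-exclusive Venn rule on noise-free fold factors."""
    tissues = list(factors)
    # the full tissue set is excluded: a region needs an outside tissue to beat
    for size in range(len(tissues) - 1, 0, -1):
        for combo in combinations(tissues, size):
            inside = set(combo)
            ok = all(
                factors[t] / factors[u] > fold_threshold
                for t in inside
                for u in tissues
                if u not in inside
            ) and all(
                factors[t] / factors[u] <= fold_threshold
                for t in inside
                for u in inside
                if t != u
            )
            if ok:
                return frozenset(inside)
    return frozenset()


@dataclass
class GroundTruth:
    """Per-gene planted-marker records plus design-level expectations.

    ``table`` has one row per generated gene: species, gene_id, group_id,
    marker_class (or "background"), the compartment label, the planted log2
    effect and the concrete elevated cell types. The ``expected_*`` helpers
    turn the planted design into the enrichment sets and conservation regions
    a perfect caller would recover; they are purely combinatorial (no counts
    involved), which is what makes recovery testing non-circular.
    """

    table: pd.DataFrame

    def genes(self, species: str) -> list[str]:
        return list(self.table.loc[self.table["species"] == species, "gene_id"])

    def expected_enriched_genes(
        self,
        species: str,
        compartment: str,
        fold_threshold: float = 4.0,
    ) -> set[str]:
        """Genes of ``species`` a perfect caller would call ``compartment``-enriched.

        For zebrafish the endocrine side is the in-silico pool of the three
        subtypes, so a subtype-restricted marker dilutes to ``(2^e + 2) / 3``
        fold; mammalian endocrine/exocrine calls contrast islet with whole
        pancreas; alpha/beta calls contrast the purified subtype libraries.
        """
        out: set[str] = set()
        sub = self.table[self.table["species"] == species]
        for row in sub.itertuples(index=False):
            elevated = set(row.elevated_cell_types.split(",")) if row.elevated_cell_types else set()
            eff = 2.0 ** row.log2_effect if elevated else 1.0

            def f(ct: str) -> float:
                return eff if ct in elevated else 1.0

            if compartment in ("alpha", "beta"):
                num, den = (("alpha", "beta") if compartment == "alpha" else ("beta", "alpha"))
                if f(num) / f(den) > fold_threshold:
                    out.add(row.gene_id)
                continue
            if species == "zebrafish":
                pooled = float(np.mean([f(t) for t in ZEBRAFISH_SUBTYPES]))
                region = _venn_region(
                    {"endocrine": pooled, "acinar": f("acinar"), "duct": f("duct")},
                    fold_threshold,
                )
                hit = (
                    region == {"endocrine"}
                    if compartment == "endocrine"
                    else bool(region) and region <= {"acinar", "duct"}
                )
            else:
                ratio = f("islet") / f("pancreas")
                hit = ratio > fold_threshold if compartment == "endocrine" else 1 / ratio > fold_threshold
            if hit:
                out.add(row.gene_id)
        return out

    def expected_regions(
        self, compartment: str, fold_threshold: float = 4.0
    ) -> dict[frozenset, set[str]]:
        """Ortholog groups keyed by their expected conservation region."""
        regions: dict[frozenset, set[str]] = {}
        enriched = {
            sp: self.expected_enriched_genes(sp, compartment, fold_threshold)
            for sp in self.table["species"].unique()
        }
        gene_group = dict(zip(self.table["gene_id"], self.table["group_id"]))
        hit_species: dict[str, set[str]] = {}
        for sp, genes in enriched.items():
            for g in genes:
                hit_species.setdefault(gene_group[g], set()).add(sp)
        for group_id, sps in hit_species.items():
            regions.setdefault(frozenset(sps), set()).add(group_id)
        return regions


def generate_orthology(config: SyntheticConfig) -> tuple[OrthologyLinkTable, GroundTruth]:
    """Build the ortholog-group skeleton: links, gene ids, marker assignment.

    Exactly ``round(frac_one2one * n_groups)`` groups are strict 1-1-1; every
    other group carries 2..max_paralogs zebrafish paralogs of a single
    mouse/human gene pair. Planted marker patterns are assigned to groups by
    the seeded RNG; counts and realized effects are drawn later by
    :func:`generate_counts`.
    """
    rng = np.random.default_rng([config.rng_seed, 0])
    n_one = round(config.frac_one2one * config.n_groups)
    n_paralog_genes = (
        rng.integers(2, config.max_paralogs + 1, size=config.n_groups - n_one)
        if config.n_groups > n_one
        else np.array([], dtype=int)
    )

    # planted patterns occupy a random subset of groups, one pattern per group
    assignment: dict[int, PlantedMarker] = {}
    planted_group_ids = rng.choice(
        config.n_groups, size=sum(p.n_groups for p in config.planted), replace=False
    )
    cursor = 0
    for marker in config.planted:
        for gid in planted_group_ids[cursor : cursor + marker.n_groups]:
            assignment[int(gid)] = marker
        cursor += marker.n_groups

    links = []
    truth_rows = []
    for gi in range(config.n_groups):
        group_id = f"og{gi:05d}"
        n_zf = 1 if gi < n_one else int(n_paralog_genes[gi - n_one])
        zf_genes = (
            [f"zf_g{gi:05d}"]
            if n_zf == 1
            else [f"zf_g{gi:05d}{chr(ord('a') + k)}" for k in range(n_zf)]
        )
        mm_gene, hs_gene = f"mm_g{gi:05d}", f"hs_g{gi:05d}"
        homology = "ortholog_one2one" if n_zf == 1 else "ortholog_one2many"
        for zf in zf_genes:
            links.append(("zebrafish", zf, "mouse", mm_gene, homology))
            links.append(("zebrafish", zf, "human", hs_gene, homology))
        links.append(("mouse", mm_gene, "human", hs_gene, "ortholog_one2one"))

        marker = assignment.get(gi)
        for sp, genes in (("zebrafish", zf_genes), ("mouse", [mm_gene]), ("human", [hs_gene])):
            for g in genes:
                if marker is not None and sp in marker.target_species:
                    elevated = ",".join(marker.elevated_types(sp))
                    truth_rows.append(
                        (sp, g, group_id, marker.marker_class, marker.compartment,
                         marker.log2_effect, elevated)
                    )
                else:
                    truth_rows.append((sp, g, group_id, "background", "", 0.0, ""))

    link_table = OrthologyLinkTable(
        pd.DataFrame(links, columns=["species_a", "gene_a", "species_b", "gene_b", "homology_type"])
    )
    truth = GroundTruth(pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS))
    return link_table, truth


def generate_counts(
    config: SyntheticConfig, truth: GroundTruth
) -> tuple[dict[str, CountMatrix], GroundTruth]:
    """Draw NB counts for every species given the marker skeleton.

    Per gene g in sample j of species s the mean is ``baseline_mean *
    2^(species offset) * 2^(log2_effect if j's cell type is elevated for g) *
    depth_j`` and the count is NB with dispersion ``config.dispersion``.
    Bit-identical for a fixed seed and config.
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    alpha = config.dispersion
    lo, hi = config.libsize_range
    matrices: dict[str, CountMatrix] = {}
    for sp in config.species:
        sub = truth.table[truth.table["species"] == sp]
        genes = list(sub["gene_id"])
        design = config.cell_design[sp]
        sample_ids, meta_rows = [], []
        for cell_type, n_rep, stage in design:
            for rep in range(1, n_rep + 1):
                suffix = "_emb_" if stage == "embryonic" else "_"
                sid = f"{sp}{suffix}{cell_type}{rep}"
                sample_ids.append(sid)
                meta_rows.append((sid, sp, cell_type, rep, stage))
        depths = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(sample_ids)))
        offsets = rng.normal(0.0, config.species_effect_sd, size=len(genes))
        base = config.baseline_mean * 2.0 ** offsets

        effect = np.zeros((len(genes), len(sample_ids)))
        elevated_sets = [
            set(e.split(",")) if e else set() for e in sub["elevated_cell_types"]
        ]
        cell_types = [m[2] for m in meta_rows]
        for gi, elev in enumerate(elevated_sets):
            if not elev:
                continue
            for sj, ct in enumerate(cell_types):
                if ct in elev:
                    effect[gi, sj] = sub["log2_effect"].iloc[gi]

        mu = base[:, None] * 2.0 ** effect * depths[None, :]
        counts = rng.negative_binomial(n=1.0 / alpha, p=1.0 / (1.0 + alpha * mu))
        cm = CountMatrix(
            pd.DataFrame(counts, index=genes, columns=sample_ids),
            pd.DataFrame(
                meta_rows, columns=["sample_id", "species", "cell_type", "replicate", "stage"]
            ).set_index("sample_id"),
        )
        matrices[sp] = cm
    return matrices, truth


@dataclass
class SyntheticDataset:
    """One realized dataset: counts per species, orthology links, truth."""

    config: SyntheticConfig
    counts: dict[str, CountMatrix]
    orthology: OrthologyLinkTable
    truth: GroundTruth


def simulate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate orthology and counts in one call."""
    config = config or SyntheticConfig()
    links, truth = generate_orthology(config)
    counts, truth = generate_counts(config, truth)
    return SyntheticDataset(config, counts, links, truth)
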