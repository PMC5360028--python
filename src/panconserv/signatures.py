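"""Enrichment calls: tissue signatures, subtype Venn regions, marker fractions.

A gene is *enriched* in a set of tissues R (its Venn region) when every
tissue inside R beats every tissue outside R by more than the fold threshold
at the adjusted-significance cutoff, while no pair inside R separates. This
reading makes the regions mutually exclusive, so region counts add up to the
total number of enriched genes, matching the Venn-diagram convention of
sorted-cell signature studies.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .dataio import CountMatrix, ThresholdConfig
from .errors import ContractError, DegenerateSampleError

VENN_COLUMNS = ["gene_id", "enriched_in", "venn_region"]


class _PairLookup:
    """Fold/significance lookup over DE tables keyed by ordered tissue pair.

    Only one direction per unordered pair is required; the reverse direction
    is derived by negating log2fc (the Wald p is symmetric).
    """

    def __init__(self, de_tables: dict[tuple[str, str], pd.DataFrame], tissues: list[str]):
        self._fold: dict[tuple[str, str], pd.Series] = {}
        self._padj: dict[tuple[str, str], pd.Series] = {}
        genes = None
        for t, u in combinations(tissues, 2):
            if (t, u) in de_tables:
                df, sign = de_tables[(t, u)], 1.0
            elif (u, t) in de_tables:
                df, sign = de_tables[(u, t)], -1.0
            else:
                raise ContractError(f"no DE table for tissue pair ({t}, {u})")
            df = df.set_index("gene_id")
            self._fold[(t, u)] = sign * df["log2fc"]
            self._fold[(u, t)] = -sign * df["log2fc"]
            self._padj[(t, u)] = self._padj[(u, t)] = df["p_adj"]
            idx = set(df.index)
            if genes is None:
                genes = idx
            elif idx != genes:
                raise ContractError("DE tables cover different gene sets")
        self.genes = sorted(genes or set())

    def significant(self, t: str, u: str, cfg: ThresholdConfig) -> pd.Series:
        """Boolean per gene: t enriched over u by the study rule."""
        fold = self._fold[(t, u)]
        padj = self._padj[(t, u)]
        return (fold > cfg.log2fc_threshold) & (padj < cfg.alpha_adj) & padj.notna()


def venn_calls(
    de_tables: dict[tuple[str, str], pd.DataFrame],
    tissues: list[str],
    cfg: ThresholdConfig | None = None,
    genes: set[str] | None = None,
) -> pd.DataFrame:
    """Assign each gene to its mutually exclusive Venn region over ``tissues``.

    Returns a frame with ``gene_id``, ``enriched_in`` (the tissue for
    singleton regions, else "none") and ``venn_region`` (comma-joined sorted
    tissue labels, empty for unassigned genes), sorted by gene_id.
    """
    cfg = cfg or ThresholdConfig()
    lookup = _PairLookup(de_tables, list(tissues))
    gene_ids = [g for g in lookup.genes if genes is None or g in genes]

    sig = {
        (t, u): lookup.significant(t, u, cfg).reindex(gene_ids).fillna(False).to_numpy()
        for t in tissues
        for u in tissues
        if t != u
    }
    region = np.array([""] * len(gene_ids), dtype=object)
    assigned = np.zeros(len(gene_ids), dtype=bool)
    # the full tissue set is not a region: with no outside tissue to beat,
    # any gene with no internal separation would land there vacuously
    subsets = [
        combo
        for size in range(len(tissues) - 1, 0, -1)
        for combo in combinations(tissues, size)
    ]
    for combo in subsets:
        inside = set(combo)
        ok = np.ones(len(gene_ids), dtype=bool)
        for t in combo:
            for u in tissues:
                if u in inside:
                    if u != t:
                        ok &= ~sig[(t, u)]
                else:
                    ok &= sig[(t, u)]
        hit = ok & ~assigned
        region[hit] = ",".join(sorted(inside))
        assigned |= hit

    enriched_in = np.where(
        [("," not in r) and r != "" for r in region], region, "none"
    )
    enriched_in[region == ""] = "none"
    return pd.DataFrame(
        {"gene_id": gene_ids, "enriched_in": enriched_in, "venn_region": region}
    )


def call_tissue_enriched(
    de_tables: dict[tuple[str, str], pd.DataFrame],
    tissues: list[str],
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Tissue-signature Venn over e.g. endocrine/acinar/duct DE results."""
    return venn_calls(de_tables, tissues, cfg)


def call_subtype_venn(
    endocrine_genes: set[str],
    de_tables: dict[tuple[str, str], pd.DataFrame],
    subtypes: list[str],
    cfg: ThresholdConfig | None = None,
) -> pd.DataFrame:
    """Subtype Venn (alpha/beta/delta) restricted to the endocrine gene set."""
    return venn_calls(de_tables, subtypes, cfg, genes=set(endocrine_genes))


def region_counts(calls: pd.DataFrame) -> pd.DataFrame:
    """Venn-region summary: region label and gene count, sorted by label."""
    counted = calls[calls["venn_region"] != ""]
    out = (
        counted.groupby("venn_region")["gene_id"]
        .count()
        .rename("n_genes")
        .reset_index()
        .sort_values("venn_region", ignore_index=True)
    )
    return out


def enriched_set(calls: pd.DataFrame, tissue: str) -> set[str]:
    """Genes whose singleton region is ``tissue``."""
    return set(calls.loc[calls["venn_region"] == tissue, "gene_id"])


def region_subset(calls: pd.DataFrame, tissues: set[str]) -> set[str]:
    """Genes whose (nonempty) region is contained in ``tissues``."""
    mask = calls["venn_region"].map(
        lambda r: r != "" and set(r.split(",")) <= set(tissues)
    )
    return set(calls.loc[mask, "gene_id"])


def marker_fraction_table(
    cm: CountMatrix, markers: list[str], by: str = "cell_type"
) -> pd.DataFrame:
    """Percent of each library's reads attributed to each marker gene.

    Per replicate the percentage is ``100 * gene count / column total``; the
    reported value is the arithmetic mean over the replicates of one library
    type. Values carry full precision; marker tables in reports are
    conventionally rendered to one decimal.
    """
    missing = [g for g in markers if g not in cm.counts.index]
    if missing:
        raise ContractError(f"markers absent from matrix: {missing}")
    totals = cm.counts.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0][0]
        raise DegenerateSampleError(f"library {bad!r} has zero total counts")
    percent = 100.0 * cm.counts.loc[markers] / totals
    rows = []
    for library_type, sample_ids in cm.group_samples(by).items():
        means = percent[sample_ids].mean(axis=1)
        for gene in markers:
            rows.append((gene, library_type, float(means.loc[gene])))
    return pd.DataFrame(rows, columns=["gene_id", "library_type", "percent"]).sort_values(
        ["gene_id", "library_type"], ignore_index=True
    )


def expressed_genes(
    cm: CountMatrix, sf: pd.Series, cfg: ThresholdConfig | None = None
) -> set[str]:
    """Genes whose mean normalized count reaches the expression threshold.

    The boundary is inclusive: a gene whose mean normalized count equals the
    threshold (default 100) counts as expressed.
    """
    cfg = cfg or ThresholdConfig()
    norm = cm.counts.to_numpy(dtype=float) / sf.loc[cm.sample_ids].to_numpy()[None, :]
    mean = norm.mean(axis=1)
    return {g for g, m in zip(cm.gene_ids, mean) if m >= cfg.expressed_threshold}


def overlap_fraction(set_a: set[str], set_b: set[str]) -> tuple[int, float]:
    """Size of the intersection and its fraction of ``set_a`` (0 if empty)."""
    count = len(set_a & set_b)
    return count, (count / len(set_a) if set_a else 0.0)
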