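import numpy as np
import pandas as pd
import pytest

from panconserv import (
    ThresholdConfig,
    call_subtype_venn,
    enriched_set,
    estimate_size_factors,
    expressed_genes,
    marker_fraction_table,
    overlap_fraction,
    region_counts,
    region_subset,
    venn_calls,
)
from panconserv.errors import ContractError, DegenerateSampleError

from conftest import make_count_matrix


def de_table(genes, log2fc, p_adj):
    """Minimal DE frame for venn assignment."""
    return pd.DataFrame(
        {
            "gene_id": genes,
            "base_mean": 100.0,
            "log2fc": log2fc,
            "se": 0.1,
            "wald_stat": 0.0,
            "p": np.minimum(p_adj, 1.0),
            "p_adj": p_adj,
            "tested": True,
        }
    )


TISSUES = ["endocrine", "acinar", "duct"]


def tables_from_folds(folds: dict[str, list[float]], genes, sig=1e-6):
    """Build all unordered pair tables from per-pair log2fc lists."""
    return {
        ("endocrine", "acinar"): de_table(genes, folds["ea"], [sig] * len(genes)),
        ("endocrine", "duct"): de_table(genes, folds["ed"], [sig] * len(genes)),
        ("acinar", "duct"): de_table(genes, folds["ad"], [sig] * len(genes)),
    }


class TestVennCalls:
    def test_twenty_fold_singleton_region(self):
        """endocrine 1000 vs acinar 50 vs duct 50 -> region {endocrine}."""
        t = tables_from_folds(
            {"ea": [np.log2(20)], "ed": [np.log2(20)], "ad": [0.0]}, ["g1"]
        )
        calls = venn_calls(t, TISSUES)
        assert calls.loc[0, "venn_region"] == "endocrine"
        assert calls.loc[0, "enriched_in"] == "endocrine"

    def test_just_below_threshold_is_none(self):
        """3.9-fold over one tissue leaves the gene unassigned."""
        t = tables_from_folds(
            {"ea": [np.log2(3.9)], "ed": [np.log2(20)], "ad": [0.0]}, ["g1"]
        )
        calls = venn_calls(t, TISSUES)
        assert calls.loc[0, "venn_region"] == ""
        assert calls.loc[0, "enriched_in"] == "none"

    def test_exact_fourfold_is_excluded(self):
        """The rule is strict: fold > 4, so log2fc == 2 exactly does not call."""
        t = tables_from_folds({"ea": [2.0], "ed": [2.0], "ad": [0.0]}, ["g1"])
        assert venn_calls(t, TISSUES).loc[0, "venn_region"] == ""

    def test_two_tissue_region(self):
        """alpha 500 / beta 480 / delta 20 with significant folds -> {alpha, beta}."""
        tables = {
            ("alpha", "beta"): de_table(["g1"], [np.log2(500 / 480)], [1e-6]),
            ("alpha", "delta"): de_table(["g1"], [np.log2(25)], [1e-6]),
            ("beta", "delta"): de_table(["g1"], [np.log2(24)], [1e-6]),
        }
        calls = venn_calls(tables, ["alpha", "beta", "delta"])
        assert calls.loc[0, "venn_region"] == "alpha,beta"
        assert calls.loc[0, "enriched_in"] == "none"  # not a singleton region

    def test_uniform_gene_unassigned(self):
        tables = {
            ("alpha", "beta"): de_table(["g1"], [0.0], [1.0]),
            ("alpha", "delta"): de_table(["g1"], [0.0], [1.0]),
            ("beta", "delta"): de_table(["g1"], [0.0], [1.0]),
        }
        assert venn_calls(tables, ["alpha", "beta", "delta"]).loc[0, "venn_region"] == ""

    def test_missing_pair_raises(self):
        tables = {("endocrine", "acinar"): de_table(["g1"], [0.0], [1.0])}
        with pytest.raises(ContractError):
            venn_calls(tables, TISSUES)

    def test_regions_partition_and_counts_add_up(self):
        rng = np.random.default_rng(0)
        n = 300
        genes = [f"g{i}" for i in range(n)]
        t = tables_from_folds(
            {
                "ea": rng.normal(0, 3, n),
                "ed": rng.normal(0, 3, n),
                "ad": rng.normal(0, 3, n),
            },
            genes,
            sig=1e-6,
        )
        calls = venn_calls(t, TISSUES)
        assert len(calls) == n  # every gene appears exactly once
        counts = region_counts(calls)
        assert counts["n_genes"].sum() == (calls["venn_region"] != "").sum()

    def test_raising_fold_threshold_only_shrinks_regions(self):
        rng = np.random.default_rng(1)
        n = 200
        genes = [f"g{i}" for i in range(n)]
        folds = {
            "ea": rng.normal(0, 3, n),
            "ed": rng.normal(0, 3, n),
            "ad": rng.normal(0, 3, n),
        }
        t = tables_from_folds(folds, genes)
        loose = venn_calls(t, TISSUES, ThresholdConfig(fold_threshold=4.0))
        strict = venn_calls(t, TISSUES, ThresholdConfig(fold_threshold=8.0))
        for tissue in TISSUES:
            assert enriched_set(strict, tissue) <= enriched_set(loose, tissue)

    def test_region_assignment_symmetric_under_relabeling(self):
        rng = np.random.default_rng(2)
        n = 100
        genes = [f"g{i}" for i in range(n)]
        ea, ed, ad = rng.normal(0, 3, n), rng.normal(0, 3, n), rng.normal(0, 3, n)
        t1 = tables_from_folds({"ea": ea, "ed": ed, "ad": ad}, genes)
        # swap acinar and duct labels: endocrine/duct table becomes endocrine/acinar
        t2 = {
            ("endocrine", "duct"): de_table(genes, ea, [1e-6] * n),
            ("endocrine", "acinar"): de_table(genes, ed, [1e-6] * n),
            ("duct", "acinar"): de_table(genes, ad, [1e-6] * n),
        }
        c1 = venn_calls(t1, TISSUES)
        c2 = venn_calls(t2, TISSUES)
        swap = {"acinar": "duct", "duct": "acinar", "endocrine": "endocrine"}
        relabeled = c1["venn_region"].map(
            lambda r: ",".join(sorted(swap[x] for x in r.split(","))) if r else ""
        )
        assert (relabeled == c2["venn_region"]).all()

    def test_subtype_venn_restricted_to_endocrine_set(self):
        tables = {
            ("alpha", "beta"): de_table(["g1", "g2"], [5.0, 5.0], [1e-6, 1e-6]),
            ("alpha", "delta"): de_table(["g1", "g2"], [5.0, 5.0], [1e-6, 1e-6]),
            ("beta", "delta"): de_table(["g1", "g2"], [0.0, 0.0], [1.0, 1.0]),
        }
        calls = call_subtype_venn({"g2"}, tables, ["alpha", "beta", "delta"])
        assert list(calls["gene_id"]) == ["g2"]
        assert calls.loc[0, "enriched_in"] == "alpha"


class TestMarkerFractions:
    def test_single_library_percent(self):
        cm = make_count_matrix(np.array([[50], [150]]), ["alpha"])
        table = marker_fraction_table(cm, ["g0"])
        assert table.loc[0, "percent"] == pytest.approx(25.0)

    def test_matches_brute_force_recomputation(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 1000, size=(30, 6))
        cm = make_count_matrix(counts, ["alpha"] * 3 + ["beta"] * 3)
        table = marker_fraction_table(cm, [f"g{i}" for i in range(30)])
        pct = 100.0 * counts / counts.sum(axis=0, keepdims=True)
        expected_alpha = pct[:, :3].mean(axis=1)
        got = table[table["library_type"] == "alpha"].set_index("gene_id")["percent"]
        np.testing.assert_allclose(
            [got[f"g{i}"] for i in range(30)], expected_alpha, rtol=1e-12
        )
        # full-gene table sums to 100 per library type
        assert got.sum() == pytest.approx(100.0)

    def test_zero_total_library_raises(self):
        cm = make_count_matrix(np.array([[0, 5], [0, 5]]), ["a", "b"])
        with pytest.raises(DegenerateSampleError):
            marker_fraction_table(cm, ["g0"])

    def test_unknown_marker_raises(self):
        cm = make_count_matrix(np.ones((2, 2), dtype=int), ["a", "b"])
        with pytest.raises(ContractError):
            marker_fraction_table(cm, ["nope"])


class TestExpressedGenes:
    def test_boundary_inclusive_and_zero_excluded(self):
        counts = np.array([[100, 100], [99, 100], [0, 0]])
        cm = make_count_matrix(counts, ["a", "a"])
        sf = pd.Series(1.0, index=cm.sample_ids)
        expressed = expressed_genes(cm, sf)
        assert "g0" in expressed  # mean exactly 100: included
        assert "g1" not in expressed
        assert "g2" not in expressed

    def test_matches_brute_force_membership(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 400, size=(50, 5))
        cm = make_count_matrix(counts, ["a"] * 5)
        sf = estimate_size_factors(cm)
        expressed = expressed_genes(cm, sf)
        for i, g in enumerate(cm.gene_ids):
            mean = np.mean(counts[i] / sf.to_numpy())
            assert (g in expressed) == (mean >= 100.0)


class TestOverlapFraction:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"x", "y"}, {"z"}, (0, 0.0)),
            ({"x", "y"}, {"x", "y", "z"}, (2, 1.0)),
            (set(), {"z"}, (0, 0.0)),
            ({"x", "y", "z", "w"}, {"x", "y"}, (2, 0.5)),
        ],
    )
    def test_examples(self, a, b, expected):
        assert overlap_fraction(a, b) == expected


class TestRegionSubset:
    def test_exocrine_union_includes_two_tissue_region(self):
        calls = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "enriched_in": ["acinar", "duct", "none", "endocrine"],
                "venn_region": ["acinar", "duct", "acinar,duct", "endocrine"],
            }
        )
        assert region_subset(calls, {"acinar", "duct"}) == {"g1", "g2", "g3"}
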