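"""Hypergeometric over-representation of annotation terms in a signature.

Builds a small annotation in which one term collects planted endocrine
markers, then tests the recovered endocrine signature against the tested-gene
population. The marker term surfaces with a small p; a random term does not.
"""

import numpy as np

import panconserv as pc

dataset = pc.simulate(pc.SyntheticConfig(n_groups=200, rng_seed=5))
zf = pc.analyze_zebrafish(dataset.counts["zebrafish"])
population = set(zf.tissue_calls["gene_id"])

truth = dataset.truth.table
endocrine_markers = frozenset(
    truth.loc[
        (truth["species"] == "zebrafish") & (truth["marker_class"] == "conserved_endocrine"),
        "gene_id",
    ]
) & frozenset(population)
rng = np.random.default_rng(0)
random_genes = frozenset(rng.choice(sorted(population), size=40, replace=False))

annotation = [
    pc.TermAnnotation("T:0001", "hormone secretion (planted markers)", endocrine_markers),
    pc.TermAnnotation("T:0002", "random background term", random_genes),
]
result = pc.term_enrichment(zf.endocrine & population, population, annotation,
                            filter_results=False)
print(result.to_string(index=False))
# k of K term genes fall in the n-gene study set drawn from N population
# genes; the planted term's upper-tail p is tiny, the random term's is not.
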