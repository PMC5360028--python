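"""Joint PCA of all species' samples on the 1-1-1 ortholog space.

Each species contributes its own variance-stabilized expression for its
single member gene of every strict 1-1-1 ortholog group. With planted tissue
effects far above the species divergence, the first component carries the
endocrine/exocrine split and the second the species split.
"""

import panconserv as pc

dataset = pc.simulate(pc.SyntheticConfig(rng_seed=3))
full = pc.analyze_dataset(dataset.counts, dataset.orthology)
labels = pc.pca_sample_labels(full)

fracs = full.pca.variance_fractions
print(f"PC1 {fracs[0]:.0%} of variance, PC2 {fracs[1]:.0%} of variance")
print(f"PC1 between-tissue variance share:  "
      f"{pc.variance_share(full.pca.coordinates['PC1'], labels['compartment']):.2f}")
print(f"PC2 between-species variance share: "
      f"{pc.variance_share(full.pca.coordinates['PC2'], labels['species']):.2f}")
print()
coords = full.pca.coordinates[["PC1", "PC2"]].round(1)
coords["species"] = labels["species"]
coords["compartment"] = labels["compartment"]
print(coords.groupby(["compartment", "species"]).mean().round(1).to_string())
# A share near 1 means the component's coordinates are nearly constant within
# each group - i.e. the component *is* the tissue (or species) axis.
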