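"""One-config orchestration of the full comparison with reproducible outputs.

A single YAML file declares either a synthetic-data design or paths to real
count/metadata/orthology files, plus thresholds and an output directory.
``run_full`` executes the stages in dependency order (simulate or load ->
normalize -> DE -> signatures -> orthology -> conservation -> PCA -> optional
term enrichment), writes every artifact as deterministic TSV and records a
manifest with parameter values and SHA-256 digests, so a re-run with the same
config reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import signatures
from .conservation import conserved_gene_table, label_genes
from .dataio import (
    CountMatrix,
    OrthologyLinkTable,
    ThresholdConfig,
    read_counts,
    read_orthology,
    write_counts,
    write_table,
)
from .enrichment_go import read_annotation, term_enrichment
from .errors import ValidationError
from .synthdata import (
    PlantedMarker,
    SyntheticConfig,
    default_planted_design,
    simulate,
    subtype_planted_design,
)
from .workflows import FullAnalysis, analyze_dataset, pca_sample_labels


@dataclass
class PipelineConfig:
    out_dir: Path
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    synthetic: SyntheticConfig | None = None
    input_counts: dict[str, tuple[Path, Path]] | None = None  # species -> (counts, metadata)
    input_orthology: Path | None = None
    annotation: Path | None = None
    run_pca: bool = True

    def __post_init__(self) -> None:
        has_synth = self.synthetic is not None
        has_inputs = self.input_counts is not None
        if has_synth == has_inputs:
            raise ValidationError("exactly one of 'synthetic' or 'inputs' must be configured")
        if has_inputs and self.input_orthology is None:
            raise ValidationError("real-data inputs require an orthology file")


def _planted_from_config(spec) -> tuple[PlantedMarker, ...]:
    if spec in (None, "default"):
        return tuple(default_planted_design())
    if spec == "default+subtypes":
        return tuple(default_planted_design() + subtype_planted_design())
    markers = []
    for entry in spec:
        entry = dict(entry)
        entry["target_species"] = tuple(entry["target_species"])
        markers.append(PlantedMarker(**entry))
    return tuple(markers)


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a pipeline YAML file (before any computation)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: top level must be a mapping")
    seed = int(raw.get("seed", 0))
    thresholds = ThresholdConfig(rng_seed=seed, **raw.get("thresholds", {}))
    synthetic = None
    input_counts = None
    input_orthology = None
    if "synthetic" in raw:
        synth = dict(raw["synthetic"])
        synth["planted"] = _planted_from_config(synth.get("planted"))
        if "libsize_range" in synth:
            synth["libsize_range"] = tuple(synth["libsize_range"])
        if "cell_design" in synth:
            synth["cell_design"] = {
                sp: [tuple(row) for row in rows] for sp, rows in synth["cell_design"].items()
            }
        synth.setdefault("rng_seed", seed)
        synthetic = SyntheticConfig(**synth)
    if "inputs" in raw:
        inputs = raw["inputs"]
        input_orthology = Path(inputs["orthology"])
        input_counts = {
            sp: (Path(entry["counts"]), Path(entry["metadata"]))
            for sp, entry in inputs["species"].items()
        }
    return PipelineConfig(
        out_dir=Path(raw.get("out_dir", "panconserv_out")),
        thresholds=thresholds,
        synthetic=synthetic,
        input_counts=input_counts,
        input_orthology=input_orthology,
        annotation=Path(raw["annotation"]) if raw.get("annotation") else None,
        run_pca=bool(raw.get("run_pca", True)),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(config: PipelineConfig) -> dict:
    """Execute every stage and return the output manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []

    if config.synthetic is not None:
        dataset = simulate(config.synthetic)
        counts, links = dataset.counts, dataset.orthology
        stages.append("simulate")
        for sp, cm in counts.items():
            write_counts(cm, out / f"{sp}_counts.tsv", out / f"{sp}_metadata.tsv")
        write_table(links.table, out / "orthology_links.tsv")
        truth = dataset.truth.table.sort_values(["species", "gene_id"], ignore_index=True)
        write_table(truth, out / "ground_truth.tsv")
    else:
        counts = {
            sp: read_counts(cpath, mpath)
            for sp, (cpath, mpath) in config.input_counts.items()
        }
        links = read_orthology(config.input_orthology)
        stages.append("load")

    analysis = analyze_dataset(counts, links, config.thresholds, run_pca=config.run_pca)
    stages += ["normalize", "de", "signatures", "orthology", "conservation"]

    for sp, ana in analysis.per_species.items():
        for name, table in sorted(ana.de_tables.items()):
            write_table(table.sort_values("gene_id", ignore_index=True), out / f"{sp}_de_{name}.tsv")
        if ana.tissue_calls is not None:
            write_table(ana.tissue_calls, out / f"{sp}_tissue_calls.tsv")
            write_table(signatures.region_counts(ana.tissue_calls), out / f"{sp}_tissue_regions.tsv")
        if ana.subtype_calls is not None:
            write_table(ana.subtype_calls, out / f"{sp}_subtype_calls.tsv")
        sets = pd.DataFrame(
            sorted(
                [(g, c) for c in ("endocrine", "exocrine", "alpha", "beta")
                 for g in getattr(ana, c)]
            ),
            columns=["gene_id", "signature"],
        ).sort_values(["signature", "gene_id"], ignore_index=True)
        write_table(sets, out / f"{sp}_enriched_sets.tsv")

    for name in ("endocrine", "exocrine", "alpha", "beta"):
        partition = getattr(analysis, f"{name}_partition")
        write_table(partition.summary_table(), out / f"conservation_{name}_regions.tsv")
        write_table(label_genes(partition, "zebrafish"), out / f"conservation_{name}_labels.tsv")
    if analysis.alpha_beta_log2fc():
        write_table(
            conserved_gene_table(analysis.alpha_partition, analysis.alpha_beta_log2fc("alpha")),
            out / "conserved_alpha_genes.tsv",
        )
        write_table(
            conserved_gene_table(analysis.beta_partition, analysis.alpha_beta_log2fc("beta")),
            out / "conserved_beta_genes.tsv",
        )

    if analysis.pca is not None:
        stages.append("pca")
        coords = analysis.pca.coordinates.copy()
        coords.insert(0, "sample_id", coords.index)
        labels = pca_sample_labels(analysis)
        coords.insert(1, "species", labels["species"].to_numpy())
        coords.insert(2, "compartment", labels["compartment"].to_numpy())
        write_table(coords.reset_index(drop=True), out / "pca_coordinates.tsv")
        fractions = pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(analysis.pca.variance_fractions))],
                "variance_fraction": analysis.pca.variance_fractions,
            }
        )
        write_table(fractions, out / "pca_variance.tsv")

    if config.annotation is not None:
        stages.append("go")
        annotation = read_annotation(config.annotation)
        zf = analysis.per_species.get("zebrafish")
        if zf is not None and zf.tissue_calls is not None:
            population = set(zf.tissue_calls["gene_id"])
            go = term_enrichment(zf.endocrine & population, population, annotation, config.thresholds)
            write_table(go, out / "go_endocrine.tsv")

    manifest = {
        "stages": stages,
        "parameters": {
            "thresholds": {
                k: getattr(config.thresholds, k)
                for k in ("fold_threshold", "alpha_adj", "expressed_threshold",
                          "go_alpha", "pseudocount", "rng_seed")
            },
            "synthetic": (
                None
                if config.synthetic is None
                else {
                    "n_groups": config.synthetic.n_groups,
                    "frac_one2one": config.synthetic.frac_one2one,
                    "max_paralogs": config.synthetic.max_paralogs,
                    "baseline_mean": config.synthetic.baseline_mean,
                    "dispersion": config.synthetic.dispersion,
                    "libsize_range": list(config.synthetic.libsize_range),
                    "species_effect_sd": config.synthetic.species_effect_sd,
                    "rng_seed": config.synthetic.rng_seed,
                }
            ),
        },
        "outputs": {
            p.name: _sha256(p) for p in sorted(out.glob("*.tsv"))
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
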