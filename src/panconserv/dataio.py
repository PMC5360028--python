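"""On-disk artifacts: count matrices, sample metadata, orthology links, results.

All tabular files are tab-separated UTF-8 with a mandatory header row; "NA" is
the only missing-value token (the dialect of Biomart exports). Counts may also
be MatrixMarket integer coordinate files with ``.rows`` / ``.cols`` sidecars.
Gene and sample identifiers are case-sensitive opaque strings and are never
normalized.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .errors import ContractError, MissingMetadataError, ParseError, ValidationError

STAGES = ("adult", "embryonic")

#: significant digits used when rendering floating-point result columns
FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class ThresholdConfig:
    """Decision thresholds for the enrichment pipeline.

    Parameters mirror the selection rules of the study design: a gene is
    called enriched when its fold change exceeds ``fold_threshold`` (strictly)
    at BH-adjusted p below ``alpha_adj``; a gene counts as expressed when its
    mean normalized count reaches ``expressed_threshold`` (inclusive); term
    over-representation is reported below ``go_alpha`` on the raw p value;
    ``pseudocount`` guards fold changes against zero fitted means.
    """

    fold_threshold: float = 4.0
    alpha_adj: float = 0.05
    expressed_threshold: float = 100.0
    go_alpha: float = 0.1
    pseudocount: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.fold_threshold > 1:
            raise ValidationError("fold_threshold must be > 1")
        if not 0 < self.alpha_adj < 1:
            raise ValidationError("alpha_adj must be in (0, 1)")
        if self.expressed_threshold < 0:
            raise ValidationError("expressed_threshold must be >= 0")
        if not 0 < self.go_alpha < 1:
            raise ValidationError("go_alpha must be in (0, 1)")
        if not self.pseudocount > 0:
            raise ValidationError("pseudocount must be > 0")

    @property
    def log2fc_threshold(self) -> float:
        return float(np.log2(self.fold_threshold))


@dataclass
class CountMatrix:
    """Genes x samples integer counts with per-sample metadata.

    ``counts`` is a genes-by-samples DataFrame of non-negative integers;
    ``samples`` is indexed by sample_id with columns ``species``,
    ``cell_type``, ``replicate`` and ``stage``. Construction validates every
    invariant, so no instance with duplicate identifiers, negative counts or
    missing metadata can exist.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene identifier {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample identifier {dup!r}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.equal(np.mod(values, 1), 0)):
                bad = np.argwhere(np.mod(values, 1) != 0)[0]
                raise ParseError(
                    f"non-integer count at gene {self.counts.index[bad[0]]!r}, "
                    f"sample {self.counts.columns[bad[1]]!r}"
                )
            self.counts = self.counts.astype(np.int64)
            values = self.counts.to_numpy()
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ParseError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.samples.index]
        if missing:
            raise MissingMetadataError(
                f"samples missing from metadata: {', '.join(map(repr, missing))}"
            )
        # reconcile by identifier, not position; drop metadata-only samples
        self.samples = self.samples.loc[list(self.counts.columns)].copy()
        for col in ("species", "cell_type"):
            if col not in self.samples.columns:
                raise ValidationError(f"metadata lacks required column {col!r}")
            if self.samples[col].isna().any() or (self.samples[col] == "").any():
                bad = self.samples.index[
                    self.samples[col].isna() | (self.samples[col] == "")
                ][0]
                raise ValidationError(f"sample {bad!r} has empty {col}")
        if "replicate" not in self.samples.columns:
            self.samples["replicate"] = 1
        reps = pd.to_numeric(self.samples["replicate"], errors="coerce")
        if reps.isna().any() or (reps < 1).any() or (reps % 1 != 0).any():
            raise ValidationError("replicate must be a positive integer")
        self.samples["replicate"] = reps.astype(int)
        if "stage" not in self.samples.columns:
            self.samples["stage"] = "adult"
        self.samples["stage"] = self.samples["stage"].fillna("adult")
        bad_stage = set(self.samples["stage"]) - set(STAGES)
        if bad_stage:
            raise ValidationError(f"unknown stage values: {sorted(bad_stage)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def group_samples(self, by: str = "cell_type") -> dict[str, list[str]]:
        """Sample ids keyed by metadata column value, in column order."""
        out: dict[str, list[str]] = {}
        for sid in self.sample_ids:
            out.setdefault(str(self.samples.at[sid, by]), []).append(sid)
        return out

    def subset_samples(self, sample_ids: list[str]) -> "CountMatrix":
        unknown = [s for s in sample_ids if s not in self.counts.columns]
        if unknown:
            raise ContractError(f"unknown samples: {unknown}")
        return CountMatrix(self.counts[sample_ids].copy(), self.samples.loc[sample_ids].copy())

    def subset_genes(self, gene_ids: list[str]) -> "CountMatrix":
        unknown = [g for g in gene_ids if g not in self.counts.index]
        if unknown:
            raise ContractError(f"unknown genes: {unknown[:5]}")
        return CountMatrix(self.counts.loc[gene_ids].copy(), self.samples.copy())


ORTHOLOGY_COLUMNS = ["species_a", "gene_a", "species_b", "gene_b", "homology_type"]


@dataclass
class OrthologyLinkTable:
    """Deduplicated cross-species gene links (Biomart-export style).

    Rows are canonically ordered so that (species_a, gene_a) <= (species_b,
    gene_b) lexicographically; the symmetric closure is therefore implicit and
    exposed through :meth:`links`.
    """

    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=ORTHOLOGY_COLUMNS))

    def __post_init__(self) -> None:
        df = self.table[ORTHOLOGY_COLUMNS].astype(str).copy()
        if ((df["gene_a"] == "") | (df["gene_b"] == "")).any():
            raise ParseError("orthology row with empty gene identifier")
        if (df["species_a"] == df["species_b"]).any():
            bad = df[df["species_a"] == df["species_b"]].iloc[0]
            raise ValidationError(
                f"orthology row links {bad['species_a']!r} to itself"
            )
        swap = df["species_a"] + "\t" + df["gene_a"] > df["species_b"] + "\t" + df["gene_b"]
        df.loc[swap, ORTHOLOGY_COLUMNS[:4]] = df.loc[
            swap, ["species_b", "gene_b", "species_a", "gene_a"]
        ].to_numpy()
        df = df.drop_duplicates(subset=ORTHOLOGY_COLUMNS[:4], ignore_index=True)
        self.table = df.sort_values(ORTHOLOGY_COLUMNS[:4], ignore_index=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def species(self) -> set[str]:
        return set(self.table["species_a"]) | set(self.table["species_b"])

    def links(self) -> list[tuple[tuple[str, str], tuple[str, str]]]:
        """Undirected links as ((species, gene), (species, gene)) pairs."""
        return [
            ((r.species_a, r.gene_a), (r.species_b, r.gene_b))
            for r in self.table.itertuples(index=False)
        ]


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, **kwargs)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc


def _read_counts_table(counts_path: Path) -> pd.DataFrame:
    if counts_path.suffix == ".mtx":
        rows_path = counts_path.with_suffix(".rows")
        cols_path = counts_path.with_suffix(".cols")
        for sidecar in (rows_path, cols_path):
            if not sidecar.exists():
                raise ParseError(f"MatrixMarket sidecar {sidecar} missing")
        mat = mmread(counts_path)
        genes = rows_path.read_text().splitlines()
        samples = cols_path.read_text().splitlines()
        dense = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        if dense.shape != (len(genes), len(samples)):
            raise ParseError(
                f"{counts_path}: matrix is {dense.shape}, sidecars declare "
                f"({len(genes)}, {len(samples)})"
            )
        return pd.DataFrame(dense, index=genes, columns=samples)
    df = _read_tsv(counts_path, index_col=0)
    df.index = df.index.astype(str)
    for col in df.columns:
        cell = df[col]
        if cell.isna().any():
            row = df.index[cell.isna()][0]
            raise ParseError(f"missing count at gene {row!r}, sample {col!r}")
        numeric = pd.to_numeric(cell, errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise ParseError(f"non-numeric count at gene {row!r}, sample {col!r}")
        df[col] = numeric
    return df


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a count matrix (TSV or .mtx with sidecars) plus sample metadata.

    Metadata is a TSV keyed by ``sample_id`` and is reconciled to count
    columns by identifier; samples present in the counts but absent from the
    metadata raise :class:`MissingMetadataError` naming them.
    """
    counts = _read_counts_table(Path(counts_path))
    meta = _read_tsv(metadata_path, dtype=str)
    if "sample_id" not in meta.columns:
        raise ParseError(f"{metadata_path}: metadata requires a sample_id column")
    if meta["sample_id"].duplicated().any():
        dup = meta["sample_id"][meta["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"duplicate sample identifier {dup!r} in metadata")
    meta = meta.set_index("sample_id")
    return CountMatrix(counts, meta)


def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path | None = None) -> None:
    """Write counts (TSV or MatrixMarket by extension) and optional metadata."""
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        coo = coo_matrix(cm.counts.to_numpy())
        with io.BytesIO() as buf:
            mmwrite(buf, coo, field="integer")
            counts_path.write_bytes(buf.getvalue())
        counts_path.with_suffix(".rows").write_text("\n".join(cm.gene_ids) + "\n")
        counts_path.with_suffix(".cols").write_text("\n".join(cm.sample_ids) + "\n")
    else:
        out = cm.counts.copy()
        out.index.name = "gene_id"
        out.to_csv(counts_path, sep="\t", lineterminator="\n")
    if metadata_path is not None:
        meta = cm.samples.copy()
        meta.index.name = "sample_id"
        meta.to_csv(metadata_path, sep="\t", lineterminator="\n")


def read_orthology(path: str | Path) -> OrthologyLinkTable:
    """Read a Biomart-style orthology link TSV.

    The header must name the five canonical fields (extra columns are
    ignored); rows are deduplicated after canonical ordering of each pair.
    """
    df = _read_tsv(path, dtype=str)
    missing = [c for c in ORTHOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: orthology table lacks columns {missing}")
    df = df[ORTHOLOGY_COLUMNS]
    if df.isna().any().any():
        raise ParseError(f"{path}: orthology table contains missing values")
    return OrthologyLinkTable(df)


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as deterministic TSV.

    Column order is taken from the frame (each emitting module fixes it);
    floats are rendered with 6 significant digits; the row order of the input
    is preserved, so emitters sort by their documented key before calling.
    """
    records.to_csv(
        path,
        sep="\t",
        index=False,
        float_format=FLOAT_FORMAT,
        na_rep="NA",
        lineterminator="\n",
    )
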