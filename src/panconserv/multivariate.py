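"""Variance-stabilizing transformation and PCA, within and across species.

The VST is the closed-form asymptotic stabilizer for NB counts,
``y = log2(n/s + c)`` with ``c = 1/(4 * alpha_bar)`` (floored at 1), where
``alpha_bar`` is the trimmed-mean dispersion: for large means the replicate
variance of y approaches ``alpha / ln(2)^2`` regardless of the mean, while
the offset c keeps low counts from exploding the variance. PCA is the
gene-centered SVD of the transformed matrix with samples as observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import CountMatrix
from .de import DispersionEstimates
from .errors import ComputationError, ContractError
from .orthology import OrthologyTables


def vst(cm: CountMatrix, sf: pd.Series, disp: DispersionEstimates | float) -> pd.DataFrame:
    """Variance-stabilized expression matrix (genes x samples).

    ``disp`` may be the per-gene estimates (summarized by their trimmed mean)
    or a scalar dispersion. Monotone in the raw count per sample; equal
    normalized counts map to equal values.
    """
    alpha_bar = disp if isinstance(disp, (int, float)) else disp.trimmed_mean
    c = max(1.0, 1.0 / (4.0 * max(alpha_bar, 1e-12)))
    norm = cm.counts.to_numpy(dtype=float) / sf.loc[cm.sample_ids].to_numpy()[None, :]
    return pd.DataFrame(np.log2(norm + c), index=cm.gene_ids, columns=cm.sample_ids)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame  # samples x components, columns PC1..PCk
    variance_fractions: np.ndarray
    loadings: pd.DataFrame  # genes x components
    gene_subset: list[str]

    @property
    def n_components(self) -> int:
        return self.coordinates.shape[1]


def pca(matrix: pd.DataFrame, gene_subset: list[str] | None = None) -> PCAResult:
    """Gene-centered SVD of a (genes x samples) expression matrix.

    Components are ordered by decreasing explained variance; the sign of each
    component is fixed by making its largest-magnitude gene loading positive,
    so results are reproducible without a seed. Variance fractions are the
    squared singular values over their total.
    """
    if gene_subset is not None:
        missing = [g for g in gene_subset if g not in matrix.index]
        if missing:
            raise ContractError(f"gene subset absent from matrix: {missing[:5]}")
        matrix = matrix.loc[gene_subset]
    if matrix.shape[1] < 2:
        raise ContractError("PCA needs at least 2 samples")
    x = matrix.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    for k in range(s.size):
        pivot = np.argmax(np.abs(u[:, k]))
        if u[pivot, k] < 0:
            u[:, k] = -u[:, k]
            vt[k, :] = -vt[k, :]
    total = float((s**2).sum())
    fractions = s**2 / total if total > 0 else np.zeros_like(s)
    comps = [f"PC{i + 1}" for i in range(s.size)]
    coords = pd.DataFrame((vt.T * s), index=matrix.columns, columns=comps)
    loadings = pd.DataFrame(u, index=matrix.index, columns=comps)
    return PCAResult(coords, fractions, loadings, list(matrix.index))


def cross_species_pca(
    per_species: dict[str, pd.DataFrame], tables: OrthologyTables
) -> PCAResult:
    """Joint PCA of all species' samples on the 1-1-1 ortholog space.

    Rows are table-one ortholog groups; each species contributes its own VST
    values for its single member gene (no cross-species rescaling, so species
    effects remain visible as their own principal direction). Sample
    identifiers must be unique across species.
    """
    missing_cover: list[str] = []
    rows: dict[str, list[np.ndarray]] = {sp: [] for sp in per_species}
    group_ids = []
    for grp in tables.table_one:
        ok = True
        vals = {}
        for sp in per_species:
            gene = grp.members[sp][0]
            if gene not in per_species[sp].index:
                ok = False
                missing_cover.append(grp.group_id)
                break
            vals[sp] = per_species[sp].loc[gene].to_numpy(dtype=float)
        if ok:
            group_ids.append(grp.group_id)
            for sp in per_species:
                rows[sp].append(vals[sp])
    if missing_cover:
        raise ComputationError(
            f"{len(missing_cover)} table-one groups missing from a species matrix, "
            f"e.g. {missing_cover[:3]}"
        )
    if not group_ids:
        raise ComputationError("no 1-1-1 ortholog groups covered by all matrices")
    blocks = [
        pd.DataFrame(np.vstack(rows[sp]), index=group_ids, columns=per_species[sp].columns)
        for sp in per_species
    ]
    joint = pd.concat(blocks, axis=1)
    if joint.columns.duplicated().any():
        raise ContractError("sample identifiers collide across species")
    return pca(joint)


def variance_share(coords: pd.Series, labels: pd.Series) -> float:
    """Between-group share of the variance of one component's coordinates.

    Used to quantify how strongly a principal component separates e.g.
    tissues (on PC1) or species (on PC2): 1 means coordinates are constant
    within groups, 0 means group means coincide.
    """
    x = coords.to_numpy(dtype=float)
    total = ((x - x.mean()) ** 2).sum()
    if total == 0:
        return 0.0
    between = 0.0
    for _, idx in labels.groupby(labels).groups.items():
        xg = coords.loc[idx].to_numpy(dtype=float)
        between += xg.size * (xg.mean() - x.mean()) ** 2
    return float(between / total)
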