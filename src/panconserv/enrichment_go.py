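"""Gene-set over-representation by the one-sided hypergeometric test.

A transparent replacement for black-box functional-annotation services: for a
study set of n genes drawn from a population of N, a term annotating K
population genes and k study genes gets ``p = P(X >= k)`` for
``X ~ Hypergeometric(N, K, n)``, BH-adjusted across tested terms. Only
over-representation is tested, and following the convention of the analyses
this mirrors, reporting filters on the *raw* p value (default < 0.1) while
the adjusted value is carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .dataio import ThresholdConfig, _read_tsv
from .de import adjust_bh
from .errors import ContractError, ParseError, ValidationError

GO_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj"]


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    genes: frozenset

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"term {self.term_id!r} annotates no genes")


def read_annotation(path: str | Path) -> list[TermAnnotation]:
    """Read a long-format gene->term TSV (term_id, term_name, gene_id)."""
    df = _read_tsv(path, dtype=str)
    required = ["term_id", "term_name", "gene_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: annotation lacks columns {missing}")
    terms = []
    for (term_id, term_name), sub in df.groupby(["term_id", "term_name"], sort=True):
        terms.append(TermAnnotation(term_id, term_name, frozenset(sub["gene_id"])))
    seen: set[str] = set()
    for t in terms:
        if t.term_id in seen:
            raise ValidationError(f"term id {t.term_id!r} has conflicting names")
        seen.add(t.term_id)
    return terms


def term_enrichment(
    study: set[str],
    population: set[str],
    annotation: list[TermAnnotation],
    cfg: ThresholdConfig | None = None,
    filter_results: bool = True,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a study set.

    Term gene sets are intersected with the population before testing; terms
    with no population gene are skipped. Rows are sorted by (p, term_id);
    with ``filter_results`` only terms with raw p below ``cfg.go_alpha``
    survive.
    """
    cfg = cfg or ThresholdConfig()
    if not study <= population:
        raise ContractError("study set must be a subset of the population")
    N, n = len(population), len(study)
    rows = []
    for term in annotation:
        term_genes = term.genes & population
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & study)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term.term_id, term.term_name, k, K, n, N, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=GO_COLUMNS[:-1])
    out["p_adj"] = adjust_bh(out["p"].to_numpy()) if len(out) else []
    out = out.sort_values(["p", "term_id"], ignore_index=True)
    if filter_results:
        out = out[out["p"] < cfg.go_alpha].reset_index(drop=True)
    return out
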