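import numpy as np
import pandas as pd
import pytest

from panconserv import CountMatrix, SyntheticConfig, default_planted_design, simulate


def make_count_matrix(counts: np.ndarray, cell_types: list[str], species: str = "zebrafish",
                      gene_prefix: str = "g") -> CountMatrix:
    """CountMatrix from an array and per-sample cell-type labels."""
    n_genes, n_samples = counts.shape
    assert len(cell_types) == n_samples
    sample_ids = [f"s{j}" for j in range(n_samples)]
    reps: dict[str, int] = {}
    rows = []
    for sid, ct in zip(sample_ids, cell_types):
        reps[ct] = reps.get(ct, 0) + 1
        rows.append((sid, species, ct, reps[ct], "adult"))
    meta = pd.DataFrame(
        rows, columns=["sample_id", "species", "cell_type", "replicate", "stage"]
    ).set_index("sample_id")
    frame = pd.DataFrame(counts, index=[f"{gene_prefix}{i}" for i in range(n_genes)],
                         columns=sample_ids)
    return CountMatrix(frame, meta)


def nb_counts(rng: np.random.Generator, mu, alpha: float, size) -> np.ndarray:
    """NB draws in the Var = mu + alpha*mu^2 parameterization."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    return rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu), size=size)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete three-species dataset with planted truth."""
    config = SyntheticConfig(n_groups=160, planted=tuple(default_planted_design()), rng_seed=42)
    return simulate(config)


@pytest.fixture(scope="session")
def two_condition_matrix():
    """50 genes x 6 samples NB null matrix, two cell types."""
    rng = np.random.default_rng(7)
    counts = nb_counts(rng, 150.0, 0.1, (50, 6))
    return make_count_matrix(counts, ["a"] * 3 + ["b"] * 3)
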