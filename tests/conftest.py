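import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dietmix.prey_reconstruction import RegressionEntry

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def toy_occurrences() -> pd.DataFrame:
    """Three stomachs with two weighted taxa: A in s1 (10 g) and s2 (5 g),
    B in s1 (30 g) and s3 (20 g).  Hand computation gives %P(A) = 100*15/45
    and %P(B) = 100*50/60."""
    return pd.DataFrame(
        {
            "stomach_id": ["s1", "s1", "s2", "s3"],
            "taxon": ["A", "B", "A", "B"],
            "family": ["fA", "fB", "fA", "fB"],
            "class": ["T", "T", "T", "T"],
            "n_individuals": [1, 1, 1, 1],
            "total_weight_g": [10.0, 30.0, 5.0, 20.0],
        }
    )


@pytest.fixture
def linear_regression() -> RegressionEntry:
    """Identity-friendly fish regression: length = 10x mm, weight = 0.01 L^3 g."""
    return RegressionEntry(
        taxon="Testfish",
        scope="species",
        input_structure="otolith",
        measurement_kind="otolith_length",
        length_form="linear",
        length_a=0.0,
        length_b=10.0,
        weight_c=0.01,
        weight_d=3.0,
    )


@pytest.fixture
def tdf_fixture() -> dict:
    """Nominal dolphin-skin discrimination factors used across SIA tests."""
    return {"means": np.array([1.0, 1.6]), "sds": np.array([0.4, 0.5])}


def grid_posterior_two_sources(data, n_grid: int = 10_000) -> tuple[float, float]:
    """Independent quadrature oracle for the two-source, single-isotope,
    no-residual mixing posterior: evaluates the unnormalised posterior of
    p1 on a uniform grid over [0, 1] (flat Dirichlet prior) and returns
    the posterior mean and sd by numerical integration."""
    p1 = np.linspace(1e-6, 1 - 1e-6, n_grid)
    mu = data.corrected_means[:, 0]
    var = data.corrected_vars[:, 0]
    m = p1 * mu[0] + (1 - p1) * mu[1]
    v = p1**2 * var[0] + (1 - p1) ** 2 * var[1]
    x = data.consumers[:, 0]
    log_post = np.array(
        [-0.5 * len(x) * np.log(2 * np.pi * vv) - ((x - mm_) ** 2).sum() / (2 * vv)
         for mm_, vv in zip(m, v)]
    )
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    mean = float((w * p1).sum())
    sd = float(np.sqrt((w * (p1 - mean) ** 2).sum()))
    return mean, sd


def enumerate_bootstrap(occ: pd.DataFrame, metric: str, taxon: str) -> np.ndarray:
    """Independent bootstrap oracle: the exact resampling distribution of a
    diet index, built by enumerating every ordered resample of stomachs and
    rerunning the plain diet-table path on each concatenated replicate.
    A taxon absent from a replicate contributes 0.  Quantiles of the
    returned population should be taken with the inverted-CDF rule."""
    import itertools

    from dietmix import diet_indices as di

    stomachs = sorted(occ.stomach_id.unique())
    n = len(stomachs)
    values = []
    for combo in itertools.product(stomachs, repeat=n):
        parts = []
        for i, s in enumerate(combo):
            part = occ[occ.stomach_id == s].copy()
            part["stomach_id"] = f"rep{i}"
            parts.append(part)
        rep = pd.concat(parts, ignore_index=True)
        table = di.diet_table(rep, n).set_index("taxon")
        values.append(float(table.loc[taxon, metric]) if taxon in table.index else 0.0)
    return np.asarray(values, dtype=float)


def make_occurrences(rng: np.random.Generator, n_stomachs=5, n_taxa=6) -> pd.DataFrame:
    """Random occurrence table; last taxon is weightless."""
    rows = []
    taxa = [f"t{i}" for i in range(n_taxa)]
    fams = [f"f{i // 2}" for i in range(n_taxa)]
    for s in range(n_stomachs):
        present = rng.choice(n_taxa, size=rng.integers(1, n_taxa + 1), replace=False)
        for i in present:
            w = np.nan if i == n_taxa - 1 else float(rng.uniform(1, 100))
            rows.append((f"s{s}", taxa[i], fams[i], "T", int(rng.integers(1, 20)), w))
    return pd.DataFrame(
        rows,
        columns=["stomach_id", "taxon", "family", "class", "n_individuals", "total_weight_g"],
    )
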