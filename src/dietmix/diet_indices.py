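"""Dietary composition indices from prey occurrences.

For each prey taxon (or family/class aggregate) across a set of stomachs:

* %N — taxon individuals as a percentage of all prey individuals;
* %O — percentage of stomachs in which the taxon occurs;
* %W — taxon reconstructed weight as a percentage of the total weight of
  weight-bearing taxa (taxa with no reconstructable weight are excluded
  from the denominator and carry no %W or IRI);
* IRI — Index of Relative Importance, (%N + %W) x %O, range 0-20,000;
* prey-specific abundance %P_i — taxon weight share computed only over
  the stomachs that contain the taxon; paired with %O it gives the
  Costello-Amundsen feeding-strategy diagram coordinates.

Two arithmetic modes are provided.  ``analysis`` keeps full precision.
``reporting`` reproduces the convention of published diet tables where
percentages are rounded to two decimals (half away from zero) *before*
the IRI product, which changes the IRI in the second decimal.

Bootstrap confidence limits resample whole stomachs (the sampling unit)
with replacement and recompute every index per replicate; a taxon
missing from a replicate contributes zero there.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "round_half_up",
    "diet_row",
    "diet_table",
    "prey_specific_abundance",
    "amundsen_points",
    "bootstrap_diet",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (published-table convention).

    Uses decimal arithmetic on ``repr(x)`` so that values like 2.675
    round on their printed representation, not their binary one.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def diet_row(
    n: float,
    total_n: float,
    o: float,
    n_stomachs: int,
    w: float | None = None,
    total_w: float | None = None,
    mode: str = "analysis",
) -> dict:
    """Indices for a single taxon from its raw N / O / W and the totals.

    Returns a dict with keys pctN, pctO, pctW, IRI (the last two None
    when the taxon carries no weight).
    """
    if mode not in ("analysis", "reporting"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_stomachs < 1:
        raise ValueError("n_stomachs must be >= 1")
    if total_n <= 0:
        raise ValueError("total prey count must be positive")
    pct_n = 100.0 * n / total_n
    pct_o = 100.0 * o / n_stomachs
    has_w = w is not None and total_w is not None and not pd.isna(w) and total_w > 0
    pct_w = 100.0 * w / total_w if has_w else None
    if mode == "reporting":
        pct_n = round_half_up(pct_n)
        pct_o = round_half_up(pct_o)
        pct_w = round_half_up(pct_w) if pct_w is not None else None
    iri = (pct_n + pct_w) * pct_o if pct_w is not None else None
    if mode == "reporting" and iri is not None:
        iri = round_half_up(iri)
    return {"pctN": pct_n, "pctO": pct_o, "pctW": pct_w, "IRI": iri}


def _aggregate(occurrences: pd.DataFrame, level: str) -> pd.DataFrame:
    """Raw N, O, W per taxon at the requested aggregation level."""
    level_col = {"species": "taxon", "taxon": "taxon", "family": "family", "class": "class"}
    if level not in level_col:
        raise ValueError(f"unknown aggregation level {level!r}")
    col = level_col[level]
    df = occurrences.copy()
    grouped = df.groupby(col, sort=True)
    agg = pd.DataFrame(
        {
            "N": grouped["n_individuals"].sum(),
            "O": grouped["stomach_id"].nunique(),
            "W": grouped["total_weight_g"].sum(min_count=1),
        }
    )
    agg.index.name = "taxon"
    return agg.reset_index()


def diet_table(
    occurrences: pd.DataFrame,
    n_stomachs: int,
    level: str = "taxon",
    mode: str = "analysis",
) -> pd.DataFrame:
    """Full diet-composition table at the requested taxonomic level.

    ``occurrences`` needs columns ``stomach_id, taxon, n_individuals,
    total_weight_g`` (plus ``family``/``class`` for aggregate levels).
    """
    if occurrences.empty:
        raise ValueError("occurrence table is empty")
    if n_stomachs < 1:
        raise ValueError("n_stomachs must be >= 1")
    agg = _aggregate(occurrences, level)
    total_n = agg["N"].sum()
    total_w = agg["W"].sum(min_count=1)
    rows = []
    for r in agg.itertuples(index=False):
        w = None if pd.isna(r.W) else r.W
        rows.append(diet_row(r.N, total_n, r.O, n_stomachs, w, total_w, mode))
    out = pd.concat([agg, pd.DataFrame(rows, index=agg.index)], axis=1)
    return out


def prey_specific_abundance(occurrences: pd.DataFrame, taxon: str) -> float:
    """Prey-specific abundance %P_i for one taxon.

    100 x (summed weight of the taxon) / (summed total stomach-content
    weight of only those stomachs containing the taxon).  NaN when the
    taxon is absent or carries no weight.
    """
    mask = occurrences["taxon"] == taxon
    if not mask.any():
        return float("nan")
    wi = occurrences.loc[mask, "total_weight_g"].sum(min_count=1)
    if pd.isna(wi):
        return float("nan")
    stomachs = occurrences.loc[mask, "stomach_id"].unique()
    wti = occurrences.loc[
        occurrences["stomach_id"].isin(stomachs), "total_weight_g"
    ].sum(min_count=1)
    return float(100.0 * wi / wti)


def amundsen_points(occurrences: pd.DataFrame, n_stomachs: int) -> pd.DataFrame:
    """(%O, %P) coordinates per weighted taxon for the feeding-strategy plot."""
    if n_stomachs < 1:
        raise ValueError("n_stomachs must be >= 1")
    rows = []
    for taxon, grp in occurrences.groupby("taxon", sort=True):
        pct_p = prey_specific_abundance(occurrences, taxon)
        if np.isnan(pct_p):
            continue
        pct_o = 100.0 * grp["stomach_id"].nunique() / n_stomachs
        rows.append((taxon, pct_o, pct_p))
    return pd.DataFrame(rows, columns=["taxon", "pctO", "pctP"])


def bootstrap_diet(
    occurrences: pd.DataFrame,
    n_stomachs: int,
    n_iter: int = 1000,
    seed: int | None = None,
    level: str = "taxon",
) -> pd.DataFrame:
    """Bootstrap confidence limits for %N, %O, %W and IRI.

    Stomachs are resampled with replacement (``n_stomachs`` per
    replicate, ``n_iter`` replicates); all indices are recomputed per
    replicate and summarised by the 2.5 / 50 / 97.5 percentiles (linear
    interpolation).  In a replicate, %O counts selected stomachs with
    multiplicity, and the %W denominator is the replicate's own total
    weight over weight-bearing taxa.

    Returns a long-format frame: taxon, metric, median, lo95, hi95.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if n_stomachs < 1:
        raise ValueError("n_stomachs must be >= 1")
    rng = np.random.default_rng(seed)

    agg_col = {"species": "taxon", "taxon": "taxon", "family": "family", "class": "class"}[level]
    counts = occurrences.pivot_table(
        index="stomach_id", columns=agg_col, values="n_individuals", aggfunc="sum", fill_value=0
    )
    weights = occurrences.pivot_table(
        index="stomach_id", columns=agg_col, values="total_weight_g", aggfunc="sum"
    ).reindex(columns=counts.columns)
    weighted_taxa = weights.notna().any(axis=0).to_numpy()
    taxa = counts.columns.to_list()
    c = counts.to_numpy(dtype=float)
    w = weights.fillna(0.0).to_numpy(dtype=float)
    presence = (c > 0).astype(float)
    n_src = c.shape[0]

    # multiplicity of each stomach in each replicate
    m = rng.multinomial(n_stomachs, np.full(n_src, 1.0 / n_src), size=n_iter).astype(float)
    n_rep = m @ c
    o_rep = m @ presence
    w_rep = m @ w

    pct_n = 100.0 * n_rep / n_rep.sum(axis=1, keepdims=True)
    pct_o = 100.0 * o_rep / n_stomachs
    tot_w = w_rep[:, weighted_taxa].sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct_w = np.where(tot_w > 0, 100.0 * w_rep / tot_w, np.nan)
    pct_w[:, ~weighted_taxa] = np.nan
    with np.errstate(invalid="ignore"):
        iri = (pct_n + pct_w) * pct_o

    out = []
    for name, arr in (("pctN", pct_n), ("pctO", pct_o), ("pctW", pct_w), ("IRI", iri)):
        for j, taxon in enumerate(taxa):
            col = arr[:, j]
            if np.isnan(col).all():
                continue
            lo, med, hi = np.nanpercentile(col, [2.5, 50.0, 97.5])
            out.append((taxon, name, med, lo, hi))
    return pd.DataFrame(out, columns=["taxon", "metric", "median", "lo95", "hi95"])
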