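"""Summaries and Ward clustering of prey isotope measurements.

Prey species with overlapping isotopic signatures cannot be separated by
a mixing model, so species are summarised (per-isotope mean/sd) and then
agglomerated into isotopically coherent source groups with Ward's
minimum-variance criterion on the (delta13C, delta15N) species means.
Group-level summaries are obtained by exact pooling of the per-species
sample statistics.

Two Ward dialects are supported: ``ward2`` (the modern convention, the
Lance-Williams recursion on squared Euclidean distances — scipy's
``ward``) and ``ward1`` (the legacy recursion applied to unsquared
distances).  The cut at ``k`` clusters is usually identical; both are
exposed because published analyses rarely say which was used.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist

ISOTOPES = ("d13C", "d15N")

MARINE_RANGES = {"d13C": (-35.0, -5.0), "d15N": (0.0, 25.0)}


def _check_marine_range(values: np.ndarray, isotope: str) -> list[str]:
    lo, hi = MARINE_RANGES[isotope]
    out = []
    for v in values:
        if not (lo < v < hi):
            out.append(f"{isotope} value {v} outside typical marine range ({lo}, {hi})")
    return out


def summarize_species(measurements: pd.DataFrame, taxon: str) -> dict:
    """Per-isotope {n, mean, sd, min, max} for one taxon.

    ``measurements`` has columns ``sample_id, role, taxon, d13C, d15N``;
    only ``role == 'source'`` rows of the given taxon are used.  The sd
    is the n-1 sample standard deviation, None when n < 2.
    """
    sub = measurements[(measurements["taxon"] == taxon) & (measurements["role"] == "source")]
    if sub.empty:
        raise ValueError(f"no source measurements for taxon {taxon!r}")
    out = {}
    for iso in ISOTOPES:
        vals = sub[iso].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValueError(f"non-finite {iso} values for taxon {taxon!r}")
        out[iso] = {
            "n": len(vals),
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            "min": float(vals.min()),
            "max": float(vals.max()),
        }
    return out


def summarize_all_species(measurements: pd.DataFrame) -> pd.DataFrame:
    """Species-level summary table (one row per source taxon)."""
    rows = []
    for taxon in sorted(measurements.loc[measurements["role"] == "source", "taxon"].unique()):
        s = summarize_species(measurements, taxon)
        rows.append(
            {
                "taxon": taxon,
                "n": s["d13C"]["n"],
                "mean_d13C": s["d13C"]["mean"],
                "sd_d13C": s["d13C"]["sd"],
                "mean_d15N": s["d15N"]["mean"],
                "sd_d15N": s["d15N"]["sd"],
            }
        )
    return pd.DataFrame(rows)


def ward_cluster(
    species_means: pd.DataFrame,
    k: int,
    dialect: str = "ward2",
    standardize: bool = False,
) -> pd.DataFrame:
    """Partition species into ``k`` groups by Ward clustering of their means.

    ``species_means`` needs columns ``taxon, mean_d13C, mean_d15N``.
    Rows are sorted lexicographically by taxon before clustering so the
    result does not depend on input order; group ids are 1..k in order
    of first appearance of each cluster in that sorted list.

    Returns a frame ``taxon, group_id``; the scipy linkage matrix is
    attached as ``result.attrs['linkage']`` (with ``labels``) for
    dendrogram export.
    """
    n = len(species_means)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if dialect not in ("ward1", "ward2"):
        raise ValueError(f"unknown Ward dialect {dialect!r}")
    df = species_means.sort_values("taxon").reset_index(drop=True)
    x = df[["mean_d13C", "mean_d15N"]].to_numpy(dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("species means must be finite")
    if standardize:
        x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    if n == 1:
        labels = np.array([1])
        z = np.empty((0, 4))
    else:
        d = pdist(x)
        # break exact ties deterministically by taxon order
        if dialect == "ward1":
            # ward.D2 on sqrt(d) realises the legacy recursion on d
            d = np.sqrt(d)
        z = linkage(d, method="ward")
        labels = fcluster(z, k, criterion="maxclust")
    # relabel clusters 1..k by first appearance in sorted-taxon order
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    out = pd.DataFrame({"taxon": df["taxon"], "group_id": [remap[l] for l in labels]})
    out.attrs["linkage"] = z
    out.attrs["labels"] = df["taxon"].to_list()
    return out


def merge_heights(partition: pd.DataFrame) -> np.ndarray:
    """Agglomeration heights of the clustering behind a partition."""
    return np.asarray(partition.attrs["linkage"])[:, 2]


def linkage_to_newick(z: np.ndarray, labels: list[str]) -> str:
    """Serialise a scipy linkage matrix as a Newick tree string."""
    tree = to_tree(np.asarray(z))

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            name = labels[node.id].replace(" ", "_")
            return f"{name}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def pool_groups(species_summaries: pd.DataFrame, partition: pd.DataFrame) -> pd.DataFrame:
    """Exact pooled per-group statistics from per-species summaries.

    Pooled mean is the n-weighted mean; pooled variance combines
    within-species and between-species terms,
    ``[sum (n_i-1) s_i^2 + sum n_i (m_i - m)^2] / (sum n_i - 1)``,
    which equals the sample variance of the concatenated raw values.
    """
    merged = species_summaries.merge(partition, on="taxon", validate="one_to_one")
    rows = []
    for gid, grp in merged.groupby("group_id", sort=True):
        n = grp["n"].to_numpy(dtype=float)
        total = n.sum()
        row: dict = {"group_id": gid, "taxa": sorted(grp["taxon"]), "n": int(total)}
        for iso in ISOTOPES:
            m = grp[f"mean_{iso}"].to_numpy(dtype=float)
            s = grp[f"sd_{iso}"].to_numpy(dtype=float)
            s = np.where(np.isnan(s) & (n == 1), 0.0, s)
            pooled_mean = float((n * m).sum() / total)
            if total < 2:
                pooled_sd = None
            else:
                ss = ((n - 1) * s**2).sum() + (n * (m - pooled_mean) ** 2).sum()
                pooled_sd = float(np.sqrt(ss / (total - 1)))
            row[f"mean_{iso}"] = pooled_mean
            row[f"sd_{iso}"] = pooled_sd
        rows.append(row)
    return pd.DataFrame(rows)
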