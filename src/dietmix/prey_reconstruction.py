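"""Reconstruction of prey counts, lengths and weights from stomach hard parts.

Hard parts recovered from predator stomachs — fish otoliths and bones,
cephalopod beaks — are converted into per-stomach prey occurrences:

* counts: each otolith represents 0.5 fish (otoliths come in pairs);
  diagnostic bones are counted per element, paired elements at 0.5 per
  piece; the highest estimate across structures wins.  Cephalopods are
  counted as max(upper beaks, lower beaks).
* sizes: a structure measurement (otolith length/width, beak rostral or
  hood length, in mm) is converted to prey length via a taxon-specific
  allometric regression, and length to wet weight (g) via a power law
  ``w = c * length**d``.

Regressions are looked up species-first with a fallback to group-level
(family) entries; a taxon with no applicable regression yields a count
without weight (the "no-weight" outcome), never an error.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

STRUCTURES = ("otolith", "bone", "upper_beak", "lower_beak")
MEASUREMENT_KINDS = ("otolith_length", "otolith_width", "rostral_length", "hood_length")

#: Bone elements treated as paired (two per fish) by default.
PAIRED_ELEMENTS = frozenset({"premaxilla", "maxilla", "dentary", "opercula", "cleitrum"})

#: measurement kinds acceptable for each measured structure
_KIND_FOR_STRUCTURE = {
    "otolith": {"otolith_length", "otolith_width"},
    "upper_beak": {"rostral_length", "hood_length"},
    "lower_beak": {"rostral_length", "hood_length"},
}


@dataclass(frozen=True)
class RegressionEntry:
    """Allometric regression for one taxon and one input structure.

    ``length_form`` is 'linear' (L = a + b x) or 'power' (L = a x**b),
    measurement x in mm, length L in mm.  The weight model is always a
    power law w = c L**d with w in g; ``weight_c``/``weight_d`` may be
    NaN when only lengths can be reconstructed.
    """

    taxon: str
    scope: str  # 'species' or 'group'
    input_structure: str
    measurement_kind: str
    length_form: str
    length_a: float
    length_b: float
    weight_c: float = float("nan")
    weight_d: float = float("nan")

    def __post_init__(self) -> None:
        if self.scope not in ("species", "group"):
            raise ValueError(f"unknown regression scope {self.scope!r}")
        if self.input_structure not in STRUCTURES:
            raise ValueError(f"unknown input structure {self.input_structure!r}")
        if self.measurement_kind not in MEASUREMENT_KINDS:
            raise ValueError(f"unknown measurement kind {self.measurement_kind!r}")
        if self.length_form not in ("linear", "power"):
            raise ValueError(f"unknown length form {self.length_form!r}")
        if not (np.isfinite(self.length_a) and np.isfinite(self.length_b)):
            raise ValueError("length coefficients must be finite")

    @property
    def has_weight_model(self) -> bool:
        return np.isfinite(self.weight_c) and np.isfinite(self.weight_d)

    def length_from_measurement(self, measurement: float) -> float:
        if self.length_form == "linear":
            return self.length_a + self.length_b * measurement
        if measurement <= 0:
            raise ValueError("power-law length model needs measurement > 0")
        return self.length_a * measurement**self.length_b

    def measurement_from_length(self, length: float) -> float:
        """Inverse of the length model (used by the data simulator)."""
        if self.length_form == "linear":
            return (length - self.length_a) / self.length_b
        return (length / self.length_a) ** (1.0 / self.length_b)


def normalize_taxon(label: str) -> str:
    """Case-insensitive, whitespace-normalized taxon key."""
    return re.sub(r"\s+", " ", str(label).strip()).lower()


def count_individuals(
    otolith_count: int,
    bone_counts: Mapping[str, int] | None = None,
    paired_elements: frozenset[str] = PAIRED_ELEMENTS,
) -> int:
    """Minimum number of fish consistent with the recovered hard parts.

    Each otolith counts as half a fish (rounded up); paired bone elements
    likewise, unpaired elements one fish per piece; the estimate is the
    maximum over all structures.
    """
    bone_counts = bone_counts or {}
    if otolith_count < 0 or any(c < 0 for c in bone_counts.values()):
        raise ValueError("hard-part counts must be non-negative")
    estimates = []
    if otolith_count:
        estimates.append(math.ceil(0.5 * otolith_count))
    for element, count in bone_counts.items():
        if not count:
            continue
        if element in paired_elements:
            estimates.append(math.ceil(0.5 * count))
        else:
            estimates.append(count)
    if not estimates:
        raise ValueError("no hard parts: cannot infer an individual")
    return max(estimates)


def estimate_size(measurement: float, entry: RegressionEntry) -> tuple[float, float | None]:
    """Back-calculate (prey length mm, weight g or None) from a measurement."""
    if not np.isfinite(measurement) or measurement <= 0:
        raise ValueError(f"measurement must be positive, got {measurement}")
    length = entry.length_from_measurement(measurement)
    if not np.isfinite(length) or length <= 0:
        raise ValueError(f"non-physical reconstructed length {length} mm")
    if not entry.has_weight_model:
        return length, None
    weight = entry.weight_c * length**entry.weight_d
    if not np.isfinite(weight) or weight <= 0:
        raise ValueError(f"non-physical reconstructed weight {weight} g")
    return length, weight


def regressions_from_frame(frame: pd.DataFrame) -> list[RegressionEntry]:
    cols = [
        "taxon", "scope", "input_structure", "measurement_kind",
        "length_form", "length_a", "length_b", "weight_c", "weight_d",
    ]
    entries = []
    for row in frame[cols].itertuples(index=False):
        entries.append(RegressionEntry(*row))
    return entries


def resolve_regression(
    entries: Iterable[RegressionEntry],
    taxon: str,
    family: str | None,
    structure: str,
) -> RegressionEntry | None:
    """Species entry beats group (family) entry beats no-weight (None)."""
    taxon_key = normalize_taxon(taxon)
    family_key = normalize_taxon(family) if family and not pd.isna(family) else None
    group_hit = None
    for entry in entries:
        if entry.input_structure != structure:
            continue
        key = normalize_taxon(entry.taxon)
        if entry.scope == "species" and key == taxon_key:
            return entry
        if entry.scope == "group" and group_hit is None and key in (taxon_key, family_key):
            group_hit = entry
    return group_hit


def _validate_record(row) -> None:
    ident = f"stomach {row.stomach_id!r}, taxon {row.taxon!r}"
    if row.structure not in STRUCTURES:
        raise ValueError(f"unknown structure {row.structure!r} ({ident})")
    if row.structure == "bone" and (pd.isna(row.bone_element) or not str(row.bone_element).strip()):
        raise ValueError(f"bone record without bone_element ({ident})")
    if row.count < 1:
        raise ValueError(f"count must be >= 1 ({ident})")
    if not pd.isna(row.measurement_mm):
        if row.measurement_mm <= 0:
            raise ValueError(f"measurement must be > 0 ({ident})")
        if row.structure == "bone":
            raise ValueError(f"bone measurements are not convertible ({ident})")


def reconstruct(
    records: pd.DataFrame,
    regressions: pd.DataFrame | list[RegressionEntry],
    beak_preference: str = "lower_beak",
    paired_elements: frozenset[str] = PAIRED_ELEMENTS,
) -> pd.DataFrame:
    """Convert a hard-part record table into per-(stomach, taxon) occurrences.

    Parameters
    ----------
    records
        Columns ``stomach_id, taxon, family, class, structure,
        bone_element, measurement_mm, count``; one row per batch of
        identical hard parts.
    regressions
        Allometric regression table (``regressions_from_frame`` schema)
        or a list of :class:`RegressionEntry`.
    beak_preference
        Beak side whose measurements are used when both are measured.

    Returns
    -------
    DataFrame with columns ``stomach_id, taxon, family, class,
    n_individuals, total_weight_g`` (weight NaN where no regression
    applies).  When fewer structures were measurable than individuals
    counted, the total weight is the mean reconstructed individual
    weight times the individual count.
    """
    if isinstance(regressions, pd.DataFrame):
        entries = regressions_from_frame(regressions)
    else:
        entries = list(regressions)

    records = records.copy()
    for col in ("bone_element", "measurement_mm"):
        if col not in records.columns:
            records[col] = np.nan
    records["count"] = records["count"].astype(int)
    for row in records.itertuples(index=False):
        _validate_record(row)

    other_beak = {"lower_beak": "upper_beak", "upper_beak": "lower_beak"}[beak_preference]
    out = []
    records["_key"] = records["taxon"].map(normalize_taxon)
    for (stomach, _key), grp in records.groupby(["stomach_id", "_key"], sort=True):
        taxon = grp["taxon"].iloc[0]
        family = grp["family"].iloc[0] if "family" in grp else np.nan
        klass = grp["class"].iloc[0] if "class" in grp else np.nan

        oto = int(grp.loc[grp.structure == "otolith", "count"].sum())
        bones = (
            grp.loc[grp.structure == "bone"]
            .groupby("bone_element")["count"].sum().to_dict()
        )
        upper = int(grp.loc[grp.structure == "upper_beak", "count"].sum())
        lower = int(grp.loc[grp.structure == "lower_beak", "count"].sum())

        n_fish = count_individuals(oto, bones, paired_elements) if (oto or bones) else 0
        n_ceph = max(upper, lower)
        n = n_fish + n_ceph

        # one weight estimate per measured record row
        measured = grp[grp.measurement_mm.notna()]
        if not measured.empty and (measured.structure == beak_preference).any() and (
            measured.structure == other_beak
        ).any():
            measured = measured[measured.structure != other_beak]
        weights = []
        for row in measured.itertuples(index=False):
            entry = resolve_regression(entries, row.taxon, family, row.structure)
            if entry is None:
                continue
            _, w = estimate_size(row.measurement_mm, entry)
            if w is not None:
                weights.append(w)
        total_w = float(np.mean(weights)) * n if weights else np.nan
        out.append((stomach, taxon, family, klass, n, total_w))

    return pd.DataFrame(
        out,
        columns=["stomach_id", "taxon", "family", "class", "n_individuals", "total_weight_g"],
    )
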