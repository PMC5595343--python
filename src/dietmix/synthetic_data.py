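"""Synthetic stomach-content and isotope datasets with known ground truth.

Every downstream stage of the package is testable without field data:

* the stomach simulator draws a per-stomach prey composition from a
  Dirichlet (the concentration parameter governs how heterogeneous
  stomachs are around the base proportions), multinomial prey counts,
  individual prey lengths from per-taxon normals, and emits the
  hard-part records that those individuals would leave — two otoliths
  per fish, one lower beak per cephalopod — with measurements obtained
  by inverting the taxon's allometric regression, so that noise-free
  reconstruction recovers the generating truth exactly;
* the isotope simulator draws consumer delta values from the exact
  likelihood of the mixing model (mixture mean, quadratic-form process
  variance, optional residual term) at a known diet proportion vector.

``default_gulf_config`` wires the isotope simulator to the published
Gulf of Cadiz four-group source summaries (51 consumers); the
diet-to-tissue discrimination factor has no published value for this
system and must be supplied by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietmix import gulf_cadiz
from dietmix.mixing_model import DEFAULT_SEED, MixingData
from dietmix.prey_reconstruction import RegressionEntry

__all__ = [
    "TaxonSpec",
    "StomachSimConfig",
    "IsotopeSimConfig",
    "SimulatedDataset",
    "simulate_stomach_dataset",
    "simulate_isotope_dataset",
    "default_gulf_config",
]


@dataclass(frozen=True)
class TaxonSpec:
    """One simulated prey taxon.

    ``regression`` is the entry used both to emit measurements (via its
    inverse length model) and, downstream, to reconstruct them; None
    marks an explicitly weightless taxon (counts only).
    """

    name: str
    family: str
    taxon_class: str = "Teleostei"  # 'Teleostei' or 'Cephalopoda'
    length_mean_mm: float = 100.0
    length_sd_mm: float = 10.0
    regression: RegressionEntry | None = None
    no_weight: bool = False

    def __post_init__(self) -> None:
        if self.regression is None and not self.no_weight:
            raise ValueError(
                f"taxon {self.name!r} needs a regression entry or an explicit no_weight flag"
            )

    @property
    def structure(self) -> str:
        return "lower_beak" if self.taxon_class == "Cephalopoda" else "otolith"


@dataclass
class StomachSimConfig:
    n_stomachs: int
    taxa: list[TaxonSpec]
    composition_concentration: float = 1.0
    base_proportions: np.ndarray | None = None  # uniform when omitted
    individuals_per_stomach: int = 77
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_stomachs < 1:
            raise ValueError("n_stomachs must be >= 1")
        if self.composition_concentration <= 0:
            raise ValueError("composition_concentration must be positive")
        if self.individuals_per_stomach < 1:
            raise ValueError("individuals_per_stomach must be >= 1")
        if not self.taxa:
            raise ValueError("need at least one taxon")
        if self.base_proportions is None:
            self.base_proportions = np.full(len(self.taxa), 1.0 / len(self.taxa))
        else:
            self.base_proportions = np.asarray(self.base_proportions, dtype=float)
            if len(self.base_proportions) != len(self.taxa):
                raise ValueError("base_proportions length mismatch")
            if abs(self.base_proportions.sum() - 1.0) > 1e-9 or (self.base_proportions <= 0).any():
                raise ValueError("base_proportions must be positive and sum to 1")


@dataclass
class IsotopeSimConfig:
    true_proportions: np.ndarray
    source_means: np.ndarray  # K x 2 (d13C, d15N)
    source_sds: np.ndarray
    tdf_means: np.ndarray  # K x 2 or length 2
    tdf_sds: np.ndarray
    n_consumers: int = 51
    residual_sd: np.ndarray = field(default_factory=lambda: np.zeros(2))
    group_names: list[str] | None = None
    source_ns: np.ndarray | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        self.true_proportions = np.asarray(self.true_proportions, dtype=float)
        if abs(self.true_proportions.sum() - 1.0) > 1e-12 or (self.true_proportions < 0).any():
            raise ValueError("true_proportions must lie on the simplex (sum 1 within 1e-12)")
        if len(self.true_proportions) < 1:
            raise ValueError("need at least one source group")
        if self.n_consumers < 1:
            raise ValueError("n_consumers must be >= 1")
        self.residual_sd = np.asarray(self.residual_sd, dtype=float)
        if (self.residual_sd < 0).any():
            raise ValueError("residual_sd must be >= 0")

    def to_mixing_data(self, consumers: np.ndarray | None = None) -> MixingData:
        x = consumers if consumers is not None else np.empty((0, 2))
        names = self.group_names or [f"Group {i + 1}" for i in range(len(self.true_proportions))]
        return MixingData(
            consumers=x,
            source_means=self.source_means,
            source_sds=self.source_sds,
            tdf_means=self.tdf_means,
            tdf_sds=self.tdf_sds,
            source_names=list(names),
        )


@dataclass
class SimulatedDataset:
    """Generated records (valid pipeline input) plus the generating truth."""

    records: pd.DataFrame
    truth: pd.DataFrame
    regressions: pd.DataFrame | None = None
    groups: pd.DataFrame | None = None


def _regressions_frame(taxa: list[TaxonSpec]) -> pd.DataFrame:
    rows = []
    for t in taxa:
        r = t.regression
        if r is None:
            continue
        rows.append(
            (r.taxon, r.scope, r.input_structure, r.measurement_kind,
             r.length_form, r.length_a, r.length_b, r.weight_c, r.weight_d)
        )
    return pd.DataFrame(
        rows,
        columns=["taxon", "scope", "input_structure", "measurement_kind",
                 "length_form", "length_a", "length_b", "weight_c", "weight_d"],
    )


def simulate_stomach_dataset(config: StomachSimConfig) -> SimulatedDataset:
    """Simulate a hard-part record table with recoverable ground truth.

    Per stomach, taxon counts are Multinomial(individuals_per_stomach,
    q) with q ~ Dirichlet(concentration * base_proportions).  Each fish
    contributes one record row of two otoliths sharing one measurement
    (one fish, one length); each cephalopod one lower beak.  Truth holds
    the per-(stomach, taxon) individual counts and exact total weights.
    """
    rng = np.random.default_rng(config.seed)
    alpha = config.composition_concentration * config.base_proportions
    records = []
    truth = []
    for s in range(1, config.n_stomachs + 1):
        sid = f"S{s:03d}"
        q = rng.dirichlet(alpha)
        counts = rng.multinomial(config.individuals_per_stomach, q)
        for taxon, n_ind in zip(config.taxa, counts):
            if n_ind == 0:
                continue
            lengths = rng.normal(taxon.length_mean_mm, taxon.length_sd_mm, size=n_ind)
            lengths = np.abs(lengths)  # reflect the rare non-physical draw
            total_weight = np.nan
            if taxon.regression is not None:
                r = taxon.regression
                weights = r.weight_c * lengths**r.weight_d if r.has_weight_model else None
                total_weight = float(weights.sum()) if weights is not None else np.nan
                measurements = [r.measurement_from_length(length) for length in lengths]
            else:
                measurements = [np.nan] * n_ind
            count_per_ind = 2 if taxon.structure == "otolith" else 1
            for m in measurements:
                records.append(
                    (sid, taxon.name, taxon.family, taxon.taxon_class,
                     taxon.structure, np.nan, m, count_per_ind)
                )
            truth.append((sid, taxon.name, taxon.family, taxon.taxon_class,
                          int(n_ind), total_weight))
    records_df = pd.DataFrame(
        records,
        columns=["stomach_id", "taxon", "family", "class",
                 "structure", "bone_element", "measurement_mm", "count"],
    )
    truth_df = pd.DataFrame(
        truth,
        columns=["stomach_id", "taxon", "family", "class",
                 "truth_n_individuals", "truth_total_weight_g"],
    )
    return SimulatedDataset(records=records_df, truth=truth_df,
                            regressions=_regressions_frame(config.taxa))


def simulate_isotope_dataset(config: IsotopeSimConfig) -> SimulatedDataset:
    """Simulate consumer isotope values from the mixing-model likelihood.

    x_ij ~ Normal(sum_k p_k (mu_kj + lambda_kj),
                  sqrt(sum_k p_k^2 (sigma_kj^2 + tau_kj^2) + residual_j^2)),
    independently per isotope.  Truth is the proportion vector.
    """
    rng = np.random.default_rng(config.seed)
    data = config.to_mixing_data()
    p = config.true_proportions
    m = p @ data.corrected_means
    v = (p**2) @ data.corrected_vars + config.residual_sd**2
    x = m + np.sqrt(v) * rng.standard_normal((config.n_consumers, len(m)))
    consumers = pd.DataFrame(
        {
            "sample_id": [f"C{i:03d}" for i in range(1, config.n_consumers + 1)],
            "d13C": x[:, 0],
            "d15N": x[:, 1],
        }
    )
    truth = pd.DataFrame(
        {"group_id": data.source_names, "truth_proportion": p}
    )
    groups = pd.DataFrame(
        {
            "group_id": data.source_names,
            "n": config.source_ns if config.source_ns is not None else np.nan,
            "mean_d13C": data.source_means[:, 0],
            "sd_d13C": data.source_sds[:, 0],
            "mean_d15N": data.source_means[:, 1],
            "sd_d15N": data.source_sds[:, 1],
        }
    )
    return SimulatedDataset(records=consumers, truth=truth, groups=groups)


def default_gulf_config(
    tdf_means,
    tdf_sds,
    true_proportions=(0.52, 0.22, 0.13, 0.13),
    n_consumers: int = gulf_cadiz.N_CONSUMERS,
    residual_sd=(0.0, 0.0),
    seed: int = DEFAULT_SEED,
) -> IsotopeSimConfig:
    """Isotope simulator wired to the published Gulf of Cadiz source groups.

    The discrimination factor is a required argument (per isotope or per
    group x isotope): no defensible default exists for dolphin skin here.
    """
    g = gulf_cadiz.group_summaries()
    return IsotopeSimConfig(
        true_proportions=np.asarray(true_proportions, dtype=float),
        source_means=g[["mean_d13C", "mean_d15N"]].to_numpy(),
        source_sds=g[["sd_d13C", "sd_d15N"]].to_numpy(),
        tdf_means=np.asarray(tdf_means, dtype=float),
        tdf_sds=np.asarray(tdf_sds, dtype=float),
        n_consumers=n_consumers,
        residual_sd=np.asarray(residual_sd, dtype=float),
        group_names=g["group_id"].to_list(),
        source_ns=g["n"].to_numpy(),
        seed=seed,
    )
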