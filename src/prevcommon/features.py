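"""Per-species commonness features and the species-data table.

Six aggregative statistics summarise each species' occurrence records
across the study datasets:

A        sum over datasets-with-occurrences of mean individuals per record
IntraDs  total records / total number of datasets
InterDs  fraction of datasets containing the species
E        mean, over occupied datasets, of (occupied cells / cells in polygon)
F        mean, over occupied datasets, of (time-units with >=1 record / time-units)
HF       as F but counting time-units with at least Thr records

A species with no records gets the all-zero vector. The standardized
(z-scored) features feed every downstream model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import StudyConfig
from .occurrence_io import RecordSet, polygon_cells

__all__ = ["FEATURES", "SpeciesDataTable", "compute_features",
           "standardize", "build_species_table"]

FEATURES = ["A", "IntraDs", "InterDs", "E", "F", "HF"]


@dataclass
class SpeciesDataTable:
    """One row per species: raw features, z-scored features, model columns."""

    table: pd.DataFrame
    log: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return list(self.table["species"])

    @property
    def feature_names(self) -> list[str]:
        return [f for f in FEATURES if f in self.table.columns]

    def matrix(self, exclude: str | None = None) -> np.ndarray:
        """Standardized feature matrix, optionally leaving one feature out."""
        cols = [f"z_{f}" for f in self.feature_names if f != exclude]
        return self.table[cols].to_numpy(float)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SpeciesDataTable":
        return cls(pd.read_csv(path))


def _dataset_cell_counts(cfg: StudyConfig) -> dict[str, int]:
    return {ds: polygon_cells(poly, cfg.cell_resolution) for ds, poly in cfg.datasets}


def compute_features(rs: RecordSet, species: str, cfg: StudyConfig,
                     cell_counts: dict[str, int] | None = None) -> dict[str, float]:
    """Evaluate the six features for one species.

    ``rs`` must carry context columns (dataset, cell, time-unit). Datasets
    with no records of the species are excluded from the means whose
    denominator is "datasets with occurrences" (A, E, F, HF); IntraDs and
    InterDs divide by the total dataset count.
    """
    if cell_counts is None:
        cell_counts = _dataset_cell_counts(cfg)
    n_datasets = len(cfg.datasets)
    n_units = cfg.n_time_units
    sub = rs.records[rs.records["species"] == species]
    if len(sub) == 0:
        return {f: 0.0 for f in FEATURES}

    a_terms, e_terms, f_terms, hf_terms = [], [], [], []
    for ds, grp in sub.groupby("dataset"):
        a_terms.append(grp["count"].sum() / len(grp))
        e_terms.append(len(grp[["cell_x", "cell_y"]].drop_duplicates()) / cell_counts[ds])
        per_unit = grp.groupby("time_unit").size()
        f_terms.append(len(per_unit) / n_units)
        thr_ok = per_unit > cfg.hf_threshold if cfg.hf_strict else per_unit >= cfg.hf_threshold
        hf_terms.append(int(thr_ok.sum()) / n_units)

    n_occ = len(a_terms)
    a_val = float(np.sum(a_terms))
    if cfg.a_mean:
        a_val /= n_occ
    return {
        "A": a_val,
        "IntraDs": len(sub) / n_datasets,
        "InterDs": n_occ / n_datasets,
        "E": float(np.mean(e_terms)),
        "F": float(np.mean(f_terms)),
        "HF": float(np.mean(hf_terms)),
    }


def standardize(sdt: SpeciesDataTable) -> SpeciesDataTable:
    """Z-score each feature column over species (sample standard deviation).

    Zero-variance columns become all zeros. Raw values are retained
    alongside the ``z_``-prefixed standardized columns. Idempotent on the
    raw columns (the z-columns are recomputed from raw each call).
    """
    df = sdt.table.copy()
    if len(df) < 2:
        raise ValueError("standardisation requires at least 2 species")
    for f in [c for c in FEATURES if c in df.columns]:
        x = df[f].to_numpy(float)
        sd = x.std(ddof=1)
        # relative guard: identical values can leave a ~1e-17 residual std
        if sd <= 1e-12 * max(1.0, float(np.abs(x).max())):
            df[f"z_{f}"] = np.zeros_like(x)
        else:
            df[f"z_{f}"] = (x - x.mean()) / sd
    return SpeciesDataTable(df, list(sdt.log))


def build_species_table(rs: RecordSet, species_list: list[str],
                        cfg: StudyConfig) -> SpeciesDataTable:
    """Compute the species-data table: one row per listed species, in order."""
    if not species_list:
        raise ValueError("species_list is empty")
    if len(set(species_list)) != len(species_list):
        raise ValueError("species_list contains duplicate names")
    cell_counts = _dataset_cell_counts(cfg)
    log: list[str] = []
    present = set(rs.records["species"].unique())
    rows = []
    for sp in species_list:
        if sp not in present:
            log.append(f"species '{sp}' has no records; zero feature vector")
        rows.append({"species": sp, **compute_features(rs, sp, cfg, cell_counts)})
    return standardize(SpeciesDataTable(pd.DataFrame(rows), log))
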