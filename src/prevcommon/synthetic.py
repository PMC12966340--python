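"""Synthetic multi-area occurrence tables with planted commonness tiers.

The generator emulates the statistical structure the commonness features
assume: each tier controls how many areas a species occupies (InterDs),
how much of each area it covers (E), in how many years it is active (F),
how many records an active year yields (IntraDs, HF), and how many
individuals a record reports (A). Very common species are abundant,
widespread and persistently observed; rare species are sparse on every
axis and form a minority of the list, so they surface as anomalies.

Areas are axis-aligned rectangular polygons laid out on the analysis
grid; records are placed uniformly inside a per-species subset of each
occupied area's grid cells. Output is deterministic given the seed and
uses the same formats as the ingestion module.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import box

from .classify import FAIRLY_COMMON, RARE, VERY_COMMON
from .config import StudyConfig, dump_config
from .occurrence_io import RecordSet, write_occurrences

__all__ = ["TierParams", "SimulationConfig", "generate", "make_fixture",
           "study_config_for", "FIXTURES"]


@dataclass(frozen=True)
class TierParams:
    """Generative knobs of one commonness tier.

    ``heterogeneity`` holds per-knob log-normal sigmas for the per-species
    jitter (order: occupancy, records, individuals, cells, years). The
    sigmas are largest for the rare tier, especially on the abundance
    knobs: rarity manifests as low values in *different* features from
    species to species (a colonial species may be seen rarely but in large
    groups), so rare species break the feature correlations of the common
    mass and form small dispersed groups rather than one compact cluster —
    the structure anomaly scoring relies on.
    """

    occupancy: float          # probability a dataset hosts the species
    records_per_year: float   # Poisson mean records in an active year
    individuals: float        # mean individuals per record (shifted Poisson)
    cell_fraction: float      # fraction of an area's cells the species uses
    active_years: float       # fraction of time-units with any activity
    heterogeneity: tuple[float, float, float, float, float] = (0.2,) * 5
    n_guilds: int = 1         # distinct ecological sub-groups within the tier
    guild_sigma: float = 0.0  # log-normal spread of guild base profiles

    def draw(self, rng: np.random.Generator) -> "TierParams":
        """Per-species realisation: independent log-normal jitter per knob."""
        j = np.exp(rng.normal(0.0, np.asarray(self.heterogeneity)))
        return TierParams(
            occupancy=float(np.clip(self.occupancy * j[0], 0.02, 1.0)),
            records_per_year=float(self.records_per_year * j[1]),
            individuals=float(max(1.0, self.individuals * j[2])),
            cell_fraction=float(np.clip(self.cell_fraction * j[3], 0.005, 1.0)),
            active_years=float(np.clip(self.active_years * j[4], 0.05, 1.0)),
            heterogeneity=(0.0,) * 5,
        )

    def guild_profiles(self, rng: np.random.Generator) -> list["TierParams"]:
        """Base profiles of the tier's guilds (one when the tier is uniform).

        Guilds model ecologically distinct sub-groups of a commonness tier
        (waders vs passerines vs odonates ...) that share an overall
        commonness level but differ in which features run higher or lower.
        """
        if self.n_guilds <= 1:
            return [self]
        out = []
        for _ in range(self.n_guilds):
            j = np.exp(rng.normal(0.0, self.guild_sigma, size=5))
            out.append(TierParams(
                occupancy=float(np.clip(self.occupancy * j[0], 0.02, 1.0)),
                records_per_year=float(self.records_per_year * j[1]),
                individuals=float(max(1.0, self.individuals * j[2])),
                cell_fraction=float(np.clip(self.cell_fraction * j[3], 0.005, 1.0)),
                active_years=float(np.clip(self.active_years * j[4], 0.05, 1.0)),
                heterogeneity=self.heterogeneity,
            ))
        return out


@dataclass
class SimulationConfig:
    """Default study conditions: 20 areas of 10x10 cells, a 2016-2025 frame,
    and 60/50/40 species per tier (rare species 26.7% of the list)."""

    n_datasets: int = 20
    polygon_size: float = 0.1           # degrees per side
    cell_resolution: float = 0.01
    n_species: dict[str, int] = field(default_factory=lambda: {
        VERY_COMMON: 60, FAIRLY_COMMON: 50, RARE: 40})
    tiers: dict[str, TierParams] = field(default_factory=lambda: {
        VERY_COMMON: TierParams(1.0, 9.5, 3.5, 0.5, 0.9,
                                heterogeneity=(0.0, 0.06, 0.22, 0.06, 0.04)),
        FAIRLY_COMMON: TierParams(0.5, 5.0, 2.5, 0.2, 0.6,
                                  heterogeneity=(0.22, 0.28, 0.3, 0.28, 0.2)),
        RARE: TierParams(0.1, 1.5, 2.5, 0.05, 0.3,
                         heterogeneity=(0.3, 0.8, 1.2, 0.5, 0.4))})
    time_start: _dt.date = _dt.date(2016, 1, 1)
    time_end: _dt.date = _dt.date(2025, 12, 31)
    seed: int = 42

    def __post_init__(self) -> None:
        for name, t in self.tiers.items():
            if not 0 <= t.occupancy <= 1 or not 0 <= t.cell_fraction <= 1 \
                    or not 0 <= t.active_years <= 1:
                raise ValueError(f"tier '{name}' fractions must lie in [0, 1]")
            if t.records_per_year < 0 or t.individuals < 1:
                raise ValueError(f"tier '{name}' rates out of range")

    def polygons(self) -> list[tuple[str, object]]:
        """Disjoint rectangles along the longitude axis (one per dataset)."""
        out = []
        for i in range(self.n_datasets):
            x0 = i * 2 * self.polygon_size
            out.append((f"area_{i:02d}",
                        box(x0, 43.0, x0 + self.polygon_size, 43.0 + self.polygon_size)))
        return out


def study_config_for(sim: SimulationConfig, **overrides) -> StudyConfig:
    """A StudyConfig matching the simulated frame, grid, and areas."""
    kw = dict(time_start=sim.time_start, time_end=sim.time_end,
              cell_resolution=sim.cell_resolution, datasets=sim.polygons(),
              seed=sim.seed)
    kw.update(overrides)
    return StudyConfig(**kw)


def generate(sim: SimulationConfig) -> tuple[RecordSet, pd.DataFrame]:
    """Draw an occurrence table and its ground-truth tier labels.

    For each species x occupied dataset, a fixed cell subset and active-year
    subset are sampled; each active year contributes Poisson-many records
    placed uniformly in the cell subset, each reporting 1 + Poisson(mean-1)
    individuals. Deterministic given the seed.
    """
    rng = np.random.default_rng(sim.seed)
    res = sim.cell_resolution
    polys = sim.polygons()
    years = list(range(sim.time_start.year, sim.time_end.year + 1))

    rows = []
    truth = []
    for tier in (VERY_COMMON, FAIRLY_COMMON, RARE):
        base = sim.tiers[tier]
        guilds = base.guild_profiles(rng)
        for i in range(sim.n_species[tier]):
            sp = f"{tier}_{i:03d}"
            truth.append({"species": sp, "tier": tier})
            params = guilds[i % len(guilds)].draw(rng)
            for ds, poly in polys:
                if rng.random() >= params.occupancy:
                    continue
                minx, miny, maxx, maxy = poly.bounds
                nx = int(round((maxx - minx) / res))
                ny = int(round((maxy - miny) / res))
                n_cells = max(1, round(params.cell_fraction * nx * ny))
                cells = rng.choice(nx * ny, size=n_cells, replace=False)
                # per-dataset binomial activity keeps F/HF continuous across
                # species instead of piling on a few discrete values
                n_active = rng.binomial(len(years), params.active_years)
                if n_active == 0:
                    continue
                active = rng.choice(len(years), size=n_active, replace=False)
                for yi in active:
                    for _ in range(rng.poisson(params.records_per_year)):
                        c = int(rng.choice(cells))
                        cx, cy = c % nx, c // nx
                        lon = minx + (cx + rng.random()) * res
                        lat = miny + (cy + rng.random()) * res
                        day = int(rng.integers(0, 365))
                        date = _dt.date(years[yi], 1, 1) + _dt.timedelta(days=day)
                        rows.append((sp, round(lon, 6), round(lat, 6), date,
                                     1 + int(rng.poisson(params.individuals - 1)), ds))
    df = pd.DataFrame(rows, columns=["species", "lon", "lat", "date", "count",
                                     "dataset"])
    return RecordSet(df, [f"synthetic: seed={sim.seed}"]), pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# named fixtures

def _tiny_records() -> tuple[pd.DataFrame, list[tuple[str, object]]]:
    """Hand-checkable fixture: 1 species, 2 areas (one empty), 10-cell grid.

    Area ds1 spans 10 x 1 cells at 0.01 deg. The species has 4 records
    there (8 individuals total) in 2 distinct cells: 3 records in 2016 and
    1 in 2017 of the 2016-2025 frame. With Thr = 3 the features evaluate
    by hand to A=2.0, IntraDs=2.0, InterDs=0.5, E=0.2, F=0.2, HF=0.1.
    """
    rows = [
        ("Ardea tinyensis", 0.005, 0.005, _dt.date(2016, 5, 1), 3, "ds1"),
        ("Ardea tinyensis", 0.006, 0.005, _dt.date(2016, 6, 1), 2, "ds1"),
        ("Ardea tinyensis", 0.015, 0.005, _dt.date(2016, 7, 1), 2, "ds1"),
        ("Ardea tinyensis", 0.015, 0.004, _dt.date(2017, 5, 1), 1, "ds1"),
    ]
    df = pd.DataFrame(rows, columns=["species", "lon", "lat", "date", "count",
                                     "dataset"])
    polys = [("ds1", box(0.0, 0.0, 0.1, 0.01)), ("ds2", box(0.2, 0.0, 0.3, 0.01))]
    return df, polys


FIXTURES = ("default", "tiny", "degenerate")


def make_fixture(name: str, out_dir: str | Path, seed: int = 42) -> dict[str, Path]:
    """Write a named fixture (occurrences, polygons, config, truth) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {k: out / f"{k}.csv" for k in ("occurrences", "truth")}
    paths["areas"] = out / "areas.geojson"
    paths["config"] = out / "config.yaml"

    if name == "default":
        sim = SimulationConfig(seed=seed)
        rs, truth = generate(sim)
        polys = sim.polygons()
        cfg = study_config_for(sim)
    elif name == "tiny":
        df, polys = _tiny_records()
        rs = RecordSet(df, ["fixture: tiny"])
        truth = pd.DataFrame({"species": ["Ardea tinyensis"], "tier": [FAIRLY_COMMON]})
        cfg = StudyConfig(time_start=_dt.date(2016, 1, 1),
                          time_end=_dt.date(2025, 12, 31),
                          hf_threshold=3, datasets=polys, seed=seed)
    elif name == "degenerate":
        # 12 species with byte-identical record patterns -> identical feature
        # rows, zero-variance standardisation, tied quantiles downstream
        base, polys = _tiny_records()
        frames = []
        names = [f"Clonus identicus {i:02d}" for i in range(12)]
        for nm in names:
            df = base.copy()
            df["species"] = nm
            frames.append(df)
        rs = RecordSet(pd.concat(frames, ignore_index=True), ["fixture: degenerate"])
        truth = pd.DataFrame({"species": names, "tier": FAIRLY_COMMON})
        cfg = StudyConfig(time_start=_dt.date(2016, 1, 1),
                          time_end=_dt.date(2025, 12, 31),
                          hf_threshold=3, datasets=polys, seed=seed)
    else:
        raise ValueError(f"unknown fixture '{name}' (choose from {FIXTURES})")

    write_occurrences(rs, paths["occurrences"])
    truth.to_csv(paths["truth"], index=False)
    features = [{"type": "Feature", "properties": {"dataset_id": ds},
                 "geometry": json.loads(json.dumps(poly.__geo_interface__))}
                for ds, poly in polys]
    paths["areas"].write_text(json.dumps(
        {"type": "FeatureCollection", "features": features}))
    dump_config(cfg, paths["config"])
    return paths
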