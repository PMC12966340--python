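"""Study and simulation configuration.

A study configuration fixes everything the feature definitions depend on:
the analysis time frame, the time-unit over which presence is assessed
(one calendar year by default), the spatial aggregation resolution used to
grid each area, the high-frequency threshold ``Thr``, the list of dataset
polygons, and the cluster-count search range.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml
from shapely.geometry import base as _shapely_base

__all__ = ["VAEConfig", "StudyConfig", "load_config", "dump_config"]


@dataclass(frozen=True)
class VAEConfig:
    """Hyperparameters of the variational-autoencoder branch.

    The architecture search grows the two hidden layers one neuron at a
    time starting from ``start_widths`` until no candidate improves the
    mean reconstruction log-probability by more than ``grow_tol`` nats or
    ``max_width`` is reached; the latent dimension is swept over
    ``latent_dims``.
    """

    start_widths: tuple[int, int] = (2, 2)
    max_width: int = 8
    latent_dims: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    epochs: int = 300
    learning_rate: float = 0.01
    grow_tol: float = 1e-3
    n_samples: int = 100       # posterior samples L for reported scores
    eval_samples: int = 20     # cheaper L used inside the architecture search
    max_restarts: int = 3      # restarts with halved learning rate on non-finite loss


@dataclass
class StudyConfig:
    """Parameters of one commonness-assessment study."""

    time_start: _dt.date = _dt.date(2016, 1, 1)
    time_end: _dt.date = _dt.date(2025, 12, 31)
    cell_resolution: float = 0.01   # decimal degrees
    hf_threshold: int = 5           # Thr: records per time-unit counted as "many"
    hf_strict: bool = False         # True -> strictly more than Thr
    a_mean: bool = False            # True -> divide A by the number of occupied datasets
    datasets: list[tuple[str, _shapely_base.BaseGeometry]] = field(default_factory=list)
    k_min: int = 3
    n_classes: int = 3
    gradient_mode: bool = False
    seed: int = 42
    restarts: int = 10
    max_iter: int = 300
    min_cluster_frac: float = 0.5   # "sparse" = size < max(2, ceil(frac*n/K))
    vae: VAEConfig = field(default_factory=VAEConfig)

    def __post_init__(self) -> None:
        if self.time_start >= self.time_end:
            raise ValueError("time_start must precede time_end")
        if self.cell_resolution <= 0:
            raise ValueError("cell_resolution must be positive")
        if self.hf_threshold < 1:
            raise ValueError("hf_threshold must be >= 1")
        if self.k_min < 2:
            raise ValueError("k_min must be >= 2")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    # -- temporal grid -----------------------------------------------------
    @property
    def n_time_units(self) -> int:
        """Number of one-year time-units, start through end year inclusive."""
        return self.time_end.year - self.time_start.year + 1

    def time_unit_index(self, date: _dt.date) -> int:
        return date.year - self.time_start.year

    def k_max(self, n_species: int) -> int:
        return n_species // 2

    @property
    def dataset_ids(self) -> list[str]:
        return [d for d, _ in self.datasets]

    def with_seed(self, seed: int) -> "StudyConfig":
        return replace(self, seed=seed)


_SCALARS = (
    "cell_resolution", "hf_threshold", "hf_strict", "a_mean", "k_min",
    "n_classes", "gradient_mode", "seed", "restarts", "max_iter",
    "min_cluster_frac",
)


def load_config(path: str | Path) -> StudyConfig:
    """Read a flat key/value study configuration (YAML mapping)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kw: dict = {}
    for key in ("time_start", "time_end"):
        if key in raw:
            v = raw[key]
            kw[key] = v if isinstance(v, _dt.date) else _dt.date.fromisoformat(str(v))
    for key in _SCALARS:
        if key in raw:
            kw[key] = raw[key]
    vae_kw = {k[4:]: v for k, v in raw.items() if k.startswith("vae_")}
    if vae_kw:
        for tup in ("start_widths", "latent_dims"):
            if tup in vae_kw:
                vae_kw[tup] = tuple(vae_kw[tup])
        kw["vae"] = VAEConfig(**vae_kw)
    return StudyConfig(**kw)


def dump_config(cfg: StudyConfig, path: str | Path) -> None:
    """Write the scalar fields of a configuration as a flat YAML mapping."""
    out = {
        "time_start": cfg.time_start.isoformat(),
        "time_end": cfg.time_end.isoformat(),
    }
    for key in _SCALARS:
        out[key] = getattr(cfg, key)
    for k, v in vars(cfg.vae).items():
        out[f"vae_{k}"] = list(v) if isinstance(v, tuple) else v
    Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
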