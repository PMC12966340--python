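"""Commonness classification of clusters and quantile groups.

Each cluster (or VAE score group) centroid is labelled per feature: H if
the centroid value exceeds the 75th percentile of that feature across all
species, L if it falls below the 25th percentile, M otherwise (boundary
values are M, since both conditions are strict). A cluster whose H labels
strictly outnumber both other labels is a high-commonness cluster and its
species become "very common"; an L majority yields "rare"; everything else
is "fairly common". Labelling runs in the standardized feature space and
is therefore invariant to the monotone z-scoring.

The three classes map to prevalence probabilities 0.2 / 0.5 / 0.8 used as
multiplicative prior weights in Bayesian niche models. An extended
gradient refines this: the prevalence of a centroid with nH high-valued
and nL low-valued features is 0.5 + 0.05 * (nH - nL), spanning the
[0.2, 0.8] lattice in steps of 0.05 (six levels each side of full-medium).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cluster import ClusteringResult
from .features import SpeciesDataTable

__all__ = [
    "RARE", "FAIRLY_COMMON", "VERY_COMMON", "CLASSES", "CentroidLabels",
    "feature_quartiles", "label_centroid", "classify_cluster",
    "gradient_score", "classify_from_clustering", "classify_from_vae",
    "ensemble", "map_prevalence", "PREVALENCE",
]

RARE = "rare"
FAIRLY_COMMON = "fairly_common"
VERY_COMMON = "very_common"
CLASSES = [RARE, FAIRLY_COMMON, VERY_COMMON]

PREVALENCE = {RARE: 0.2, FAIRLY_COMMON: 0.5, VERY_COMMON: 0.8}


@dataclass(frozen=True)
class CentroidLabels:
    labels: tuple[str, ...]      # per-feature, each in {"H", "M", "L"}

    @property
    def nH(self) -> int:
        return self.labels.count("H")

    @property
    def nM(self) -> int:
        return self.labels.count("M")

    @property
    def nL(self) -> int:
        return self.labels.count("L")


def feature_quartiles(table: SpeciesDataTable,
                      exclude: str | None = None) -> np.ndarray:
    """Per-feature (p25, p75) over all species, on standardized values.

    Returns an array of shape (d, 2). Linear-interpolation quantile
    convention; invariant to species order.
    """
    X = table.matrix(exclude=exclude)
    if X.shape[0] < 4:
        raise ValueError("quartiles require at least 4 species")
    p25 = np.percentile(X, 25, axis=0)
    p75 = np.percentile(X, 75, axis=0)
    return np.column_stack([p25, p75])


def label_centroid(centroid: np.ndarray, q: np.ndarray) -> CentroidLabels:
    """H/M/L label per feature of one centroid against the global quartiles."""
    centroid = np.asarray(centroid, dtype=float)
    if centroid.shape[0] != q.shape[0]:
        raise ValueError("centroid and quartile dimensions differ")
    labels = tuple(
        "H" if v > hi else ("L" if v < lo else "M")
        for v, (lo, hi) in zip(centroid, q)
    )
    return CentroidLabels(labels)


def classify_cluster(labels: CentroidLabels) -> str:
    """Majority vote over the centroid's H/M/L labels; ties are medium."""
    if labels.nH > labels.nM and labels.nH > labels.nL:
        return VERY_COMMON
    if labels.nL > labels.nM and labels.nL > labels.nH:
        return RARE
    return FAIRLY_COMMON


def gradient_score(labels: CentroidLabels) -> float:
    """Extended-gradient prevalence: 0.5 + 0.05*(nH - nL), clipped to [0.2, 0.8]."""
    return float(np.clip(0.5 + 0.05 * (labels.nH - labels.nL), 0.2, 0.8))


def _classify_groups(table: SpeciesDataTable, groups: np.ndarray,
                     exclude: str | None = None):
    """Shared core: centroid -> labels -> class per group index."""
    X = table.matrix(exclude=exclude)
    q = feature_quartiles(table, exclude=exclude)
    classes = np.empty(len(groups), dtype=object)
    gradients = np.full(len(groups), np.nan)
    for g in np.unique(groups):
        members = groups == g
        centroid = X[members].mean(axis=0)
        lab = label_centroid(centroid, q)
        classes[members] = classify_cluster(lab)
        gradients[members] = gradient_score(lab)
    return classes, gradients


def classify_from_clustering(table: SpeciesDataTable, clustering: ClusteringResult,
                             exclude: str | None = None):
    """Per-species class (and gradient prevalence) from a clustering.

    Species inherit the class of their cluster; a singleton cluster is
    classified from its single vector. Empty commonness classes are a
    legitimate outcome (e.g. no cluster with an L majority means no
    species is labelled rare).
    """
    return _classify_groups(table, clustering.best.assignments, exclude=exclude)


def classify_from_vae(table: SpeciesDataTable, groups: np.ndarray,
                      exclude: str | None = None):
    """Per-species class from VAE score quantile groups (same centroid rule)."""
    return _classify_groups(table, np.asarray(groups, dtype=int), exclude=exclude)


def ensemble(label_a, label_b, label_c) -> np.ndarray | str:
    """Majority vote over the three model labels; no majority -> fairly common.

    Accepts scalars or aligned arrays.
    """
    scalar = isinstance(label_a, str)
    a = np.atleast_1d(np.asarray(label_a, dtype=object))
    b = np.atleast_1d(np.asarray(label_b, dtype=object))
    c = np.atleast_1d(np.asarray(label_c, dtype=object))
    out = np.empty(a.shape, dtype=object)
    for i in range(len(a)):
        votes = [a[i], b[i], c[i]]
        winner = FAIRLY_COMMON
        for cls in CLASSES:
            if votes.count(cls) >= 2:
                winner = cls
                break
        out[i] = winner
    return out[0] if scalar else out


def map_prevalence(cls) -> np.ndarray | float:
    """Map class labels to the 0.2 / 0.5 / 0.8 prevalence probabilities."""
    if isinstance(cls, str):
        return PREVALENCE[cls]
    return np.asarray([PREVALENCE[c] for c in cls], dtype=float)
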