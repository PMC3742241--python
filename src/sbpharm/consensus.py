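"""Consensus pharmacophore assembly.

Features pooled from an ensemble of aligned complexes are clustered
(same kind only, greedy agglomerative on centroid distance), each cluster is
scored by its statistical frequency — the percentage of distinct complexes
represented among its members — and clusters above a frequency threshold are
merged with excluded-volume spheres into the screenable consensus model.

With an ensemble of N complexes a cluster present in ``count`` of them has
frequency ``round-half-up(100 * count / N)``; the default retention rule is
strictly greater than 60 %.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import (ExcludedVolume, PharmFeature, greedy_merge)

#: cluster-label prefix per feature kind (H1, D1, A1, Pos1, Neg1, ...)
KIND_PREFIX = {"HYD": "H", "HBD": "D", "HBA": "A", "POS": "Pos", "NEG": "Neg"}
#: order in which kinds are listed in reports
KIND_ORDER = {"HBA": 0, "HBD": 1, "HYD": 2, "POS": 3, "NEG": 4}


@dataclass
class FeatureCluster:
    """A cluster of same-kind features pooled across complexes."""

    cluster_id: str
    kind: str
    members: list[PharmFeature]
    centroid: np.ndarray
    count: int       # distinct complexes represented
    frequency: int   # integer percent

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)

    @property
    def tolerance(self) -> float:
        return max(m.tolerance for m in self.members)


@dataclass
class ModelFeature:
    """One feature of a built consensus model."""

    feature_id: str
    kind: str
    center: np.ndarray
    tolerance: float
    mandatory: bool = True
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)


@dataclass
class ConsensusPharmacophore:
    """The screenable consensus model: retained features plus excluded
    volumes."""

    features: list[ModelFeature]
    excluded_volumes: list[ExcludedVolume] = field(default_factory=list)
    n_complexes: int = 0
    threshold: int = 60
    provenance: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "meta": {
                "n_complexes": self.n_complexes,
                "threshold": self.threshold,
                "provenance": list(self.provenance),
            },
            "features": [
                {"id": f.feature_id, "kind": f.kind,
                 "center": f.center.tolist(), "tolerance": f.tolerance,
                 "mandatory": f.mandatory, "weight": f.weight}
                for f in self.features
            ],
            "excluded_volumes": [
                {"center": ev.center.tolist(), "radius": ev.radius,
                 "source_residue": ev.source_residue}
                for ev in self.excluded_volumes
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusPharmacophore":
        feats = [ModelFeature(f["id"], f["kind"], np.array(f["center"]),
                              f["tolerance"], f.get("mandatory", True),
                              f.get("weight", 1.0))
                 for f in d["features"]]
        evs = [ExcludedVolume(np.array(e["center"]), e["radius"],
                              e.get("source_residue", ""))
               for e in d.get("excluded_volumes", [])]
        meta = d.get("meta", {})
        return cls(feats, evs, meta.get("n_complexes", 0),
                   meta.get("threshold", 60), meta.get("provenance", []))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "ConsensusPharmacophore":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def frequency(count: int, n_complexes: int) -> int:
    """Statistical frequency: percentage of complexes containing the
    feature, rounded half-up to an integer percent."""
    if n_complexes <= 0 or not (0 <= count <= n_complexes):
        raise ValueError("bad count")
    return int(np.floor(100.0 * count / n_complexes + 0.5))


def cluster_features(features: list[PharmFeature],
                     cluster_radius: float = 2.0,
                     n_complexes: int | None = None) -> list[FeatureCluster]:
    """Greedy agglomerative, same-kind-only clustering of pooled features.

    The two same-kind clusters with minimal centroid distance are merged
    iteratively while that distance is at most `cluster_radius`.  A cluster's
    count is the number of distinct source complexes among its members (a
    complex contributing two coincident features counts once).  Labels run
    per kind in descending count order (H1, H2, ..., D1, ...), ties broken by
    lexicographic centroid order.
    """
    if not features:
        return []
    if n_complexes is None:
        n_complexes = len({f.complex_id for f in features})

    clusters: list[FeatureCluster] = []
    by_kind: dict[str, list[PharmFeature]] = {}
    for f in features:
        by_kind.setdefault(f.kind, []).append(f)

    for kind, group in by_kind.items():
        # canonical input order makes the greedy walk permutation-invariant
        group = sorted(group, key=lambda f: (tuple(np.round(f.center, 9)),
                                             f.complex_id))
        pts = np.array([f.center for f in group])
        cents, members = greedy_merge(pts, cluster_radius, inclusive=True)
        for cent, mem in zip(cents, members):
            ms = [group[i] for i in sorted(mem)]
            count = len({m.complex_id for m in ms})
            clusters.append(FeatureCluster(
                cluster_id="", kind=kind, members=ms, centroid=cent,
                count=count, frequency=frequency(count, n_complexes)))

    # label per kind by descending count, ties by centroid lex order
    clusters.sort(key=lambda c: (KIND_ORDER.get(c.kind, 99), -c.count,
                                 tuple(np.round(c.centroid, 9))))
    counters: dict[str, int] = {}
    for c in clusters:
        k = counters.get(c.kind, 0) + 1
        counters[c.kind] = k
        c.cluster_id = f"{KIND_PREFIX[c.kind]}{k}"
    return clusters


def select_clusters(clusters: list[FeatureCluster],
                    threshold: int = 60) -> list[FeatureCluster]:
    """Retain clusters whose frequency is strictly above `threshold`
    percent, preserving order."""
    selected = [c for c in clusters if c.frequency > threshold]
    if not selected:
        warnings.warn("model has no features", stacklevel=2)
    return selected


def build_model(selected: list[FeatureCluster],
                evs: list[ExcludedVolume] | None = None,
                meta: dict | None = None) -> ConsensusPharmacophore:
    """Assemble the consensus pharmacophore from retained clusters.

    Feature centers are cluster centroids; the tolerance of a feature is the
    maximum member tolerance.
    """
    if not selected:
        raise ValueError("empty model")
    meta = meta or {}
    feats = [ModelFeature(c.cluster_id, c.kind, c.centroid, c.tolerance)
             for c in selected]
    return ConsensusPharmacophore(
        features=feats,
        excluded_volumes=list(evs or []),
        n_complexes=meta.get("n_complexes", 0),
        threshold=meta.get("threshold", 60),
        provenance=meta.get("provenance", []),
    )
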