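"""Mapping ligand conformers onto a consensus pharmacophore.

A conformer maps the model when an injective, kind-compatible assignment of
its candidate feature points onto *all* model features exists such that,
after least-squares superposition of the matched point sets, every matched
point lies inside its feature's tolerance sphere and no ligand heavy atom
penetrates an excluded volume.  Mapping quality is the geometric fit value

    fit = sum_f w_f * max(0, 1 - (d_f / t_f)^2)

(d_f displacement, t_f tolerance, w_f weight), maximal when every point sits
exactly on its feature center.  Screening ranks library molecules by the
best fit over their conformers.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .complex_io import LigandMolecule
from .consensus import ConsensusPharmacophore
from .features import PharmFeature, ligand_feature_points
from .geometry import RigidTransform, kabsch, rmsd_no_fit

logger = logging.getLogger(__name__)


@dataclass
class ConformerSet:
    """A molecule with one shared topology and several coordinate sets."""

    molecule_id: str
    topology: LigandMolecule
    conformers: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.topology.atoms)
        self.conformers = [np.asarray(c, dtype=float) for c in self.conformers]
        for c in self.conformers:
            if c.shape != (n, 3):
                raise ValueError("conformer does not match topology atom count")


@dataclass
class MappingResult:
    """Best assignment of one conformer onto the model."""

    assignment: list[tuple[str, int]] = field(default_factory=list)
    transform: RigidTransform = field(default_factory=RigidTransform.identity)
    displacements: np.ndarray = field(default_factory=lambda: np.zeros(0))
    fit: float = 0.0
    ev_clash: bool = False
    conformer_index: int = -1

    @property
    def valid(self) -> bool:
        return bool(self.assignment)


@dataclass
class ScreenHit:
    molecule_id: str
    best: MappingResult
    rank: int = 0


def fit_value(displacements, tolerances, weights=None) -> float:
    """Weighted quadratic-falloff geometric fit value (see module docs)."""
    d = np.asarray(displacements, dtype=float)
    t = np.asarray(tolerances, dtype=float)
    if weights is None:
        w = np.ones_like(d)
    else:
        w = np.asarray(weights, dtype=float)
    if not (d.shape == t.shape == w.shape):
        raise ValueError("arity: displacement/tolerance/weight lengths differ")
    if np.any(t <= 0):
        raise ValueError("tolerances must be positive")
    return float(np.sum(w * np.maximum(0.0, 1.0 - (d / t) ** 2)))


def _assignments(model: ConsensusPharmacophore,
                 points: list[PharmFeature]):
    """Yield injective kind-compatible assignments covering every model
    feature, as lists of (model feature index, ligand point index)."""
    by_kind: dict[str, list[int]] = {}
    for j, p in enumerate(points):
        by_kind.setdefault(p.kind, []).append(j)
    model_by_kind: dict[str, list[int]] = {}
    for i, f in enumerate(model.features):
        model_by_kind.setdefault(f.kind, []).append(i)

    per_kind = []
    for kind, fidx in model_by_kind.items():
        cand = by_kind.get(kind, [])
        if len(cand) < len(fidx):
            return  # a required kind cannot be covered
        per_kind.append((fidx, list(itertools.permutations(cand, len(fidx)))))

    for combo in itertools.product(*(perms for _, perms in per_kind)):
        pairs = []
        for (fidx, _), chosen in zip(per_kind, combo):
            pairs.extend(zip(fidx, chosen))
        yield pairs


def map_conformer(conformer: np.ndarray,
                  ligand_points: list[PharmFeature],
                  model: ConsensusPharmacophore,
                  conformer_index: int = 0) -> MappingResult:
    """Best mapping of one conformer onto the model.

    `ligand_points` are the chemistry-only candidate features evaluated at
    this conformer's coordinates.  All injective kind-compatible assignments
    onto all model features are enumerated; each is superposed by Kabsch
    (centroid translation for fewer than three features), displacements are
    recomputed in the model frame, and assignments violating a tolerance or
    clashing with an excluded volume are rejected.  Returns the
    fit-maximizing assignment, or an invalid result with fit 0.
    """
    if not model.features:
        raise ValueError("model has no features")
    conformer = np.asarray(conformer, dtype=float)
    best = MappingResult(conformer_index=conformer_index)

    tolerances = np.array([f.tolerance for f in model.features])
    weights = np.array([f.weight for f in model.features])
    centers = np.array([f.center for f in model.features])
    ev_centers = np.array([ev.center for ev in model.excluded_volumes]) \
        if model.excluded_volumes else None
    ev_radii = np.array([ev.radius for ev in model.excluded_volumes]) \
        if model.excluded_volumes else None

    for pairs in _assignments(model, ligand_points):
        P = np.array([ligand_points[j].center for _, j in pairs])
        Q = np.array([centers[i] for i, _ in pairs])
        if len(pairs) >= 3:
            tf, _ = kabsch(P, Q)
        else:
            tf = RigidTransform(np.eye(3), Q.mean(axis=0) - P.mean(axis=0))
        moved = tf.apply(P)
        disp = np.linalg.norm(moved - Q, axis=1)
        tol = np.array([tolerances[i] for i, _ in pairs])
        if np.any(disp > tol + 1e-9):
            continue
        if ev_centers is not None:
            xyz = tf.apply(conformer)
            from scipy.spatial.distance import cdist
            dd = cdist(xyz, ev_centers)
            if np.any(dd < ev_radii[None, :] - 1e-9):
                continue
        w = np.array([weights[i] for i, _ in pairs])
        fit = fit_value(disp, tol, w)
        if not best.valid or fit > best.fit:
            best = MappingResult(
                assignment=[(model.features[i].feature_id, j)
                            for i, j in pairs],
                transform=tf, displacements=disp, fit=fit,
                ev_clash=False, conformer_index=conformer_index)
    return best


def map_molecule(confset: ConformerSet,
                 model: ConsensusPharmacophore) -> MappingResult:
    """Best mapping over all conformers (ties: lowest conformer index)."""
    if not confset.conformers:
        raise ValueError("no conformers")
    best: MappingResult | None = None
    for k, coords in enumerate(confset.conformers):
        points = ligand_feature_points(confset.topology.with_coords(coords))
        # exclude hydrogens from the clash test: tolerance spheres and
        # excluded volumes are defined on heavy atoms
        heavy = confset.topology.heavy_indices()
        res = map_conformer(coords[heavy], points, model, conformer_index=k)
        if best is None or (res.valid and res.fit > best.fit + 1e-12) \
                or (res.valid and not best.valid):
            best = res
    return best


def read_library_sdf(text: str) -> list[ConformerSet]:
    """Parse multi-conformer SDF text into ConformerSets (consecutive
    records sharing a title are conformers of one molecule)."""
    from . import chem

    out = []
    for title, mols in chem.read_sdf(text):
        topo = chem.from_rdkit(mols[0])
        confs = []
        for m in mols:
            conf = m.GetConformer()
            confs.append(np.array([[conf.GetAtomPosition(i).x,
                                    conf.GetAtomPosition(i).y,
                                    conf.GetAtomPosition(i).z]
                                   for i in range(m.GetNumAtoms())]))
        out.append(ConformerSet(title, topo, confs))
    return out


def bound_vs_mapped_rmsd(bound: np.ndarray, mapped: np.ndarray) -> float:
    """Heavy-atom RMSD between a bound pose and the best-mapping conformer,
    both already expressed in the model frame (no re-superposition)."""
    bound = np.asarray(bound, dtype=float)
    mapped = np.asarray(mapped, dtype=float)
    if bound.shape != mapped.shape:
        raise ValueError("correspondence: atom counts differ")
    return rmsd_no_fit(bound, mapped)


def screen_library(library, model: ConsensusPharmacophore,
                   top_k: int = 1000,
                   min_fit: float | None = None) -> list[ScreenHit]:
    """Rank library molecules by best-over-conformer fit.

    Molecules without a valid mapping are dropped; unreadable molecules are
    logged and skipped.  Hits are ranked by descending fit, ties broken by
    molecule id, and truncated to `top_k` (or thresholded at `min_fit`).
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    hits: list[ScreenHit] = []
    skipped = 0
    for confset in library:
        try:
            res = map_molecule(confset, model)
        except Exception as exc:  # unreadable/degenerate molecule
            logger.warning("skipping %s: %s",
                           getattr(confset, "molecule_id", "?"), exc)
            skipped += 1
            continue
        if res is None or not res.valid:
            continue
        if min_fit is not None and res.fit < min_fit:
            continue
        hits.append(ScreenHit(confset.molecule_id, res))
    hits.sort(key=lambda h: (-h.best.fit, h.molecule_id))
    hits = hits[:top_k]
    for r, h in enumerate(hits, start=1):
        h.rank = r
    if skipped:
        logger.info("screen_library skipped %d unreadable molecules", skipped)
    return hits
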