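"""Synthetic protein–ligand ensembles and screening libraries.

The generator builds download-free test inputs in which every pharmacophore
feature is planted by construction: a site of a given kind receives a small
ligand fragment (amine, carbonyl, propyl chain, carboxylate) plus the
minimal receptor residue that engages it (a serine hydroxyl acceptor, a
backbone-amide donor, an alanine methyl pocket, an aspartate carboxylate or
a lysine ammonium), at geometries safely inside the perception cutoffs.
"Proteins" are therefore minimal atom scaffolds, not folded chains — all
in-scope computations are local geometric rules, so nothing more is needed.

The stock ensemble (:func:`table1_sites`) plants 19 well-separated sites
over 14 complexes with the multiplicity pattern observed for the MetRS
crystal-structure ensemble: counts 12, 11, 10, 9, 9, 9, 5, 2, 2, 2 and nine
singletons across hydrophobic, donor, acceptor and ionizable kinds.

Determinism: every random draw comes from one seeded generator; the same
seed yields byte-identical PDB and SDF output.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import chem
from .complex_io import AtomRecord, ComplexStructure, LigandMolecule
from .consensus import ConsensusPharmacophore
from .features import ligand_feature_points

#: (kind, multiplicity) rows of the stock 19-site ensemble, in label order
TABLE1_MULTIPLICITIES = [
    ("HBA", 1), ("HBA", 1),
    ("HBD", 11), ("HBD", 9), ("HBD", 2), ("HBD", 1), ("HBD", 1),
    ("HBD", 1), ("HBD", 1), ("HBD", 1),
    ("HYD", 12), ("HYD", 10), ("HYD", 9), ("HYD", 5), ("HYD", 2), ("HYD", 1),
    ("POS", 9), ("POS", 2),
    ("NEG", 1),
]


@dataclass
class FixtureSpec:
    """Parameters of a synthetic complex ensemble."""

    seed: int = 0
    n_complexes: int = 14
    planted_sites: list[tuple[str, np.ndarray, int]] = field(default_factory=list)
    noise_sd: float = 0.3          # expected magnitude of site jitter, A
    library: tuple[int, int] = (10, 90)

    def __post_init__(self) -> None:
        self.planted_sites = [(k, np.asarray(c, dtype=float).reshape(3), m)
                              for k, c, m in self.planted_sites]
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for _, _, m in self.planted_sites:
            if m > self.n_complexes:
                raise ValueError("multiplicity exceeds number of complexes")


def table1_sites(spacing: float = 12.0) -> list[tuple[str, np.ndarray, int]]:
    """The stock 19 planted sites on a cubic grid (pairwise >= spacing)."""
    grid = [np.array(p, dtype=float) * spacing
            for p in itertools.product(range(3), repeat=3)]
    return [(kind, grid[i], mult)
            for i, (kind, mult) in enumerate(TABLE1_MULTIPLICITIES)]


def table1_spec(seed: int = 0, noise_sd: float = 0.3) -> FixtureSpec:
    return FixtureSpec(seed=seed, n_complexes=14,
                       planted_sites=table1_sites(), noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# per-site building blocks
# ---------------------------------------------------------------------------

def _basis(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random orthonormal frame (u, v, w)."""
    u = rng.normal(size=3)
    u /= np.linalg.norm(u)
    a = rng.normal(size=3)
    v = a - np.dot(a, u) * u
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return u, v, w


def _ligand_fragment(kind: str, c: np.ndarray, u: np.ndarray,
                     v: np.ndarray) -> tuple[list[tuple[str, str, np.ndarray]],
                                             list[tuple[int, int, int]],
                                             list[int]]:
    """Atoms (element, name stem, position), intra-fragment bonds and formal
    charges for one planted ligand fragment whose feature centre is `c`."""
    if kind == "HBD":
        atoms = [("N", "N", c), ("H", "H", c + 1.0 * u)]
        return atoms, [(0, 1, 1)], [0, 0]
    if kind == "HBA":
        atoms = [("O", "O", c), ("C", "C", c - 1.25 * v)]
        return atoms, [(0, 1, 2)], [0, 0]
    if kind == "HYD":
        atoms = [("C", "C", c - 1.3 * v), ("C", "C", c), ("C", "C", c + 1.3 * v)]
        return atoms, [(0, 1, 1), (1, 2, 1)], [0, 0, 0]
    if kind == "POS":
        atoms = [("N", "N", c), ("C", "C", c + 1.47 * v)]
        return atoms, [(0, 1, 1)], [0, 0]
    if kind == "NEG":
        atoms = [("C", "C", c), ("O", "O", c + 1.25 * v), ("O", "O", c - 1.25 * v)]
        return atoms, [(0, 1, 2), (0, 2, 1)], [0, 0, -1]
    raise ValueError(f"unknown kind {kind!r}")


def _probe_fragment(kind: str, c: np.ndarray, u: np.ndarray,
                    v: np.ndarray) -> tuple[list[tuple[str, str, np.ndarray]],
                                            list[tuple[int, int, int]],
                                            list[int]]:
    """Compact abstract probe groups for library molecules.

    Ionizable and acceptor probes are single charged/lone heteroatoms so
    that a probe's heavy atoms stay within ~1.3 A of its feature centre
    regardless of orientation (keeps actives clear of excluded volumes by
    construction).
    """
    if kind == "HBD":
        return [("N", "N", c), ("H", "H", c + 1.0 * u)], [(0, 1, 1)], [0, 0]
    if kind == "HBA":
        return [("O", "O", c)], [], [0]
    if kind == "POS":  # methylammonium-like: compact and rule-of-five friendly
        return [("N", "N", c), ("C", "C", c + 1.47 * v)], [(0, 1, 1)], [1, 0]
    if kind == "NEG":
        return [("O", "O", c)], [], [-1]
    return _ligand_fragment(kind, c, u, v)


def _receptor_residue(kind: str, c: np.ndarray, u: np.ndarray,
                      w: np.ndarray) -> tuple[str, list[tuple[str, str, np.ndarray]]]:
    """Minimal receptor residue engaging a feature of `kind` at `c`.

    Receptor atoms sit 2.7-6.0 A from the site along u, inside the relevant
    perception cutoff but outside every other rule's capture radius.
    """
    if kind == "HBD":   # serine hydroxyl accepts the planted donor
        return "SER", [("O", "OG", c + 2.7 * u), ("C", "CB", c + 4.15 * u)]
    if kind == "HBA":   # backbone amide nitrogen donates
        return "GLY", [("N", "N", c + 2.7 * u), ("C", "CA", c + 4.15 * u)]
    if kind == "HYD":   # alanine methyl pocket
        return "ALA", [("C", "CB", c + 3.4 * u), ("C", "CA", c + 4.9 * u)]
    if kind == "POS":   # aspartate carboxylate counter-charge
        return "ASP", [("O", "OD1", c + 4.5 * u),
                       ("O", "OD2", c + 4.5 * u + 1.3 * w),
                       ("C", "CG", c + 5.2 * u), ("C", "CB", c + 6.0 * u)]
    if kind == "NEG":   # lysine ammonium counter-charge
        return "LYS", [("N", "NZ", c + 4.8 * u), ("C", "CE", c + 6.0 * u)]
    raise ValueError(f"unknown kind {kind!r}")


#: anchor residues present in every complex (used for CA superposition)
_ANCHORS = [np.array([70.0, 0.0, 0.0]), np.array([0.0, 70.0, 0.0]),
            np.array([0.0, 0.0, 70.0])]


def make_complex_ensemble(spec: FixtureSpec,
                          min_separation: float = 6.0
                          ) -> list[ComplexStructure]:
    """Generate the ensemble of aligned synthetic complexes.

    Each planted site appears in exactly `multiplicity` complexes (chosen by
    the seeded generator); the ligand fragment of a site is jittered per
    complex by Gaussian noise of expected magnitude `noise_sd` while the
    receptor atoms stay fixed, mimicking a rigid receptor with variable
    ligand poses.
    """
    rng = np.random.default_rng(spec.seed)
    sites = spec.planted_sites
    for (_, ca, _), (_, cb, _) in itertools.combinations(sites, 2):
        if np.linalg.norm(ca - cb) < min_separation:
            raise ValueError("sites collide: planted sites closer than "
                             f"{min_separation} A")

    # per-site fixed geometry and complex assignment
    site_frames = [_basis(rng) for _ in sites]
    assignments = [sorted(rng.choice(spec.n_complexes, size=m, replace=False))
                   for (_, _, m) in sites]
    per_axis_sd = spec.noise_sd / np.sqrt(3.0)

    complexes = []
    for ci in range(spec.n_complexes):
        protein: list[AtomRecord] = []
        serial = 1
        for k, anchor in enumerate(_ANCHORS):
            protein.append(AtomRecord(serial, "CA", "C", anchor, "GLY",
                                      k + 1, "A", False))
            serial += 1

        lig_atoms: list[AtomRecord] = []
        lig_bonds: list[tuple[int, int, int]] = []
        lig_charges: list[int] = []
        lig_serial = 9000
        name_counter: dict[str, int] = {}

        for si, (kind, center, _) in enumerate(sites):
            u, v, w = site_frames[si]
            resname, res_atoms = _receptor_residue(kind, center, u, w)
            for el, nm, pos in res_atoms:
                protein.append(AtomRecord(serial, nm, el, pos, resname,
                                          100 + si, "A", False))
                serial += 1
            if ci not in assignments[si]:
                continue
            eps = rng.normal(0.0, per_axis_sd, size=3) if spec.noise_sd > 0 \
                else np.zeros(3)
            atoms, bonds, charges = _ligand_fragment(kind, center + eps, u, v)
            base = len(lig_atoms)
            for el, stem, pos in atoms:
                name_counter[stem] = name_counter.get(stem, 0) + 1
                lig_atoms.append(AtomRecord(lig_serial, f"{stem}{name_counter[stem]}",
                                            el, pos, "LIG", 900, "A", True))
                lig_serial += 1
            lig_bonds.extend((base + i, base + j, o) for i, j, o in bonds)
            lig_charges.extend(charges)

        ligand = LigandMolecule(lig_atoms, lig_bonds, lig_charges,
                                multi_fragment=True)
        complexes.append(ComplexStructure(f"CPLX{ci:02d}", protein, ligand))
    return complexes


# ---------------------------------------------------------------------------
# screening libraries
# ---------------------------------------------------------------------------

def _active_ligand(model: ConsensusPharmacophore, rng: np.random.Generator,
                   jitter: float = 0.0) -> LigandMolecule:
    """A molecule whose candidate feature points land on the model centers
    (each fragment optionally jittered by up to `jitter` A)."""
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int, int]] = []
    charges: list[int] = []
    serial = 1
    name_counter: dict[str, int] = {}
    for f in model.features:
        u, v, _ = _basis(rng)
        c = np.asarray(f.center, dtype=float)
        if jitter > 0:
            d = rng.normal(size=3)
            c = c + (jitter * rng.uniform(0, 1)) * d / np.linalg.norm(d)
        frag_atoms, frag_bonds, frag_charges = _probe_fragment(f.kind, c, u, v)
        base = len(atoms)
        for el, stem, pos in frag_atoms:
            name_counter[stem] = name_counter.get(stem, 0) + 1
            atoms.append(AtomRecord(serial, f"{stem}{name_counter[stem]}", el,
                                    pos, "LIG", 1, "A", True))
            serial += 1
        bonds.extend((base + i, base + j, o) for i, j, o in frag_bonds)
        charges.extend(frag_charges)
    return LigandMolecule(atoms, bonds, charges, multi_fragment=True)


def _delete_kind_capability(ligand: LigandMolecule, kind: str,
                            required: int,
                            rng: np.random.Generator) -> LigandMolecule:
    """Remove whole fragments until fewer than `required` candidate points
    of `kind` remain — the resulting decoy cannot cover the model."""
    while True:
        cands = [f for f in ligand_feature_points(ligand) if f.kind == kind]
        if len(cands) < required:
            return ligand
        frags = chem.fragments(ligand)
        producing = [fr for fr in frags
                     if any(set(f.atom_indices) <= set(fr) for f in cands)]
        victim = producing[int(rng.integers(len(producing)))]
        keep = [i for i in range(len(ligand.atoms)) if i not in set(victim)]
        remap = {old: new for new, old in enumerate(keep)}
        atoms = [ligand.atoms[i] for i in keep]
        bonds = [(remap[i], remap[j], o) for i, j, o in ligand.bonds
                 if i in remap and j in remap]
        fc = [ligand.formal_charges[i] for i in keep]
        ligand = LigandMolecule(atoms, bonds, fc, multi_fragment=True)


def _rigid_scatter(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Random rigid transform of a whole coordinate set."""
    from .geometry import random_rotation
    R = random_rotation(rng)
    t = rng.uniform(-30, 30, size=3)
    return coords @ R.T + t


def _fragment_scramble(ligand: LigandMolecule,
                       rng: np.random.Generator) -> np.ndarray:
    """Translate each fragment independently — a non-mapping conformation."""
    coords = ligand.coords.copy()
    for fr in chem.fragments(ligand):
        shift = rng.uniform(-25, 25, size=3)
        coords[list(fr)] += shift
    return coords


def make_library(model: ConsensusPharmacophore, n_actives: int,
                 n_decoys: int, seed: int = 0,
                 decoy_mode: str = "delete",
                 decoy_displacement: float = 8.0,
                 n_conformers: int = 3) -> str:
    """Multi-conformer SDF text with planted actives and structural decoys.

    Actives carry one conformer whose feature points satisfy every model
    sphere (plus scrambled conformers); decoys are actives with one required
    feature kind deleted (``decoy_mode="delete"``) or displaced by
    `decoy_displacement` A (``"displace"``); a displacement of 0 turns the
    decoys back into actives.
    """
    if not model.features:
        raise ValueError("model has no features")
    rng = np.random.default_rng(seed)
    kinds = sorted({f.kind for f in model.features})
    kind_required = {k: sum(1 for f in model.features if f.kind == k)
                     for k in kinds}
    mols = []

    def conformers_for(ligand: LigandMolecule,
                       good: np.ndarray | None) -> list[np.ndarray]:
        confs = [_fragment_scramble(ligand, rng) for _ in range(n_conformers)]
        if good is not None:
            slot = int(rng.integers(n_conformers))
            confs[slot] = good
        return confs

    for i in range(n_actives):
        lig = _active_ligand(model, rng, jitter=0.3)
        good = _rigid_scatter(lig.coords, rng)
        for conf in conformers_for(lig, good):
            mols.append(chem.to_rdkit(lig.with_coords(conf), f"ACT{i:04d}"))

    for i in range(n_decoys):
        lig = _active_ligand(model, rng, jitter=0.3)
        kind = kinds[int(rng.integers(len(kinds)))]
        if decoy_mode == "delete":
            lig = _delete_kind_capability(lig, kind, kind_required[kind], rng)
            good = _rigid_scatter(lig.coords, rng)
        elif decoy_mode == "displace":
            coords = lig.coords.copy()
            shift_dir = rng.normal(size=3)
            shift = decoy_displacement * shift_dir / np.linalg.norm(shift_dir)
            for f in ligand_feature_points(lig):
                if f.kind == kind:
                    coords[list(f.atom_indices)] += shift
                    break
            lig = lig.with_coords(coords)
            good = _rigid_scatter(lig.coords, rng)
        else:
            raise ValueError(f"unknown decoy_mode {decoy_mode!r}")
        for conf in conformers_for(lig, good):
            mols.append(chem.to_rdkit(lig.with_coords(conf), f"DEC{i:04d}"))

    return chem.write_sdf(mols)
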