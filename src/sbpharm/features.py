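"""Interaction-filtered pharmacophore feature perception.

A candidate feature is first typed from ligand chemistry alone
(:func:`ligand_feature_points`), then retained only if the aligned receptor
actually engages it (:func:`perceive`): donors/acceptors need a geometric
hydrogen bond, hydrophobes need a nearby apolar receptor carbon, and charged
features need a complementary charged receptor group.  Receptor-occupied
space near the ligand becomes excluded-volume spheres
(:func:`excluded_volumes_for`).

All geometric cutoffs live in :class:`PerceptionRules` and follow common
sphere-tolerance pharmacophore conventions; they are deliberately explicit
rather than tuned to any particular modelling suite.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .complex_io import AtomRecord, ComplexStructure, LigandMolecule
from .chem import total_h_count, rings, fragments

FEATURE_KINDS = ("HBD", "HBA", "HYD", "POS", "NEG")

#: side-chain carbons regarded as polar (bonded to N/O/S); backbone carbonyl
#: carbon "C" is polar in every residue
_POLAR_SIDECHAIN_CARBONS = {
    "ASP": {"CG"}, "GLU": {"CD"}, "ASN": {"CG"}, "GLN": {"CD"},
    "ARG": {"CZ"}, "TYR": {"CZ"}, "SER": {"CB"}, "THR": {"CB"},
    "CYS": {"CB"}, "HIS": {"CG", "CD2", "CE1"}, "TRP": {"CD1", "CE2"},
    "MET": {"CG", "CE"}, "LYS": {"CE"},
}

#: receptor carboxylate oxygens (complement a positive-ionizable feature)
_ACIDIC_OXYGENS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"),
                   ("GLU", "OE2")}
#: receptor basic nitrogens (complement a negative-ionizable feature)
_BASIC_NITROGENS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"),
                    ("ARG", "NH2"), ("HIS", "ND1"), ("HIS", "NE2")}


@dataclass
class PerceptionRules:
    """Geometric criteria for interaction-filtered perception (angstroms,
    degrees)."""

    max_da: float = 3.5          # donor–acceptor distance ceiling
    min_angle: float = 120.0     # D-H...A angle floor (when H present)
    hyd_contact: float = 4.5     # apolar carbon to hydrophobic centroid
    ion_contact: float = 5.5     # counter-charge to ionizable feature
    tolerance: float = 1.6       # feature sphere tolerance
    ev_contact: float = 5.0      # receptor atom to ligand for excluded volumes
    ev_radius: float = 1.2       # excluded-volume sphere radius
    ev_merge: float = 1.0        # merge radius for coincident candidates

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PerceptionRules":
        return cls(**d)


@dataclass
class PharmFeature:
    """A typed pharmacophore point."""

    kind: str
    center: np.ndarray
    tolerance: float
    direction: np.ndarray | None = None
    complex_id: str = ""
    contacts: list[str] = field(default_factory=list)
    atom_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float).reshape(3)
            n = np.linalg.norm(self.direction)
            if abs(n - 1.0) > 1e-6:
                raise ValueError("direction must be a unit vector")


@dataclass
class ExcludedVolume:
    center: np.ndarray
    radius: float
    source_residue: str = ""

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass
class HBond:
    """A geometric ligand-receptor hydrogen bond."""

    donor: AtomRecord
    acceptor: AtomRecord
    d_a_distance: float
    hydrogen: AtomRecord | None = None
    dha_angle: float | None = None
    donor_is_ligand: bool = True
    ligand_atom_index: int = -1


# ---------------------------------------------------------------------------
# chemistry-only candidate typing
# ---------------------------------------------------------------------------

def _is_polar_carbon(ligand: LigandMolecule, i: int) -> bool:
    if ligand.atoms[i].element.upper() != "C":
        return True
    if ligand.formal_charges[i] != 0:
        return True
    return any(ligand.atoms[j].element.upper() in {"N", "O", "S", "P"}
               for j, _ in ligand.neighbors(i))


def _bonded_to_carbonyl_carbon(ligand: LigandMolecule, i: int) -> bool:
    for j, _ in ligand.neighbors(i):
        if ligand.atoms[j].element.upper() != "C":
            continue
        for k, order in ligand.neighbors(j):
            if k != i and order >= 2 and ligand.atoms[k].element.upper() == "O":
                return True
    return False


def _is_acceptor_capable(ligand: LigandMolecule, i: int) -> bool:
    """Lone-pair availability: any oxygen, or a hydrogen-free nitrogen with
    a multiple bond that is not an amide nitrogen."""
    el = ligand.atoms[i].element.upper()
    charge = ligand.formal_charges[i]
    if el == "O":
        return charge <= 0
    if el == "N":
        return (charge <= 0 and total_h_count(ligand, i) == 0
                and any(order >= 2 for _, order in ligand.neighbors(i))
                and not _bonded_to_carbonyl_carbon(ligand, i))
    return False


def _guanidine_carbons(ligand: LigandMolecule) -> set[int]:
    out = set()
    for i, a in enumerate(ligand.atoms):
        if a.element.upper() != "C":
            continue
        n_neighbors = [j for j, _ in ligand.neighbors(i)
                       if ligand.atoms[j].element.upper() == "N"]
        if len(n_neighbors) == 3:
            out.add(i)
    return out


def _anionic_groups(ligand: LigandMolecule) -> list[tuple[int, ...]]:
    """Carboxylate / sulfonate / phosphonate groups: a C/S/P centre bonded to
    >=2 terminal oxygens.  Returns (centre, O, O, ...) index tuples."""
    groups = []
    for i, a in enumerate(ligand.atoms):
        if a.element.upper() not in {"C", "S", "P"}:
            continue
        terminal_o = []
        for j, _ in ligand.neighbors(i):
            if ligand.atoms[j].element.upper() != "O":
                continue
            heavy_nb = [k for k, _ in ligand.neighbors(j)
                        if ligand.atoms[k].is_heavy]
            if heavy_nb == [i]:
                terminal_o.append(j)
        if len(terminal_o) >= 2:
            groups.append((i, *sorted(terminal_o)))
    return groups


def ligand_feature_points(ligand: LigandMolecule,
                          tolerance: float = 1.6) -> list[PharmFeature]:
    """Chemistry-only candidate features of a ligand (no receptor filter).

    HBD: N/O/S bearing at least one hydrogen (explicit or valence-implied).
    HBA: any O, or an N with a multiple bond, no hydrogen, not an amide N.
    HYD: centroids of all-carbon rings and of acyclic chains of >=3
    contiguous apolar carbons.  POS: protonatable amines, guanidines,
    quaternary or formally positive atoms.  NEG: carboxylate-like groups and
    formally negative atoms.
    """
    if (len(ligand.atoms) > 1 and not ligand.bonds
            and not ligand.multi_fragment):
        raise ValueError("bond perception required: ligand has no bonds")

    feats: list[PharmFeature] = []

    def add(kind: str, center: np.ndarray, idx: tuple[int, ...]) -> None:
        feats.append(PharmFeature(kind, center, tolerance, atom_indices=idx))

    anion_groups = _anionic_groups(ligand)
    anion_atoms = {i for g in anion_groups for i in g}
    guanidines = _guanidine_carbons(ligand)
    guanidine_n = {j for c in guanidines for j, _ in ligand.neighbors(c)
                   if ligand.atoms[j].element.upper() == "N"}
    ring_list = rings(ligand)
    ring_atoms = {i for r in ring_list for i in r}

    for i, a in enumerate(ligand.atoms):
        el = a.element.upper()
        if not a.is_heavy:
            continue
        charge = ligand.formal_charges[i]
        n_h = total_h_count(ligand, i)

        # hydrogen-bond donor
        if el in {"N", "O", "S"} and n_h >= 1 and charge >= 0:
            add("HBD", a.coords, (i,))

        # hydrogen-bond acceptor
        if _is_acceptor_capable(ligand, i):
            add("HBA", a.coords, (i,))

        # positive ionizable: formally positive / quaternary / protonatable amine
        if charge > 0:
            add("POS", a.coords, (i,))
        elif el == "N" and i not in guanidine_n:
            orders = [o for _, o in ligand.neighbors(i)]
            heavy_deg = sum(1 for j, _ in ligand.neighbors(i)
                            if ligand.atoms[j].is_heavy)
            amine_like = (orders and all(o == 1 for o in orders)
                          and i not in ring_atoms
                          and not _bonded_to_carbonyl_carbon(ligand, i))
            if amine_like and (heavy_deg == 4 or n_h + heavy_deg <= 4):
                add("POS", a.coords, (i,))

        # negative ionizable: lone formally negative atom outside a group
        if charge < 0 and i not in anion_atoms:
            add("NEG", a.coords, (i,))

    for c in sorted(guanidines):
        add("POS", ligand.atoms[c].coords, (c,))

    for group in anion_groups:
        center = np.mean([ligand.atoms[i].coords for i in group], axis=0)
        add("NEG", center, tuple(group))

    # hydrophobic: all-carbon rings
    for ring in ring_list:
        if all(ligand.atoms[i].element.upper() == "C" for i in ring):
            center = np.mean([ligand.atoms[i].coords for i in ring], axis=0)
            add("HYD", center, tuple(ring))

    # hydrophobic: acyclic chains of >=3 contiguous apolar carbons
    import networkx as nx
    g = nx.Graph()
    apolar = [i for i, a in enumerate(ligand.atoms)
              if a.element.upper() == "C" and i not in ring_atoms
              and not _is_polar_carbon(ligand, i)]
    g.add_nodes_from(apolar)
    apolar_set = set(apolar)
    g.add_edges_from((i, j) for i, j, _ in ligand.bonds
                     if i in apolar_set and j in apolar_set)
    for comp in nx.connected_components(g):
        if len(comp) >= 3:
            idx = tuple(sorted(comp))
            center = np.mean([ligand.atoms[i].coords for i in idx], axis=0)
            add("HYD", center, idx)

    return feats


# ---------------------------------------------------------------------------
# hydrogen-bond detection
# ---------------------------------------------------------------------------

def _protein_hydrogens(complex_: ComplexStructure) -> dict[int, list[AtomRecord]]:
    """Hydrogens attached to each protein heavy atom (by proximity < 1.25 A,
    same residue); empty when the structure carries no hydrogens."""
    hyd = [a for a in complex_.protein_atoms if not a.is_heavy]
    attached: dict[int, list[AtomRecord]] = {}
    if not hyd:
        return attached
    for idx, a in enumerate(complex_.protein_atoms):
        if not a.is_heavy:
            continue
        for h in hyd:
            if (h.residue_label == a.residue_label
                    and np.linalg.norm(h.coords - a.coords) < 1.25):
                attached.setdefault(idx, []).append(h)
    return attached


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(complex_: ComplexStructure, max_da: float = 3.5,
                  min_angle: float = 120.0) -> list[HBond]:
    """Geometric ligand-receptor hydrogen bonds.

    Donor-acceptor heavy-atom distance must be <= `max_da`; when the donor
    hydrogen is explicit, the D-H...A angle must also be >= `min_angle`.
    Structures without hydrogens are judged on distance alone, the usual
    situation for X-ray models.
    """
    lig = complex_.ligand
    out: list[HBond] = []

    lig_donors = [i for i in lig.heavy_indices()
                  if lig.atoms[i].element.upper() in {"N", "O", "S"}
                  and total_h_count(lig, i) >= 1]
    lig_acceptors = [i for i in lig.heavy_indices()
                     if _is_acceptor_capable(lig, i)]
    prot_heavy = [(k, a) for k, a in enumerate(complex_.protein_atoms)
                  if a.is_heavy]
    prot_donors = [(k, a) for k, a in prot_heavy
                   if a.element.upper() in {"N", "O", "S"}]
    prot_acceptors = [(k, a) for k, a in prot_heavy
                      if a.element.upper() in {"N", "O"}]
    prot_h = _protein_hydrogens(complex_)

    def lig_hydrogens(i: int) -> list[AtomRecord]:
        return [lig.atoms[j] for j, _ in lig.neighbors(i)
                if not lig.atoms[j].is_heavy]

    def angle_ok(donor: AtomRecord, hydrogens: list[AtomRecord],
                 acceptor: AtomRecord) -> tuple[bool, AtomRecord | None, float | None]:
        if not hydrogens:
            return True, None, None
        best_h, best_ang = None, -1.0
        for h in hydrogens:
            ang = _angle_deg(donor.coords, h.coords, acceptor.coords)
            if ang > best_ang:
                best_h, best_ang = h, ang
        if best_ang >= min_angle:
            return True, best_h, best_ang
        return False, None, None

    # ligand donor -> protein acceptor
    for i in lig_donors:
        d = lig.atoms[i]
        for k, a in prot_acceptors:
            dist = float(np.linalg.norm(d.coords - a.coords))
            if dist > max_da or dist < 1e-6:
                continue
            ok, h, ang = angle_ok(d, lig_hydrogens(i), a)
            if ok:
                out.append(HBond(d, a, dist, h, ang, True, i))

    # protein donor -> ligand acceptor
    for i in lig_acceptors:
        acc = lig.atoms[i]
        for k, d in prot_donors:
            dist = float(np.linalg.norm(d.coords - acc.coords))
            if dist > max_da or dist < 1e-6:
                continue
            ok, h, ang = angle_ok(d, prot_h.get(k, []), acc)
            if ok:
                out.append(HBond(d, acc, dist, h, ang, False, i))

    return out


# ---------------------------------------------------------------------------
# interaction filter
# ---------------------------------------------------------------------------

def _protein_apolar_carbons(complex_: ComplexStructure) -> list[AtomRecord]:
    out = []
    for a in complex_.protein_atoms:
        if a.element.upper() != "C":
            continue
        if a.name == "C":  # backbone carbonyl
            continue
        if a.name in _POLAR_SIDECHAIN_CARBONS.get(a.residue_name, ()):
            continue
        out.append(a)
    return out


def perceive(complex_: ComplexStructure,
             rules: PerceptionRules | None = None) -> list[PharmFeature]:
    """Interaction-filtered pharmacophore features of one aligned complex.

    Candidates from :func:`ligand_feature_points` are retained only when the
    receptor engages them; every retained feature records the contacting
    residue labels.
    """
    rules = rules or PerceptionRules()
    lig = complex_.ligand
    candidates = ligand_feature_points(lig, tolerance=rules.tolerance)
    hbonds = detect_hbonds(complex_, rules.max_da, rules.min_angle)

    donor_contacts: dict[int, list[HBond]] = {}
    acceptor_contacts: dict[int, list[HBond]] = {}
    for hb in hbonds:
        if hb.donor_is_ligand:
            donor_contacts.setdefault(hb.ligand_atom_index, []).append(hb)
        else:
            acceptor_contacts.setdefault(hb.ligand_atom_index, []).append(hb)

    apolar = _protein_apolar_carbons(complex_)
    acidic_o = [a for a in complex_.protein_atoms
                if (a.residue_name, a.name) in _ACIDIC_OXYGENS
                or a.name == "OXT"]
    basic_n = [a for a in complex_.protein_atoms
               if (a.residue_name, a.name) in _BASIC_NITROGENS]

    def near(center: np.ndarray, atoms: list[AtomRecord],
             cutoff: float) -> list[AtomRecord]:
        return [a for a in atoms
                if np.linalg.norm(a.coords - center) <= cutoff + 1e-12]

    retained: list[PharmFeature] = []
    for cand in candidates:
        contacts: list[str] = []
        direction = None
        if cand.kind == "HBD":
            hbs = donor_contacts.get(cand.atom_indices[0], [])
            if not hbs:
                continue
            contacts = [hb.acceptor.residue_label for hb in hbs]
            best = min(hbs, key=lambda hb: hb.d_a_distance)
            v = best.acceptor.coords - cand.center
            direction = v / np.linalg.norm(v)
        elif cand.kind == "HBA":
            hbs = acceptor_contacts.get(cand.atom_indices[0], [])
            if not hbs:
                continue
            contacts = [hb.donor.residue_label for hb in hbs]
            best = min(hbs, key=lambda hb: hb.d_a_distance)
            v = best.donor.coords - cand.center
            direction = v / np.linalg.norm(v)
        elif cand.kind == "HYD":
            hits = near(cand.center, apolar, rules.hyd_contact)
            if not hits:
                continue
            contacts = [a.residue_label for a in hits]
        elif cand.kind == "POS":
            hits = near(cand.center, acidic_o, rules.ion_contact)
            if not hits:
                continue
            contacts = [a.residue_label for a in hits]
        elif cand.kind == "NEG":
            hits = near(cand.center, basic_n, rules.ion_contact)
            if not hits:
                continue
            contacts = [a.residue_label for a in hits]
        retained.append(PharmFeature(
            kind=cand.kind, center=cand.center, tolerance=rules.tolerance,
            direction=direction, complex_id=complex_.complex_id,
            contacts=sorted(set(contacts)), atom_indices=cand.atom_indices,
        ))
    return retained


# ---------------------------------------------------------------------------
# excluded volumes
# ---------------------------------------------------------------------------

def greedy_merge(points: np.ndarray, merge_radius: float,
                 inclusive: bool = False
                 ) -> tuple[np.ndarray, list[list[int]]]:
    """Greedy agglomerative merge: repeatedly fuse the closest pair of
    clusters while their centroid distance is below `merge_radius`
    (or at most `merge_radius` when `inclusive`).

    Returns centroids and the member-index lists.  Deterministic: ties are
    broken by lexicographic centroid order.
    """
    from scipy.spatial.distance import cdist

    points = np.asarray(points, dtype=float)
    clusters: list[list[int]] = [[i] for i in range(len(points))]
    cents = [points[i].copy() for i in range(len(points))]
    while len(clusters) > 1:
        C = np.array(cents)
        D = cdist(C, C)
        iu = np.triu_indices(len(C), k=1)
        if iu[0].size == 0:
            break
        dmin = D[iu].min()
        stop = dmin > merge_radius + 1e-12 if inclusive else dmin >= merge_radius
        if stop:
            break
        # deterministic tie-break: lexicographically smallest centroid pair
        cand = [(a, b) for a, b in zip(*iu) if D[a, b] <= dmin + 1e-12]
        key = lambda ab: (tuple(np.minimum(C[ab[0]], C[ab[1]])),
                          tuple(np.maximum(C[ab[0]], C[ab[1]])))
        a, b = min(cand, key=key)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        cents = [c for k, c in enumerate(cents) if k not in (a, b)]
        clusters.append(merged)
        cents.append(points[merged].mean(axis=0))
    return np.array(cents), clusters


def excluded_volumes_for(complexes: list[ComplexStructure],
                         contact_cutoff: float = 5.0,
                         radius: float = 1.2,
                         merge_radius: float = 1.0) -> list[ExcludedVolume]:
    """Excluded-volume spheres at receptor heavy atoms near any ligand.

    One candidate sphere per binding-site protein heavy atom within
    `contact_cutoff` of any ligand atom in any complex; candidates closer
    than `merge_radius` are merged to their centroid.
    """
    if not complexes:
        raise ValueError("no structures")
    centers: list[np.ndarray] = []
    sources: list[str] = []
    for cx in complexes:
        lig = cx.ligand.coords
        for a in cx.protein_atoms:
            if not a.is_heavy:
                continue
            dmin = float(np.min(np.linalg.norm(lig - a.coords, axis=1)))
            if dmin <= contact_cutoff + 1e-12:
                centers.append(a.coords)
                sources.append(a.residue_label)
    if not centers:
        return []
    cents, members = greedy_merge(np.array(centers), merge_radius)
    out = []
    for cent, mem in zip(cents, members):
        out.append(ExcludedVolume(cent, radius, sources[min(mem)]))
    out.sort(key=lambda ev: tuple(ev.center))
    return out
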