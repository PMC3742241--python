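"""Protein–ligand complex I/O and superposition.

Reads PDB text (via gemmi), splits protein from the ligand of interest,
strips waters and monatomic ions, extracts binding-site residues, and
superposes complexes into a common reference frame with CA-based Kabsch
fitting.

Residues are labelled ``chain:resname:resnum`` (e.g. ``A:ASP:296``);
numbering is taken verbatim from the input file.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .geometry import RigidTransform, kabsch

#: residue names stripped from structures: water plus common monatomic ions
WATER_NAMES = {"HOH", "WAT"}
ION_NAMES = {"NA", "K", "MG", "ZN", "CL", "CA", "MN"}

#: three-letter -> one-letter amino-acid codes (for short residue labels)
ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
THREE_LETTER = {v: k for k, v in ONE_LETTER.items()}

#: single-bond covalent radii (angstrom) used by the distance fallback
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05,
    "P": 1.07, "F": 0.57, "CL": 1.02, "BR": 1.20, "I": 1.39,
}


@dataclass
class AtomRecord:
    """One atom from a PDB record."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_name: str
    residue_number: int
    chain: str
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")

    @property
    def residue_label(self) -> str:
        return f"{self.chain}:{self.residue_name}:{self.residue_number}"

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class LigandMolecule:
    """A small molecule: atoms, a bond graph and per-atom formal charges."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)
    formal_charges: list[int] = field(default_factory=list)
    multi_fragment: bool = False

    def __post_init__(self) -> None:
        if not self.formal_charges:
            self.formal_charges = [0] * len(self.atoms)
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond indices out of range")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.is_heavy]

    def neighbors(self, i: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs of atom i."""
        out = []
        for a, b, order in self.bonds:
            if a == i:
                out.append((b, order))
            elif b == i:
                out.append((a, order))
        return out

    def with_coords(self, coords: np.ndarray) -> "LigandMolecule":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array does not match atom count")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return LigandMolecule(atoms, list(self.bonds), list(self.formal_charges),
                              self.multi_fragment)


@dataclass
class ComplexStructure:
    """One protein–ligand co-crystal in a common 3-D frame."""

    complex_id: str
    protein_atoms: list[AtomRecord]
    ligand: LigandMolecule
    removed: dict = field(default_factory=lambda: {"waters": 0, "ions": 0})

    @property
    def protein_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.protein_atoms], dtype=float)

    def residues(self) -> dict[str, list[AtomRecord]]:
        """Protein atoms grouped by residue label, file order preserved."""
        out: dict[str, list[AtomRecord]] = {}
        for a in self.protein_atoms:
            out.setdefault(a.residue_label, []).append(a)
        return out

    def transformed(self, tf: RigidTransform) -> "ComplexStructure":
        """Rigidly move protein and ligand together."""
        prot = [replace(a, coords=tf.apply(a.coords)) for a in self.protein_atoms]
        lig = self.ligand.with_coords(tf.apply(self.ligand.coords))
        return ComplexStructure(self.complex_id, prot, lig, dict(self.removed))


class LigandNotFoundError(ValueError):
    pass


class NoProteinError(ValueError):
    pass


def _dedupe_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep the highest-occupancy altloc per atom name (ties: first seen)."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.name not in best:
            best[atom.name] = atom
            order.append(atom.name)
        elif atom.occ > best[atom.name].occ:
            best[atom.name] = atom
    return [best[name] for name in order]


def _parse_conect(pdb_text: str) -> list[tuple[int, int, int]]:
    """(serial_a, serial_b, order) triples; a pair repeated in CONECT
    records denotes a multiple bond, the PDB convention."""
    counts: dict[tuple[int, int], int] = {}
    for line in pdb_text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[6 + 5 * k: 11 + 5 * k].strip() for k in range(5)]
        fields = [f for f in fields if f]
        if len(fields) < 2:
            continue
        a = int(fields[0])
        for f in fields[1:]:
            b = int(f)
            key = (min(a, b), max(a, b))
            counts[key] = counts.get(key, 0) + 1
    # each bond normally appears once from each end; order = ceil(n/2)
    return sorted((a, b, max(1, (n + 1) // 2))
                  for (a, b), n in counts.items())


def perceive_bonds(atoms: list[AtomRecord], slack: float = 0.45) -> list[tuple[int, int, int]]:
    """Distance-based single-bond perception from covalent radii.

    Two atoms are bonded when their separation is below the sum of covalent
    radii plus `slack`.  All perceived bonds are single; used only when the
    PDB carries no CONECT records for the ligand.
    """
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            ri = COVALENT_RADII.get(atoms[i].element.upper(), 0.77)
            rj = COVALENT_RADII.get(atoms[j].element.upper(), 0.77)
            d = float(np.linalg.norm(atoms[i].coords - atoms[j].coords))
            if d <= ri + rj + slack:
                bonds.append((i, j, 1))
    return bonds


def _atom_record(atom: gemmi.Atom, res: gemmi.Residue, chain_name: str,
                 hetero: bool) -> AtomRecord:
    return AtomRecord(
        serial=atom.serial,
        name=atom.name,
        element=atom.element.name,
        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        residue_name=res.name.strip(),
        residue_number=res.seqid.num,
        chain=chain_name or "A",
        is_hetero=hetero,
    )


def read_complex(pdb_text: str, ligand_code: str,
                 complex_id: str = "complex") -> ComplexStructure:
    """Parse PDB text into a ComplexStructure.

    Protein atoms are all ATOM records; the ligand is the first copy of the
    HETATM residue named `ligand_code`.  Waters and monatomic ions are
    removed and counted.  Ligand bonds come from CONECT records when present,
    otherwise from covalent-radius distance perception; formal charges are
    taken from PDB charge columns (usually absent, hence zero).
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise NoProteinError("no protein: empty structure")
    model = st[0]

    protein: list[AtomRecord] = []
    ligand_atoms: list[AtomRecord] = []
    removed = {"waters": 0, "ions": 0}
    ligand_found = False

    for chain in model:
        for res in chain:
            hetero = res.het_flag == "H"
            name = res.name.strip()
            if name in WATER_NAMES:
                removed["waters"] += 1
                continue
            if hetero and name in ION_NAMES:
                removed["ions"] += 1
                continue
            atoms = _dedupe_altlocs(res)
            if hetero and name == ligand_code:
                if not ligand_found:  # first copy only
                    ligand_atoms = [_atom_record(a, res, chain.name, True)
                                    for a in atoms]
                    ligand_found = True
                continue
            if not hetero:
                protein.extend(_atom_record(a, res, chain.name, False)
                               for a in atoms)

    if not ligand_found or not ligand_atoms:
        raise LigandNotFoundError(f"ligand not found: {ligand_code!r}")
    if not protein:
        raise NoProteinError("no protein: no ATOM records")

    serial_to_idx = {a.serial: i for i, a in enumerate(ligand_atoms)}
    bonds = [(serial_to_idx[a], serial_to_idx[b], o)
             for a, b, o in _parse_conect(pdb_text)
             if a in serial_to_idx and b in serial_to_idx]
    if not bonds and len(ligand_atoms) > 1:
        bonds = perceive_bonds(ligand_atoms)

    charges = _ligand_charges(pdb_text, ligand_atoms)
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(range(len(ligand_atoms)))
    g.add_edges_from((i, j) for i, j, _ in bonds)
    multi = nx.number_connected_components(g) > 1 if len(ligand_atoms) else False
    ligand = LigandMolecule(ligand_atoms, bonds, charges, multi_fragment=multi)
    return ComplexStructure(complex_id, protein, ligand, removed)


def _ligand_charges(pdb_text: str, ligand_atoms: list[AtomRecord]) -> list[int]:
    """Formal charges from PDB columns 79-80 ('1-', '2+', ...)."""
    by_serial: dict[int, int] = {}
    for line in pdb_text.splitlines():
        if not line.startswith(("ATOM", "HETATM")) or len(line) < 80:
            continue
        field = line[78:80].strip()
        if not field:
            continue
        try:
            serial = int(line[6:11])
        except ValueError:
            continue
        mag = int(field[0]) if field[0].isdigit() else 0
        sign = -1 if field.endswith("-") else 1
        by_serial[serial] = sign * mag
    return [by_serial.get(a.serial, 0) for a in ligand_atoms]


def write_pdb(complex_: ComplexStructure) -> str:
    """Serialise a ComplexStructure to PDB text (ATOM/HETATM/CONECT/END)."""
    lines = []
    fmt = ("{rec:<6}{serial:>5} {name:<4}{alt:1}{res:<3} {chain:1}"
           "{resnum:>4}{icode:1}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
           "{occ:>6.2f}{b:>6.2f}          {el:>2}{chg:<2}")

    def atom_line(rec: str, a: AtomRecord, charge: int = 0) -> str:
        name = a.name if len(a.name) >= 4 else f" {a.name:<3}"
        chg = "" if charge == 0 else f"{abs(charge)}{'-' if charge < 0 else '+'}"
        return fmt.format(rec=rec, serial=a.serial, name=name, alt=" ",
                          res=a.residue_name, chain=a.chain,
                          resnum=a.residue_number, icode=" ",
                          x=a.coords[0], y=a.coords[1], z=a.coords[2],
                          occ=1.00, b=0.00, el=a.element.upper(), chg=chg
                          ).rstrip()

    for a in complex_.protein_atoms:
        lines.append(atom_line("ATOM", a))
    lines.append("TER")
    for a, q in zip(complex_.ligand.atoms, complex_.ligand.formal_charges):
        lines.append(atom_line("HETATM", a, q))
    for i, j, order in complex_.ligand.bonds:
        si = complex_.ligand.atoms[i].serial
        sj = complex_.ligand.atoms[j].serial
        for _ in range(max(1, order)):  # repeat pair to encode bond order
            lines.append(f"CONECT{si:>5}{sj:>5}")
            lines.append(f"CONECT{sj:>5}{si:>5}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def binding_site(complex_: ComplexStructure, radius: float = 12.0) -> set[str]:
    """Residue labels with any atom within `radius` (closed bound) of any
    ligand atom."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    lig = complex_.ligand.coords
    tree = cKDTree(lig)
    site: set[str] = set()
    for label, atoms in complex_.residues().items():
        pts = np.array([a.coords for a in atoms])
        dmin = tree.query(pts, k=1)[0].min()
        if dmin <= radius + 1e-12:
            site.add(label)
    return site


def _ca_coords(complex_: ComplexStructure,
               labels: list[str]) -> np.ndarray:
    residues = complex_.residues()
    pts = []
    for label in labels:
        atoms = residues.get(label)
        if atoms is None:
            raise ValueError(f"pairing unresolved: residue {label} absent")
        ca = next((a for a in atoms if a.name == "CA"), None)
        if ca is None:
            raise ValueError(f"pairing unresolved: residue {label} has no CA")
        pts.append(ca.coords)
    return np.array(pts)


def superpose_to_reference(
    mobile: ComplexStructure,
    reference: ComplexStructure,
    pairing: list[tuple[str, str]],
) -> tuple[ComplexStructure, float]:
    """Superpose `mobile` onto `reference` by Kabsch on paired CA atoms.

    `pairing` lists (mobile residue label, reference residue label) pairs;
    at least three are required.  The ligand moves rigidly with its protein.
    """
    if len(pairing) < 3:
        raise ValueError("pairing unresolved: need at least 3 residue pairs")
    P = _ca_coords(mobile, [m for m, _ in pairing])
    Q = _ca_coords(reference, [r for _, r in pairing])
    tf, rmsd = kabsch(P, Q)
    return mobile.transformed(tf), rmsd
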