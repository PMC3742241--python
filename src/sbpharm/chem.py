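"""Small-molecule chemistry helpers: implicit hydrogens, RDKit bridge, SDF I/O.

The in-memory ligand container (:class:`~sbpharm.complex_io.LigandMolecule`)
is a bare atom/bond graph so that it can hold both crystallographic het
groups (usually hydrogen-free, single bonds from CONECT) and fully explicit
synthetic molecules.  Hydrogen counts are therefore computed from default
valences rather than trusted from the input.
"""
from __future__ import annotations

import io

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem  # noqa: F401  (registers descriptors)

from .complex_io import AtomRecord, LigandMolecule

#: default valences used for implicit-hydrogen accounting
DEFAULT_VALENCE = {"H": 1, "C": 4, "N": 3, "O": 2, "S": 2, "P": 3,
                   "F": 1, "CL": 1, "BR": 1, "I": 1}

_BOND_TYPES = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
               3: Chem.BondType.TRIPLE}
_BOND_ORDERS = {v: k for k, v in _BOND_TYPES.items()}


def bond_order_sum(ligand: LigandMolecule, i: int) -> int:
    return sum(order for _, order in ligand.neighbors(i))


def explicit_h_count(ligand: LigandMolecule, i: int) -> int:
    return sum(1 for j, _ in ligand.neighbors(i)
               if ligand.atoms[j].element.upper() == "H")


def total_h_count(ligand: LigandMolecule, i: int) -> int:
    """Explicit plus implicit hydrogens on heavy atom i.

    Implicit count = default valence (charge-adjusted) minus bond-order sum,
    floored at zero, so hydrogen-free crystallographic ligands and explicit-H
    molecules give consistent answers.
    """
    el = ligand.atoms[i].element.upper()
    val = DEFAULT_VALENCE.get(el)
    if val is None:
        return explicit_h_count(ligand, i)
    val += ligand.formal_charges[i] if el in {"N", "P"} else 0
    if el in {"O", "S"}:
        val += ligand.formal_charges[i]
    implicit = max(0, val - bond_order_sum(ligand, i))
    return explicit_h_count(ligand, i) + implicit


def rings(ligand: LigandMolecule) -> list[list[int]]:
    """Smallest-cycle basis of the heavy-atom bond graph."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(ligand.atoms)))
    g.add_edges_from((i, j) for i, j, _ in ligand.bonds)
    return [sorted(c) for c in nx.cycle_basis(g)]


def fragments(ligand: LigandMolecule) -> list[list[int]]:
    """Connected components of the bond graph (atom index lists)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(ligand.atoms)))
    g.add_edges_from((i, j) for i, j, _ in ligand.bonds)
    return [sorted(c) for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# RDKit bridge
# ---------------------------------------------------------------------------

def to_rdkit(ligand: LigandMolecule, name: str = "") -> Chem.Mol:
    """Convert to an RDKit molecule with a 3-D conformer.

    Sanitization is attempted but not required: crystallographic fragments
    with unusual valences fall back to a lenient property-cache update so
    that descriptors (MW, logP) still evaluate.
    """
    rw = Chem.RWMol()
    for i, a in enumerate(ligand.atoms):
        at = Chem.Atom(a.element.capitalize())
        at.SetFormalCharge(int(ligand.formal_charges[i]))
        at.SetNoImplicit(any(ligand.atoms[j].element.upper() == "H"
                             for j, _ in ligand.neighbors(i)))
        rw.AddAtom(at)
    for i, j, order in ligand.bonds:
        rw.AddBond(i, j, _BOND_TYPES.get(order, Chem.BondType.SINGLE))
    mol = rw.GetMol()
    conf = Chem.Conformer(len(ligand.atoms))
    for i, a in enumerate(ligand.atoms):
        conf.SetAtomPosition(i, a.coords.tolist())
    mol.AddConformer(conf, assignId=True)
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
    if name:
        mol.SetProp("_Name", name)
    return mol


def from_rdkit(mol: Chem.Mol, conf_id: int = 0) -> LigandMolecule:
    """Convert an RDKit molecule (with a conformer) to a LigandMolecule."""
    conf = mol.GetConformer(conf_id)
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(AtomRecord(
            serial=i + 1, name=f"{at.GetSymbol()}{i + 1}",
            element=at.GetSymbol(),
            coords=np.array([pos.x, pos.y, pos.z]),
            residue_name="LIG", residue_number=1, chain="A", is_hetero=True,
        ))
    bonds = []
    for b in mol.GetBonds():
        order = _BOND_ORDERS.get(b.GetBondType(), 1)
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    charges = [at.GetFormalCharge() for at in mol.GetAtoms()]
    lig = LigandMolecule(atoms, bonds, charges)
    lig.multi_fragment = len(fragments(lig)) > 1
    return lig


# ---------------------------------------------------------------------------
# SDF I/O (V2000, multi-conformer grouped by consecutive identical titles)
# ---------------------------------------------------------------------------

def read_sdf(text: str) -> list[tuple[str, list[Chem.Mol]]]:
    """Read SDF text; consecutive records with the same title are grouped."""
    supplier = Chem.SDMolSupplier()
    supplier.SetData(text, sanitize=False, removeHs=False)
    groups: list[tuple[str, list[Chem.Mol]]] = []
    for mol in supplier:
        if mol is None:
            continue
        mol.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(mol)
        title = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        if groups and groups[-1][0] == title:
            groups[-1][1].append(mol)
        else:
            groups.append((title, [mol]))
    return groups


def write_sdf(mols: list[Chem.Mol]) -> str:
    buf = io.StringIO()
    writer = Chem.SDWriter(buf)
    writer.SetKekulize(False)
    for mol in mols:
        writer.write(mol)
    writer.close()
    return buf.getvalue()
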