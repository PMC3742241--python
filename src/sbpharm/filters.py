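"""Hit-selection filters: Lipinski rule of five, key-residue contacts, and
the final ranked report.

Lipinski counts use the classic convention — donors are N/O/S-H groups,
acceptors are all nitrogens and oxygens — with molecular weight and Crippen
atom-contribution logP evaluated by RDKit.  A molecule passes when
HBD <= 5, HBA <= 10, MW < 500 Da (strict) and logP < 5.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .chem import to_rdkit
from .complex_io import (ComplexStructure, LigandMolecule, ONE_LETTER)
from .features import (PerceptionRules, _protein_apolar_carbons,
                       detect_hbonds)


@dataclass
class FilterReport:
    """Druglikeness and interaction summary for one molecule."""

    molecule_id: str
    mw: float
    hbd_count: int
    hba_count: int
    logp: float
    lipinski_pass: bool
    key_contacts: dict[str, object] = field(default_factory=dict)
    external_score: float | None = None


def lipinski_pass(mw: float, hbd: int, hba: int, logp: float) -> bool:
    """The rule-of-five predicate: <=5 donors, <=10 acceptors, MW strictly
    below 500 Da, logP below 5."""
    return hbd <= 5 and hba <= 10 and mw < 500.0 and logp < 5.0


def lipinski(molecule: LigandMolecule | Chem.Mol,
             molecule_id: str = "") -> FilterReport:
    """Rule-of-five report for a molecule."""
    mol = molecule if isinstance(molecule, Chem.Mol) else to_rdkit(molecule)
    mw = float(Descriptors.MolWt(mol))
    logp = float(Crippen.MolLogP(mol))
    hbd = sum(a.GetTotalNumHs(True) for a in mol.GetAtoms()
              if a.GetSymbol() in ("N", "O", "S"))
    hba = sum(1 for a in mol.GetAtoms() if a.GetSymbol() in ("N", "O"))
    return FilterReport(
        molecule_id=molecule_id or (mol.GetProp("_Name")
                                    if mol.HasProp("_Name") else ""),
        mw=mw, hbd_count=hbd, hba_count=hba, logp=logp,
        lipinski_pass=lipinski_pass(mw, hbd, hba, logp),
    )


def _resolve_residue_label(label: str,
                           receptor: ComplexStructure) -> list[str]:
    """Match a short label like 'D296' (one-letter code + number) or a full
    'chain:resname:number' label against receptor residues."""
    labels = list(receptor.residues().keys())
    if label in labels:
        return [label]
    short = label.strip()
    if len(short) >= 2 and short[0].isalpha() and short[1:].isdigit():
        one, num = short[0].upper(), int(short[1:])
        out = []
        for lab in labels:
            chain, resname, resnum = lab.split(":")
            if int(resnum) == num and ONE_LETTER.get(resname) == one:
                out.append(lab)
        return out
    return []


def key_residue_contacts(pose: LigandMolecule,
                         receptor: ComplexStructure,
                         residues: list[str],
                         rules: PerceptionRules | None = None
                         ) -> dict[str, object]:
    """Check whether a posed ligand engages each named key residue.

    A residue is marked True when a hydrogen bond (the perception criteria)
    or an apolar carbon-carbon contact within the hydrophobic cutoff exists
    between the pose and that residue; residues absent from the receptor are
    marked the string ``"absent"`` rather than silently False.
    """
    rules = rules or PerceptionRules()
    result: dict[str, object] = {}
    residues_by_label = receptor.residues()
    for label in residues:
        matches = _resolve_residue_label(label, receptor)
        if not matches:
            result[label] = "absent"
            continue
        atoms = [a for m in matches for a in residues_by_label[m]]
        sub = ComplexStructure(receptor.complex_id, atoms, pose)
        contact = bool(detect_hbonds(sub, rules.max_da, rules.min_angle))
        if not contact:
            apolar = _protein_apolar_carbons(sub)
            lig_c = [a.coords for a in pose.atoms
                     if a.element.upper() == "C"]
            if apolar and lig_c:
                pc = np.array([a.coords for a in apolar])
                lc = np.array(lig_c)
                from scipy.spatial.distance import cdist
                contact = bool(np.any(cdist(lc, pc) <= rules.hyd_contact + 1e-12))
        result[label] = contact
    return result


def final_report(hits, reports: list[FilterReport],
                 criteria: dict | None = None) -> pd.DataFrame:
    """Join screening hits with filter reports and apply configured gates.

    `criteria` keys: ``require_lipinski`` (bool), ``required_contacts``
    (residue labels that must be True), ``min_external_score`` (float).
    Gates only remove or flag rows; passing hits keep their screening order.
    The result carries a ``final`` flag and a ``reasons`` column naming each
    failed gate.
    """
    criteria = criteria or {}
    by_id = {r.molecule_id: r for r in reports}
    missing = [h.molecule_id for h in hits if h.molecule_id not in by_id]
    if missing:
        raise ValueError(f"join failure: no filter report for {missing}")

    rows = []
    for h in hits:
        r = by_id[h.molecule_id]
        reasons = []
        if criteria.get("require_lipinski") and not r.lipinski_pass:
            reasons.append("lipinski")
        for res in criteria.get("required_contacts", []):
            if r.key_contacts.get(res) is not True:
                reasons.append(f"contact:{res}")
        min_ext = criteria.get("min_external_score")
        if min_ext is not None:
            if r.external_score is None or r.external_score < min_ext:
                reasons.append("external_score")
        rows.append({
            "molecule_id": h.molecule_id,
            "rank": h.rank,
            "fit": h.best.fit,
            "conformer_index": h.best.conformer_index,
            "mw": r.mw, "hbd": r.hbd_count, "hba": r.hba_count,
            "logp": r.logp, "lipinski_pass": r.lipinski_pass,
            "external_score": r.external_score,
            "final": not reasons,
            "reasons": ";".join(reasons),
        })
    return pd.DataFrame(rows)
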