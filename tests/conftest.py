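"""Shared fixtures: toy PDB text, planted ensembles, consensus model."""
import numpy as np
import pytest

from sbpharm import (build_model, cluster_features, excluded_volumes_for,
                     make_complex_ensemble, perceive, select_clusters)
from sbpharm.complex_io import AtomRecord, ComplexStructure, LigandMolecule
from sbpharm.fixtures import table1_spec


def pdb_line(rec, serial, name, res, chain, resnum, x, y, z, element,
             charge=""):
    name_f = name if len(name) >= 4 else f" {name:<3}"
    return (f"{rec:<6}{serial:>5} {name_f:<4} {res:<3} {chain}{resnum:>4}"
            f"    {x:>8.3f}{y:>8.3f}{z:>8.3f}{1.0:>6.2f}{0.0:>6.2f}"
            f"          {element:>2}{charge:<2}").rstrip()


@pytest.fixture
def toy_pdb():
    """Five protein atoms, three waters, one 4-atom MSP ligand, one Na ion."""
    lines = [
        pdb_line("ATOM", 1, "N", "GLY", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line("ATOM", 2, "CA", "GLY", "A", 1, 1.5, 0.0, 0.0, "C"),
        pdb_line("ATOM", 3, "C", "GLY", "A", 1, 2.2, 1.3, 0.0, "C"),
        pdb_line("ATOM", 4, "O", "GLY", "A", 1, 1.6, 2.4, 0.0, "O"),
        pdb_line("ATOM", 5, "CA", "ALA", "A", 2, 4.0, 1.5, 0.5, "C"),
        "TER",
        pdb_line("HETATM", 6, "C1", "MSP", "A", 100, 8.0, 8.0, 8.0, "C"),
        pdb_line("HETATM", 7, "C2", "MSP", "A", 100, 9.4, 8.0, 8.0, "C"),
        pdb_line("HETATM", 8, "O1", "MSP", "A", 100, 10.1, 9.1, 8.0, "O"),
        pdb_line("HETATM", 9, "N1", "MSP", "A", 100, 10.0, 6.8, 8.0, "N"),
        pdb_line("HETATM", 10, "O", "HOH", "A", 201, 20.0, 0.0, 0.0, "O"),
        pdb_line("HETATM", 11, "O", "HOH", "A", 202, 21.0, 0.0, 0.0, "O"),
        pdb_line("HETATM", 12, "O", "HOH", "A", 203, 22.0, 0.0, 0.0, "O"),
        pdb_line("HETATM", 13, "NA", "NA", "A", 301, 25.0, 0.0, 0.0, "NA"),
        "CONECT    6    7",
        "CONECT    7    8",
        "CONECT    7    9",
        "END",
    ]
    return "\n".join(lines) + "\n"


def chain_complex(n_res=12, seed=0, complex_id="ref"):
    """A minimal all-CA protein chain plus a 2-atom ligand, for
    superposition tests."""
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_res):
        pos = np.array([3.8 * i, 0.0, 0.0]) + rng.normal(0, 2.0, 3)
        atoms.append(AtomRecord(i + 1, "CA", "C", pos, "GLY", i + 1, "A"))
    lig_atoms = [
        AtomRecord(900, "C1", "C", np.array([5.0, 6.0, 1.0]), "LIG", 900,
                   "A", True),
        AtomRecord(901, "O1", "O", np.array([6.2, 6.5, 1.0]), "LIG", 900,
                   "A", True),
    ]
    ligand = LigandMolecule(lig_atoms, [(0, 1, 1)], [0, 0])
    return ComplexStructure(complex_id, atoms, ligand)


# study conditions: 14 complexes, 19 planted sites, 0.3 A noise
ENSEMBLE_SEED = 11


@pytest.fixture(scope="session")
def ensemble():
    return make_complex_ensemble(table1_spec(seed=ENSEMBLE_SEED, noise_sd=0.3))


@pytest.fixture(scope="session")
def pooled_features(ensemble):
    return [f for cx in ensemble for f in perceive(cx)]


@pytest.fixture(scope="session")
def clusters(pooled_features):
    return cluster_features(pooled_features, 2.0, n_complexes=14)


@pytest.fixture(scope="session")
def model(ensemble, clusters):
    return build_model(select_clusters(clusters, 60),
                       excluded_volumes_for(ensemble),
                       {"n_complexes": 14, "threshold": 60,
                        "provenance": [c.complex_id for c in ensemble]})
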