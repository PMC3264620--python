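import numpy as np
import pytest

from abhelix.model_io import (
    AtomRecord,
    Frame,
    Topology,
    assign_formal_charges,
    attach_ligand,
    build_alpha_helix,
    build_peptide,
    load_ligand_spec,
)


@pytest.fixture(scope="session")
def ideal_helix():
    """Capped A-beta(13-26) built as a canonical alpha helix."""
    return build_alpha_helix()


@pytest.fixture(scope="session")
def extended_chain():
    return build_peptide("HHQKLVFFAEDVGS", 13, -135.0, 135.0)


@pytest.fixture(scope="session")
def dec_spec():
    return load_ligand_spec("dec_deta")


@pytest.fixture(scope="session")
def pep_spec():
    return load_ligand_spec("pep1b")


@pytest.fixture(scope="session")
def helix_with_dec(ideal_helix, dec_spec):
    """Helix plus Dec-DETA parked 50 A away (no contacts by construction)."""
    topo, frame = ideal_helix
    n = len(dec_spec.heavy_atoms)
    far = np.full((n, 3), 50.0) + 1.5 * np.arange(n)[:, None]
    t2, f2 = attach_ligand(topo, frame, dec_spec, far)
    return t2, f2


@pytest.fixture(scope="session")
def helix_with_pep(ideal_helix, pep_spec):
    topo, frame = ideal_helix
    n = len(pep_spec.heavy_atoms)
    far = np.full((n, 3), 50.0) + 1.5 * np.arange(n)[:, None]
    t2, f2 = attach_ligand(topo, frame, pep_spec, far)
    return t2, f2


def move_ligand_atom(topology, frame, atom_name, new_pos):
    """Copy of the frame with one ligand atom moved to an absolute position."""
    coords = frame.coords.copy()
    coords[topology.atom_index(0, atom_name, "ligand")] = new_pos
    return Frame(frame.time_ps, coords)


def two_atom_system(distance, elements=("N", "O")):
    """Minimal two-heavy-atom topology/frame pair at a given separation."""
    atoms = [
        AtomRecord(elements[0], elements[0], 13, "HIS", "peptide"),
        AtomRecord(elements[1], elements[1], 14, "HIS", "peptide"),
    ]
    topo = Topology(atoms=atoms, sequence="HH", first_index=13)
    frame = Frame(0.0, np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]]))
    return topo, frame
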