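"""Hydrogen bonds, alpha-helical HB counts, contact maps, nonpolar contacts.

All criteria are plain distance cutoffs, as used throughout the analysis
protocol: a hydrogen bond exists when the acceptor-hydrogen distance is
<= 2.4 A (no angular term); a residue-ligand contact when the sidechain
COG to ligand-heavy-atom distance is <= 6.0 A; a nonpolar C-C/C-N
contact when the distance is <= 5.0 A.  Ties at the boundary count as
contacts.  Bifurcated hydrogen bonds (one hydrogen within the cutoff of
two acceptors) count once per (hydrogen, acceptor) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from abhelix.model_io import (
    Frame,
    LigandSpec,
    Topology,
    Trajectory,
)
from abhelix.geometry import sidechain_center_of_geometry

__all__ = [
    "HBond",
    "detect_hbonds",
    "backbone_donors",
    "peptide_donors",
    "peptide_acceptors",
    "ligand_donors",
    "ligand_acceptors",
    "count_alpha_hbs",
    "ligand_peptide_hbonds",
    "residue_ligand_contact",
    "contact_map",
    "nonpolar_contacts",
    "dual_mode_binding",
    "HB_CUTOFF",
    "CONTACT_CUTOFF",
    "NONPOLAR_CUTOFF",
]

HB_CUTOFF = 2.4        # acceptor-hydrogen distance, Angstrom
CONTACT_CUTOFF = 6.0   # sidechain COG to ligand heavy atom, Angstrom
NONPOLAR_CUTOFF = 5.0  # C-C / C-N distance, Angstrom

_BASIC_RES = ("HIS", "LYS")
_ACIDIC_RES = ("ASP", "GLU")


@dataclass(frozen=True)
class HBond:
    """One detected hydrogen bond (topology atom indices)."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance: float

    def describe(self, topology: Topology) -> str:
        d = topology.atoms[self.donor_index]
        h = topology.atoms[self.hydrogen_index]
        a = topology.atoms[self.acceptor_index]
        return (
            f"{d.residue_name}{d.residue_index}:{h.atom_name} -> "
            f"{a.residue_name}{a.residue_index}:{a.atom_name} "
            f"({self.distance:.2f} A)"
        )


# ---------------------------------------------------------------------------
# donor / acceptor enumeration

def _donor_pairs(topology: Topology, segment: str,
                 backbone_only: bool = False,
                 sidechain_only: bool = False) -> list[tuple[int, int]]:
    pairs = []
    for i, a in enumerate(topology.atoms):
        if a.segment != segment or not a.attached_polar_hydrogens:
            continue
        if backbone_only and not a.is_backbone:
            continue
        if sidechain_only and a.is_backbone:
            continue
        for h in a.attached_polar_hydrogens:
            pairs.append(
                (i, topology.atom_index(a.residue_index, h, a.segment))
            )
    return pairs


def backbone_donors(topology: Topology) -> list[tuple[int, int]]:
    """Peptide backbone N-HN donor (heavy, hydrogen) index pairs."""
    return _donor_pairs(topology, "peptide", backbone_only=True)


def peptide_donors(topology: Topology) -> list[tuple[int, int]]:
    return _donor_pairs(topology, "peptide")


def ligand_donors(topology: Topology) -> list[tuple[int, int]]:
    return _donor_pairs(topology, "ligand")


def peptide_acceptors(topology: Topology,
                      backbone_only: bool = False) -> list[int]:
    return [
        i for i, a in enumerate(topology.atoms)
        if a.segment == "peptide" and a.is_hb_acceptor
        and (a.is_backbone or not backbone_only)
    ]


def ligand_acceptors(topology: Topology) -> list[int]:
    return [
        i for i, a in enumerate(topology.atoms)
        if a.segment == "ligand" and a.is_hb_acceptor
    ]


# ---------------------------------------------------------------------------
# hydrogen bonds

def detect_hbonds(frame: Frame, topology: Topology,
                  donors: list[tuple[int, int]], acceptors: list[int],
                  cutoff: float = HB_CUTOFF) -> list[HBond]:
    """All (hydrogen, acceptor) pairs within the distance cutoff.

    Pairs where donor and acceptor sit in the same residue of the same
    segment are excluded (a group cannot hydrogen-bond to itself).
    """
    if not donors or not acceptors:
        return []
    hyd = np.array([h for _, h in donors])
    acc = np.array(acceptors)
    dist = np.linalg.norm(
        frame.coords[hyd][:, None, :] - frame.coords[acc][None, :, :], axis=2
    )
    out = []
    for di, (d, h) in enumerate(donors):
        datom = topology.atoms[d]
        for ai, a in enumerate(acceptors):
            aatom = topology.atoms[a]
            if (datom.segment == aatom.segment
                    and datom.residue_index == aatom.residue_index):
                continue
            if dist[di, ai] <= cutoff:
                out.append(HBond(d, h, a, float(dist[di, ai])))
    return out


def count_alpha_hbs(frame: Frame, topology: Topology,
                    region: tuple[int, int] = (15, 24),
                    cutoff: float = HB_CUTOFF) -> int:
    """Number of alpha-helical O(i)-HN(i+4) bonds with both residues in region."""
    lo, hi = region
    count = 0
    for i in range(lo, hi - 3):
        if not (topology.has_atom(i, "O") and topology.has_atom(i + 4, "HN")):
            continue
        o = frame.coords[topology.atom_index(i, "O")]
        hn = frame.coords[topology.atom_index(i + 4, "HN")]
        if np.linalg.norm(o - hn) <= cutoff:
            count += 1
    return count


def ligand_peptide_hbonds(frame: Frame, topology: Topology,
                          cutoff: float = HB_CUTOFF) -> list[HBond]:
    """Hydrogen bonds between peptide and ligand, both directions.

    Peptide sidechain and backbone atoms are both eligible as donors and
    acceptors; the ligand roles come from the topology annotations built
    from its LigandSpec.
    """
    if not topology.has_ligand:
        raise ValueError("topology has no ligand")
    bonds = detect_hbonds(
        frame, topology, peptide_donors(topology), ligand_acceptors(topology),
        cutoff,
    )
    bonds += detect_hbonds(
        frame, topology, ligand_donors(topology), peptide_acceptors(topology),
        cutoff,
    )
    return bonds


# ---------------------------------------------------------------------------
# residue-ligand contacts

def residue_ligand_contact(frame: Frame, topology: Topology,
                           residue_index: int, ligand_atom: str,
                           cutoff: float = CONTACT_CUTOFF) -> bool:
    """Sidechain-COG to ligand-heavy-atom contact at the distance cutoff."""
    atom = topology.atoms[topology.atom_index(0, ligand_atom, "ligand")]
    if not atom.is_heavy:
        raise ValueError(f"{ligand_atom} is not a heavy atom")
    cog = sidechain_center_of_geometry(frame, topology, residue_index)
    pos = frame.coords[topology.atom_index(0, ligand_atom, "ligand")]
    return bool(np.linalg.norm(cog - pos) <= cutoff)


def contact_map(trajectory: Trajectory, ligand_spec: LigandSpec,
                cutoff: float = CONTACT_CUTOFF) -> pd.DataFrame:
    """Per-cell contact probability over analyzable frames.

    Rows are peptide residues (caps excluded), columns the ligand heavy
    atoms in LigandSpec order; every value is (frames in contact) /
    (frames analyzed), hence in [0, 1].
    """
    traj = trajectory.analyzable()
    topo = traj.topology
    residues = topo.residue_indices
    lig_idx = np.array([
        topo.atom_index(0, n, "ligand") for n in ligand_spec.heavy_atoms
    ])
    counts = np.zeros((len(residues), len(lig_idx)))
    for fr in traj.frames:
        cogs = np.stack([
            sidechain_center_of_geometry(fr, topo, ri) for ri in residues
        ])
        d = np.linalg.norm(
            cogs[:, None, :] - fr.coords[lig_idx][None, :, :], axis=2
        )
        counts += d <= cutoff
    probs = counts / traj.n_frames
    return pd.DataFrame(probs, index=residues,
                        columns=list(ligand_spec.heavy_atoms))


def nonpolar_contacts(frame: Frame, topology: Topology,
                      ligand_spec: LigandSpec,
                      cutoff: float = NONPOLAR_CUTOFF,
                      region: tuple[int, int] | None = None) -> int:
    """C-C / C-N contact count between the middle nonpolar part and ligand.

    Pairs a peptide carbon of the nonpolar region (17-21; backbone
    carbonyl carbons excluded) with each ligand nonpolar atom at the
    distance cutoff.
    """
    if region is None:
        region = topology.region_nonpolar
    lo, hi = region
    pep_idx = [
        i for i, a in enumerate(topology.atoms)
        if a.segment == "peptide" and a.element == "C"
        and lo <= a.residue_index <= hi
        and not a.is_backbone_carbonyl_carbon
        and a.residue_name not in ("ACE", "NH2")
    ]
    lig_idx = [
        topology.atom_index(0, n, "ligand") for n in ligand_spec.nonpolar_atoms
    ]
    if not pep_idx or not lig_idx:
        return 0
    d = np.linalg.norm(
        frame.coords[pep_idx][:, None, :]
        - frame.coords[lig_idx][None, :, :], axis=2,
    )
    return int(np.sum(d <= cutoff))


# ---------------------------------------------------------------------------
# dual-mode binding

def dual_mode_binding(hbonds: list[HBond], topology: Topology,
                      ligand_spec: LigandSpec) -> bool:
    """Simultaneous two-sided charge-complementary hydrogen bonding.

    True iff, within one frame's HB list, some ligand basic-group donor
    bonds a peptide acidic sidechain acceptor AND some peptide basic
    sidechain donor bonds a ligand acidic-group acceptor.  A ligand with
    no acidic groups (Dec-DETA) can never satisfy the second condition.
    """
    basic = set(ligand_spec.basic_atoms)
    acidic = set(ligand_spec.acidic_atoms)
    lig_basic_to_pep_acid = False
    pep_basic_to_lig_acid = False
    for hb in hbonds:
        d = topology.atoms[hb.donor_index]
        a = topology.atoms[hb.acceptor_index]
        if (d.segment == "ligand" and d.atom_name in basic
                and a.segment == "peptide" and not a.is_backbone
                and a.residue_name in _ACIDIC_RES):
            lig_basic_to_pep_acid = True
        if (d.segment == "peptide" and not d.is_backbone
                and d.residue_name in _BASIC_RES
                and a.segment == "ligand" and a.atom_name in acidic):
            pep_basic_to_lig_acid = True
    return lig_basic_to_pep_acid and pep_basic_to_lig_acid
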