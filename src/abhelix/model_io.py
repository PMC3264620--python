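"""Molecular data model, ideal-helix construction, charges, and trajectory I/O.

The system modelled here is the amyloid-beta fragment A-beta(13-26)
(sequence HHQKLVFFAEDVGS, biological numbering 13-26) capped with an
N-terminal acetyl (ACE, index 12) and a C-terminal amide (NH2, index 27),
optionally accompanied by a small designed ligand (Dec-DETA or Pep1b)
described by a :class:`LigandSpec`.

Geometry is built by internal-coordinate chain extension (NeRF) with
standard bond lengths and angles; sidechain heavy atoms and polar
hydrogens are grafted from the CCD ideal residue templates shipped with
biotite.  Nonpolar hydrogens are not modelled: every analysis in this
package uses heavy atoms and polar (donor) hydrogens only.

Coordinates are in Angstrom, times in picoseconds, charges in units of e.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "AtomRecord",
    "Topology",
    "LigandSpec",
    "Frame",
    "Trajectory",
    "build_alpha_helix",
    "build_peptide",
    "assign_formal_charges",
    "net_charge",
    "load_ligand_spec",
    "packaged_ligand_names",
    "read_trajectory",
    "write_trajectory",
    "write_pdb",
    "ATOMIC_MASSES",
    "REGION_MID",
    "REGION_NONPOLAR",
]

# ---------------------------------------------------------------------------
# constants

AA1_TO_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
AA3_TO_1 = {v: k for k, v in AA1_TO_3.items()}

ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}

ABETA_13_26 = "HHQKLVFFAEDVGS"
REGION_MID = (15, 24)        # the central helix analysed throughout
REGION_NONPOLAR = (17, 21)   # LVFFA, the middle nonpolar part

# backbone internal coordinates (Engh & Huber-like standard values)
B_N_CA = 1.458
B_CA_C = 1.525
B_C_N = 1.329
B_C_O = 1.231
B_N_H = 1.000
A_N_CA_C = 111.2
A_CA_C_N = 116.2
A_C_N_CA = 121.7
A_CA_C_O = 120.8
A_C_N_H = 119.2
OMEGA = 180.0

# sidechain donor hydrogens retained per residue (doubly protonated His,
# protonated Lys, neutral Ser/Gln; Asp/Glu are deprotonated: no acidic H)
_SIDECHAIN_POLAR_H = {
    "HIS": {"HD1": "ND1", "HE2": "NE2"},
    "LYS": {"HZ1": "NZ", "HZ2": "NZ", "HZ3": "NZ"},
    "SER": {"HG": "OG"},
    "GLN": {"HE21": "NE2", "HE22": "NE2"},
}
# CCD template hydrogen names that map onto the names above
_CCD_H_ALIASES = {"HG1": "HG"}

# sidechain hydrogen-bond acceptors (heavy atoms)
_SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "SER": {"OG"},
    "GLN": {"OE1"},
}

# formal charges of ionizable sidechains in their charged states
_SIDECHAIN_CHARGE = {"HIS": ("ND1", +1), "LYS": ("NZ", +1),
                     "ASP": ("OD2", -1), "GLU": ("OE2", -1)}


# ---------------------------------------------------------------------------
# domain types

@dataclass
class AtomRecord:
    """One atom of the peptide or ligand with its analysis roles."""

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    segment: str                    # "peptide" | "ligand"
    is_backbone: bool = False
    is_backbone_carbonyl_carbon: bool = False
    attached_polar_hydrogens: tuple[str, ...] = ()
    is_hb_acceptor: bool = False
    formal_charge: int = 0

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def __post_init__(self) -> None:
        if self.is_backbone_carbonyl_carbon and not (
            self.is_backbone and self.element == "C"
        ):
            raise ValueError(
                f"{self.atom_name}: backbone carbonyl carbon must be a "
                "backbone C atom"
            )
        if self.attached_polar_hydrogens and self.element not in ("N", "O"):
            raise ValueError(
                f"{self.atom_name}: polar hydrogens can only attach to N or O"
            )


@dataclass
class Topology:
    """Ordered atoms of one peptide(+ligand) system."""

    atoms: list[AtomRecord]
    sequence: str
    first_index: int = 13
    ligand_name: str | None = None
    charges_assigned: bool = False
    region_mid: tuple[int, int] = REGION_MID
    region_nonpolar: tuple[int, int] = REGION_NONPOLAR

    def __post_init__(self) -> None:
        self._index = {
            (a.residue_index, a.atom_name, a.segment): i
            for i, a in enumerate(self.atoms)
        }

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residue_indices(self) -> list[int]:
        """Peptide residue indices (caps excluded)."""
        last = self.first_index + len(self.sequence) - 1
        return list(range(self.first_index, last + 1))

    def atom_index(self, residue_index: int, atom_name: str,
                   segment: str = "peptide") -> int:
        key = (residue_index, atom_name, segment)
        if key not in self._index:
            raise KeyError(
                f"no atom {atom_name} in {segment} residue {residue_index}"
            )
        return self._index[key]

    def has_atom(self, residue_index: int, atom_name: str,
                 segment: str = "peptide") -> bool:
        return (residue_index, atom_name, segment) in self._index

    @property
    def has_ligand(self) -> bool:
        return any(a.segment == "ligand" for a in self.atoms)

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[a.element] for a in self.atoms])


@dataclass(frozen=True)
class LigandSpec:
    """Named heavy-atom subsets and hydrogen-bond roles of a ligand.

    ``basic_groups`` / ``acidic_groups`` partition the charged functional
    groups; each basic group carries +1e and each acidic group -1e.
    ``nonpolar_atoms`` are the atoms entering the C-C/C-N contact count
    (the Dec-DETA hydrocarbon tail C1-C9; the Pep1b indole C13-C20 + N3).
    """

    name: str
    heavy_atoms: tuple[str, ...]
    basic_groups: tuple[tuple[str, ...], ...]
    acidic_groups: tuple[tuple[str, ...], ...]
    nonpolar_atoms: tuple[str, ...]
    donor_hydrogens: dict[str, tuple[str, ...]]
    extra_acceptors: tuple[str, ...] = ()
    nonpolar_target_residue: int | None = None

    def __post_init__(self) -> None:
        heavy = set(self.heavy_atoms)
        basic = {a for g in self.basic_groups for a in g}
        acidic = {a for g in self.acidic_groups for a in g}
        for role, atoms in (
            ("basic", basic),
            ("acidic", acidic),
            ("nonpolar", set(self.nonpolar_atoms)),
            ("acceptor", set(self.extra_acceptors)),
            ("donor", set(self.donor_hydrogens)),
        ):
            unknown = atoms - heavy
            if unknown:
                raise ValueError(
                    f"{self.name}: {role} subset references unknown atom(s) "
                    f"{sorted(unknown)}"
                )
        if basic & acidic:
            raise ValueError(
                f"{self.name}: basic and acidic subsets overlap: "
                f"{sorted(basic & acidic)}"
            )
        missing = basic - set(self.donor_hydrogens)
        if missing:
            raise ValueError(
                f"{self.name}: basic atoms without donor hydrogens: "
                f"{sorted(missing)}"
            )

    @property
    def basic_atoms(self) -> tuple[str, ...]:
        return tuple(a for g in self.basic_groups for a in g)

    @property
    def acidic_atoms(self) -> tuple[str, ...]:
        return tuple(a for g in self.acidic_groups for a in g)

    @property
    def acceptor_atoms(self) -> tuple[str, ...]:
        return self.acidic_atoms + self.extra_acceptors

    @property
    def net_charge(self) -> int:
        return len(self.basic_groups) - len(self.acidic_groups)


@dataclass
class Frame:
    """One coordinate snapshot (Angstrom) at a time point (ps)."""

    time_ps: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.time_ps < 0:
            raise ValueError("time_ps must be >= 0")


@dataclass
class Trajectory:
    """Time-ordered frames over one Topology."""

    topology: Topology
    frames: list[Frame]
    stride_ps: float = 10.0
    analysis_start_ps: float = 0.0

    def __post_init__(self) -> None:
        for k, fr in enumerate(self.frames):
            if fr.coords.shape[0] != self.topology.n_atoms:
                raise ValueError(
                    f"frame {k}: {fr.coords.shape[0]} atoms, topology has "
                    f"{self.topology.n_atoms}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])

    @property
    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coords for f in self.frames])

    def analyzable(self) -> "Trajectory":
        """Frames at or after ``analysis_start_ps`` (the heating period)."""
        kept = [f for f in self.frames if f.time_ps >= self.analysis_start_ps]
        if not kept:
            raise ValueError("no analyzable frames after analysis_start_ps")
        return Trajectory(self.topology, kept, self.stride_ps, 0.0)


# ---------------------------------------------------------------------------
# internal-coordinate placement (NeRF)

def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d bonded to c with angle(b,c,d) and torsion(a,b,c,d)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return math.degrees(math.atan2(y, x))


# ---------------------------------------------------------------------------
# residue templates (CCD ideal coordinates via biotite)

_TEMPLATE_CACHE: dict[str, tuple[list[str], np.ndarray, list[str]]] = {}


def _residue_template(resname: str):
    """Sidechain atom names + ideal coords, aligned to the N/CA/C frame.

    Returns (names, coords, elements) of sidechain heavy atoms and the
    polar hydrogens retained for ``resname``, expressed in the CCD ideal
    geometry, together with the template backbone N/CA/C coordinates
    (prepended as the first three rows, names "N", "CA", "C").
    """
    if resname in _TEMPLATE_CACHE:
        return _TEMPLATE_CACHE[resname]
    import biotite.structure.info as info

    res = info.residue(resname)
    names = list(res.atom_name)
    coord = {n: res.coord[i] for i, n in enumerate(names)}
    wanted: list[str] = []
    for n in names:
        if n in ("N", "CA", "C", "O", "OXT", "H", "H2", "HXT"):
            continue
        elem = "H" if n.startswith("H") else n[0]
        canon = _CCD_H_ALIASES.get(n, n)
        if elem == "H":
            keep = _SIDECHAIN_POLAR_H.get(resname, {})
            if canon in keep:
                wanted.append(n)
            continue
        # deprotonated acids keep no carboxyl hydrogens; drop any stray OXT-like
        wanted.append(n)
    out_names = ["N", "CA", "C"] + [_CCD_H_ALIASES.get(n, n) for n in wanted]
    out_coords = np.array(
        [coord["N"], coord["CA"], coord["C"]] + [coord[n] for n in wanted]
    )
    out_elems = ["N", "C", "C"] + [
        ("H" if n.startswith("H") else n[0]) for n in wanted
    ]
    _TEMPLATE_CACHE[resname] = (out_names, out_coords, out_elems)
    return _TEMPLATE_CACHE[resname]


def _kabsch_rt(mobile: np.ndarray, target: np.ndarray):
    """Rotation/translation superposing mobile onto target (least squares)."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


# ---------------------------------------------------------------------------
# peptide construction

def _backbone_coords(n_res: int, phi: np.ndarray, psi: np.ndarray):
    """Backbone + cap coordinates by chain extension.

    Returns dict keyed by (res_slot, atom_name) where slot -1 is the ACE
    cap, 0..n-1 the residues, n the NH2 cap.
    """
    xyz: dict[tuple[int, str], np.ndarray] = {}
    # ACE cap: CH3-C(=O)- placed in a fixed laboratory frame
    ch3 = np.array([0.0, 0.0, 0.0])
    c_ace = np.array([1.520, 0.0, 0.0])
    virt = np.array([0.0, 1.0, 0.0])
    o_ace = _place(virt, ch3, c_ace, B_C_O, 121.0, 0.0)
    xyz[(-1, "CH3")] = ch3
    xyz[(-1, "C")] = c_ace
    xyz[(-1, "O")] = o_ace
    prev_ca, prev_c, prev_o = ch3, c_ace, o_ace
    prev_n = virt  # torsion reference for the first residue's N is arbitrary
    for i in range(n_res):
        if i == 0:
            n = _place(o_ace, ch3, c_ace, B_C_N, A_CA_C_N, 180.0)
        else:
            n = _place(prev_n, prev_ca, prev_c, B_C_N, A_CA_C_N, psi[i - 1])
        hn = _place(prev_o, prev_c, n, B_N_H, A_C_N_H, 180.0)
        ca = _place(prev_ca, prev_c, n, B_N_CA, A_C_N_CA, OMEGA)
        c = _place(prev_c, n, ca, B_CA_C, A_N_CA_C, phi[i])
        o = _place(n, ca, c, B_C_O, A_CA_C_O, psi[i] + 180.0)
        xyz[(i, "N")] = n
        xyz[(i, "HN")] = hn
        xyz[(i, "CA")] = ca
        xyz[(i, "C")] = c
        xyz[(i, "O")] = o
        prev_n, prev_ca, prev_c, prev_o = n, ca, c, o
    # NH2 cap: -C(=O)-NH2 amide
    nt = _place(prev_n, prev_ca, prev_c, B_C_N, A_CA_C_N, psi[n_res - 1])
    ht1 = _place(prev_o, prev_c, nt, B_N_H, A_C_N_H, 180.0)
    ht2 = _place(prev_o, prev_c, nt, B_N_H, A_C_N_H, 0.0)
    xyz[(n_res, "N")] = nt
    xyz[(n_res, "HT1")] = ht1
    xyz[(n_res, "HT2")] = ht2
    return xyz


def build_peptide(sequence: str, first_index: int = 13,
                  phi_deg: Sequence[float] | float = -57.0,
                  psi_deg: Sequence[float] | float = -47.0,
                  ) -> tuple[Topology, Frame]:
    """Build a capped full-atom peptide from per-residue (phi, psi).

    Backbone (N, HN, CA, C, O plus ACE/NH2 caps) is generated by
    internal-coordinate chain extension; sidechain heavy atoms and polar
    hydrogens are grafted from ideal residue templates superposed on each
    residue's N/CA/C frame.  Deterministic: identical inputs give
    bitwise-identical coordinates.
    """
    sequence = sequence.strip().upper()
    if len(sequence) < 5:
        raise ValueError("sequence must have at least 5 residues")
    resnames = []
    for code in sequence:
        if code not in AA1_TO_3:
            raise ValueError(f"unknown residue code {code!r}")
        resnames.append(AA1_TO_3[code])
    n_res = len(resnames)
    phi = np.broadcast_to(np.asarray(phi_deg, dtype=float), (n_res,)).copy()
    psi = np.broadcast_to(np.asarray(psi_deg, dtype=float), (n_res,)).copy()
    bb = _backbone_coords(n_res, phi, psi)

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []

    def add(name, elem, resi, resn, **kw):
        atoms.append(AtomRecord(name, elem, resi, resn, "peptide", **kw))

    # ACE cap (index first_index - 1)
    cap_i = first_index - 1
    add("CH3", "C", cap_i, "ACE", is_backbone=True)
    coords.append(bb[(-1, "CH3")])
    add("C", "C", cap_i, "ACE", is_backbone=True,
        is_backbone_carbonyl_carbon=True)
    coords.append(bb[(-1, "C")])
    add("O", "O", cap_i, "ACE", is_backbone=True, is_hb_acceptor=True)
    coords.append(bb[(-1, "O")])

    for i, resn in enumerate(resnames):
        resi = first_index + i
        add("N", "N", resi, resn, is_backbone=True,
            attached_polar_hydrogens=("HN",))
        coords.append(bb[(i, "N")])
        add("HN", "H", resi, resn, is_backbone=True)
        coords.append(bb[(i, "HN")])
        add("CA", "C", resi, resn, is_backbone=True)
        coords.append(bb[(i, "CA")])
        add("C", "C", resi, resn, is_backbone=True,
            is_backbone_carbonyl_carbon=True)
        coords.append(bb[(i, "C")])
        add("O", "O", resi, resn, is_backbone=True, is_hb_acceptor=True)
        coords.append(bb[(i, "O")])
        # sidechain graft
        tnames, tcoords, telems = _residue_template(resn)
        if len(tnames) > 3:
            anchor = np.stack([bb[(i, "N")], bb[(i, "CA")], bb[(i, "C")]])
            rot, tr = _kabsch_rt(tcoords[:3], anchor)
            placed = tcoords[3:] @ rot.T + tr
            polar_h = _SIDECHAIN_POLAR_H.get(resn, {})
            acceptors = _SIDECHAIN_ACCEPTORS.get(resn, set())
            for name, elem, xyz in zip(tnames[3:], telems[3:], placed):
                if elem == "H":
                    add(name, "H", resi, resn)
                else:
                    attached = tuple(
                        h for h, heavy in polar_h.items() if heavy == name
                    )
                    add(name, elem, resi, resn,
                        attached_polar_hydrogens=attached,
                        is_hb_acceptor=name in acceptors)
                coords.append(xyz)

    # NH2 cap (index first_index + n_res)
    cap_j = first_index + n_res
    add("N", "N", cap_j, "NH2", is_backbone=True,
        attached_polar_hydrogens=("HT1", "HT2"))
    coords.append(bb[(n_res, "N")])
    add("HT1", "H", cap_j, "NH2", is_backbone=True)
    coords.append(bb[(n_res, "HT1")])
    add("HT2", "H", cap_j, "NH2", is_backbone=True)
    coords.append(bb[(n_res, "HT2")])

    topo = Topology(atoms=atoms, sequence=sequence, first_index=first_index)
    return topo, Frame(0.0, np.array(coords))


def build_alpha_helix(sequence: str = ABETA_13_26, first_index: int = 13,
                      phi_deg: float = -57.0, psi_deg: float = -47.0,
                      ) -> tuple[Topology, Frame]:
    """Build the capped peptide as an ideal alpha helix.

    With the canonical (-57, -47) backbone the A-beta(13-26) model carries
    ten O(i)-HN(i+4) backbone hydrogen bonds over residues 13-26, six of
    them inside the middle region 15-24.
    """
    return build_peptide(sequence, first_index, phi_deg, psi_deg)


def attach_ligand(topology: Topology, frame: Frame, spec: LigandSpec,
                  ligand_coords: np.ndarray,
                  hydrogen_coords: dict[str, np.ndarray] | None = None,
                  ) -> tuple[Topology, Frame]:
    """Append ligand atoms (heavy atoms in spec order, then donor H)."""
    atoms = list(topology.atoms)
    coords = [frame.coords]
    name_to_row = {n: i for i, n in enumerate(spec.heavy_atoms)}
    if ligand_coords.shape != (len(spec.heavy_atoms), 3):
        raise ValueError("ligand_coords must match spec.heavy_atoms")
    acceptors = set(spec.acceptor_atoms)
    lig_rows = []
    for n in spec.heavy_atoms:
        elem = "H" if n.startswith("H") else n[0]
        atoms.append(AtomRecord(
            n, elem, 0, spec.name.upper()[:3], "ligand",
            attached_polar_hydrogens=tuple(spec.donor_hydrogens.get(n, ())),
            is_hb_acceptor=n in acceptors,
        ))
        lig_rows.append(ligand_coords[name_to_row[n]])
    hcoords = hydrogen_coords or {}
    for heavy, hs in spec.donor_hydrogens.items():
        for h in hs:
            atoms.append(AtomRecord(h, "H", 0, spec.name.upper()[:3], "ligand"))
            if h in hcoords:
                lig_rows.append(np.asarray(hcoords[h], dtype=float))
            else:
                # default: 1.0 A from the heavy atom along +z
                lig_rows.append(
                    ligand_coords[name_to_row[heavy]] + np.array([0, 0, 1.0])
                )
    coords.append(np.array(lig_rows))
    topo = Topology(atoms=atoms, sequence=topology.sequence,
                    first_index=topology.first_index, ligand_name=spec.name)
    return topo, Frame(frame.time_ps, np.vstack(coords))


# ---------------------------------------------------------------------------
# charges

def assign_formal_charges(topology: Topology,
                          ligand_spec: LigandSpec | None = None) -> Topology:
    """Assign formal charges for fully charged ionizable groups.

    His/Lys sidechains +1e, Glu/Asp sidechains -1e, caps neutral; each
    ligand basic group +1e, each acidic group -1e.  Returns a new
    Topology with ``charges_assigned`` set.
    """
    atoms = [replace(a, formal_charge=0) for a in topology.atoms]
    for a in atoms:
        if a.segment != "peptide" or a.residue_name in ("ACE", "NH2"):
            continue
        rule = _SIDECHAIN_CHARGE.get(a.residue_name)
        if rule and a.atom_name == rule[0]:
            a.formal_charge = rule[1]
    if ligand_spec is not None:
        by_name = {a.atom_name: a for a in atoms if a.segment == "ligand"}
        if not by_name:
            raise ValueError(
                "ligand_spec given but topology has no ligand atoms"
            )
        for group in ligand_spec.basic_groups:
            by_name[group[0]].formal_charge += 1
        for group in ligand_spec.acidic_groups:
            by_name[group[0]].formal_charge -= 1
    topo = Topology(atoms=atoms, sequence=topology.sequence,
                    first_index=topology.first_index,
                    ligand_name=topology.ligand_name, charges_assigned=True)
    return topo


def net_charge(topology: Topology) -> int:
    """Sum of formal charges (e).  Fails if charges were never assigned."""
    if not topology.charges_assigned:
        raise ValueError(
            "formal charges not assigned; call assign_formal_charges first"
        )
    return int(sum(a.formal_charge for a in topology.atoms))


# ---------------------------------------------------------------------------
# ligand specs

def packaged_ligand_names() -> list[str]:
    return ["dec_deta", "pep1b"]


def load_ligand_spec(source) -> LigandSpec:
    """Load a LigandSpec from a packaged name, a YAML path, or a mapping.

    The packaged fixtures are ``"dec_deta"`` and ``"pep1b"``.
    """
    if isinstance(source, LigandSpec):
        return source
    if isinstance(source, dict):
        cfg = source
    else:
        name = str(source)
        if name in packaged_ligand_names():
            text = (resources.files("abhelix.data") / f"{name}.yaml").read_text()
        else:
            with open(name) as fh:
                text = fh.read()
        cfg = yaml.safe_load(text)
    try:
        return LigandSpec(
            name=cfg["name"],
            heavy_atoms=tuple(cfg["heavy_atoms"]),
            basic_groups=tuple(tuple(g) for g in cfg.get("basic_groups", [])),
            acidic_groups=tuple(tuple(g) for g in cfg.get("acidic_groups", [])),
            nonpolar_atoms=tuple(cfg.get("nonpolar_atoms", [])),
            donor_hydrogens={
                k: tuple(v) for k, v in cfg.get("donor_hydrogens", {}).items()
            },
            extra_acceptors=tuple(cfg.get("extra_acceptors", [])),
            nonpolar_target_residue=cfg.get("nonpolar_target_residue"),
        )
    except KeyError as exc:
        raise ValueError(f"ligand config missing required key {exc}") from exc


# ---------------------------------------------------------------------------
# trajectory I/O

def _topology_from_atom_table(res_ids, res_names, atom_names,
                              ligand_spec: LigandSpec | None):
    """Rebuild a roles-annotated Topology matching a parsed atom table."""
    pep_ids = sorted({
        int(i) for i, rn in zip(res_ids, res_names)
        if rn not in ("ACE", "NH2") and rn in AA3_TO_1
    })
    if not pep_ids:
        raise ValueError("no peptide residues found in file")
    first = pep_ids[0]
    seq = []
    for ri in range(first, pep_ids[-1] + 1):
        rn = next(r for i, r in zip(res_ids, res_names) if int(i) == ri)
        seq.append(AA3_TO_1[rn])
    topo, frame = build_peptide("".join(seq), first)
    if ligand_spec is not None:
        n_lig = len(ligand_spec.heavy_atoms) + sum(
            len(v) for v in ligand_spec.donor_hydrogens.values()
        )
        topo, frame = attach_ligand(
            topo, frame, ligand_spec,
            np.zeros((len(ligand_spec.heavy_atoms), 3)),
        )
    expected = [a.atom_name for a in topo.atoms]
    got = list(atom_names)
    if expected != got:
        raise ValueError(
            "atom names in file do not match the reconstructed topology "
            f"(expected {len(expected)} atoms, file has {len(got)}; first "
            f"difference at position "
            f"{next((k for k, (e, g) in enumerate(zip(expected, got)) if e != g), min(len(expected), len(got)))})"
        )
    return topo


def write_pdb(topology: Topology, frames: Frame | Iterable[Frame],
              path) -> None:
    """Write one or more frames as (multi-model) PDB via biotite."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    n = topology.n_atoms
    arr = struc.AtomArrayStack(len(frames), n)
    arr.coord = np.stack([f.coords for f in frames])
    arr.chain_id = np.array(
        ["A" if a.segment == "peptide" else "L" for a in topology.atoms]
    )
    arr.res_id = np.array([a.residue_index for a in topology.atoms])
    arr.res_name = np.array([a.residue_name for a in topology.atoms])
    arr.atom_name = np.array([a.atom_name for a in topology.atoms])
    arr.element = np.array([a.element for a in topology.atoms])
    arr.hetero = np.array([a.segment == "ligand" for a in topology.atoms])
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def write_trajectory(trajectory: Trajectory, path, format: str = "pdb",
                     ) -> None:
    """Write a trajectory as multi-model PDB or the internal npz format."""
    if format == "pdb":
        write_pdb(trajectory.topology, trajectory.frames, path)
    elif format == "internal":
        np.savez(
            path,
            times=trajectory.times,
            coords=trajectory.coords,
            atom_names=np.array(
                [a.atom_name for a in trajectory.topology.atoms]
            ),
            sequence=np.array(trajectory.topology.sequence),
            first_index=np.array(trajectory.topology.first_index),
            stride_ps=np.array(trajectory.stride_ps),
            analysis_start_ps=np.array(trajectory.analysis_start_ps),
        )
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def _check_pdb_model_atom_counts(text: str) -> int:
    """Validate equal atom counts across MODEL blocks; return count/model."""
    counts = []
    current = None
    saw_model = False
    for line in text.splitlines():
        rec = line[:6].strip()
        if rec == "MODEL":
            saw_model = True
            current = 0
        elif rec in ("ATOM", "HETATM"):
            if current is None:
                current = 0
            current += 1
        elif rec == "ENDMDL":
            counts.append(current or 0)
            current = None
    if not saw_model and current is not None:
        counts.append(current)
    if not counts or all(c == 0 for c in counts):
        raise ValueError("no atom records found in PDB file")
    ref = counts[0]
    for k, c in enumerate(counts):
        if c != ref:
            raise ValueError(
                f"atom-count mismatch in model {k + 1}: {c} atoms, "
                f"model 1 has {ref}"
            )
    return ref


def read_trajectory(path, format: str = "pdb",
                    ligand_spec: LigandSpec | str | None = None,
                    stride_ps: float | None = None,
                    analysis_start_ps: float = 0.0,
                    times_ps: Sequence[float] | None = None) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory`.

    PDB carries no time axis, so frame times default to ``stride_ps``
    spacing (or explicit ``times_ps``).  The Topology is reconstructed
    from the residue sequence (plus ``ligand_spec`` for complexes) and
    validated atom-by-atom against the file.
    """
    if ligand_spec is not None:
        ligand_spec = load_ligand_spec(ligand_spec)
    if format == "internal":
        with np.load(path) as npz:
            times = npz["times"]
            coords = npz["coords"]
            atom_names = [str(s) for s in npz["atom_names"]]
            seq = str(npz["sequence"])
            first = int(npz["first_index"])
            stride = float(npz["stride_ps"])
            start = float(npz["analysis_start_ps"])
        topo, _ = build_peptide(seq, first)
        if ligand_spec is not None:
            topo, _ = attach_ligand(
                topo, Frame(0.0, np.zeros((topo.n_atoms, 3))), ligand_spec,
                np.zeros((len(ligand_spec.heavy_atoms), 3)))
            # rebuild dropped the coords; only the topology is kept
        if [a.atom_name for a in topo.atoms] != atom_names:
            raise ValueError("stored atom names do not match topology")
        frames = [Frame(t, c) for t, c in zip(times, coords)]
        return Trajectory(topo, frames, stride, start)
    if format != "pdb":
        raise ValueError(f"unknown trajectory format {format!r}")

    from biotite.structure.io.pdb import PDBFile

    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty PDB file: {path}")
    _check_pdb_model_atom_counts(text)
    pdb = PDBFile.read(io.StringIO(text))
    stack = pdb.get_structure(model=None)
    topo = _topology_from_atom_table(
        stack.res_id, stack.res_name, stack.atom_name, ligand_spec
    )
    stride = 10.0 if stride_ps is None else float(stride_ps)
    n = stack.stack_depth()
    if times_ps is not None:
        if len(times_ps) != n:
            raise ValueError("times_ps length does not match model count")
        times = np.asarray(times_ps, dtype=float)
    else:
        times = np.arange(n) * stride
    frames = [Frame(t, stack.coord[k]) for k, t in enumerate(times)]
    return Trajectory(topo, frames, stride, analysis_start_ps)
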