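"""Synthetic peptide(+ligand) trajectories with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes for a 20 ns run sampled every 10 ps: per-residue helix/coil
two-state continuous-time Markov chains (no cooperativity), a two-state
bound/unbound chain for the ligand, and a protection factor rho >= 1
dividing the per-residue unfolding rate while the ligand is bound.
Chains are sampled exactly at the stride via the closed-form two-state
transition probabilities, not by Euler discretization.

Coordinates are rebuilt per frame by internal-coordinate chain
extension: helical residues get (phi, psi) = (-57, -47) plus Gaussian
noise, coil residues sample an extended basin (-135, +135) plus noise.
The default noise SD (0.8 deg) keeps the helical basin narrow enough
that a fully helical stretch retains all of its i,i+4 hydrogen bonds at
the 2.4 A criterion (the ideal-helix O-HN distance is 2.12 A, so the
basin must stay within ~0.3 A of it); conformational fluctuation is
carried by the helix/coil chain, not the jitter.
When bound, the rigid ligand is placed so its charged groups sit within
hydrogen-bond range of their designed targets (basic donors at E22/D23
acceptors; acidic acceptors, if any, at K16/H13 donor hydrogens); when
unbound it is displaced far (>= 15 A) from the peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from abhelix.model_io import (
    ABETA_13_26,
    Frame,
    LigandSpec,
    Topology,
    Trajectory,
    attach_ligand,
    build_peptide,
    load_ligand_spec,
)
from abhelix.geometry import sidechain_center_of_geometry

__all__ = [
    "SyntheticParams",
    "GroundTruth",
    "simulate",
    "expected_helicity",
    "HELIX_PHI_PSI",
    "COIL_PHI_PSI",
]

HELIX_PHI_PSI = (-57.0, -47.0)
COIL_PHI_PSI = (-135.0, 135.0)

# designed tether targets: ligand basic donors reach the acidic-residue
# sidechain acceptors, ligand acidic acceptors reach the basic-residue
# donor hydrogens
_BASIC_TARGETS = ((22, "OE1"), (23, "OD1"))      # E22, D23
_ACIDIC_TARGETS = ((16, "HZ1", "NZ"), (13, "HD1", "ND1"))  # K16, H13


@dataclass(frozen=True)
class SyntheticParams:
    """Generator settings; rates in 1/ns, stride in ps, noise in degrees."""

    seed: int
    sequence: str = ABETA_13_26
    first_index: int = 13
    n_frames: int = 2000
    stride_ps: float = 10.0
    k_u: float = 0.5               # helix -> coil, per residue
    k_f: float = 0.5               # coil -> helix, per residue
    k_on: float = 1.0              # ligand binding
    k_off: float = 0.4             # ligand unbinding
    protection_factor: float = 4.0  # divides k_u while bound
    dihedral_noise_deg: float = 0.8
    ligand_spec: LigandSpec | str | None = None

    def __post_init__(self) -> None:
        for name in ("k_u", "k_f", "k_on", "k_off"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.protection_factor < 1:
            raise ValueError("protection_factor must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.stride_ps <= 0:
            raise ValueError("stride_ps must be > 0")
        if self.dihedral_noise_deg < 0:
            raise ValueError("dihedral_noise_deg must be >= 0")

    def resolved_spec(self) -> LigandSpec | None:
        if self.ligand_spec is None:
            return None
        return load_ligand_spec(self.ligand_spec)


@dataclass(frozen=True)
class GroundTruth:
    """Hidden states realized by the generator plus their expectations."""

    expected_occupancy: float
    expected_helicity: np.ndarray      # per residue, stationary
    helix_states: np.ndarray           # (n_frames, n_residues) bool
    bound_states: np.ndarray           # (n_frames,) bool

    def to_frame(self, times_ps: np.ndarray,
                 first_index: int) -> pd.DataFrame:
        cols = {
            f"helix_{first_index + j}": self.helix_states[:, j]
            for j in range(self.helix_states.shape[1])
        }
        return pd.DataFrame({"time_ps": times_ps, "bound": self.bound_states,
                             **cols})


# ---------------------------------------------------------------------------
# two-state chain utilities

def _switch_prob(rate_out: float, rate_in: float, dt_ns: float) -> float:
    """P(leave current state within dt) for a two-state chain."""
    s = rate_out + rate_in
    if s == 0:
        return 0.0
    return (rate_out / s) * (1.0 - np.exp(-s * dt_ns))


def stationary_occupancy(k_on: float, k_off: float) -> float:
    if k_on == 0:
        return 0.0
    return k_on / (k_on + k_off)


def expected_helicity(params: SyntheticParams) -> np.ndarray:
    """Closed-form stationary helix probability per residue.

    Uses the occupancy-averaged effective unfolding rate
    k_u_eff = occ * k_u / rho + (1 - occ) * k_u.  With both rates zero
    the initial (helical) state persists, so the probability is 1.
    """
    occ = (stationary_occupancy(params.k_on, params.k_off)
           if params.ligand_spec is not None else 0.0)
    k_u_eff = occ * params.k_u / params.protection_factor \
        + (1.0 - occ) * params.k_u
    n = len(params.sequence)
    if params.k_f + k_u_eff == 0:
        return np.ones(n)
    return np.full(n, params.k_f / (params.k_f + k_u_eff))


# ---------------------------------------------------------------------------
# rigid ligand templates

def _indole_ring() -> dict[str, np.ndarray]:
    names6 = ["C13", "C14", "C15", "C16", "C17", "C18"]
    coords = {}
    for k, n in enumerate(names6):
        ang = np.pi / 3 * k
        coords[n] = np.array([1.39 * np.cos(ang), 1.39 * np.sin(ang), 0.0])
    # fused five-ring bump
    coords["C19"] = np.array([2.60, 0.95, 0.0])
    coords["C20"] = np.array([3.35, -0.20, 0.0])
    coords["N3"] = np.array([2.60, -1.30, 0.0])
    return coords


def _ligand_template(spec: LigandSpec) -> dict[str, np.ndarray]:
    """Plausible rigid coordinates for the packaged ligands.

    Synthetic stand-in geometries: atom spacing and group layout are
    realistic but the full bond graph of each ligand is not modelled.
    Unknown specs get a generic zig-zag chain.
    """
    t: dict[str, np.ndarray] = {}
    if spec.name == "dec_deta":
        for k in range(9):  # C9 ... C1 zig-zag tail
            t[f"C{9 - k}"] = np.array([1.25 * k, 0.0, 0.45 * (k % 2)])
        t["C11"] = np.array([11.5, 0.4, 0.0])
        t["O1"] = np.array([11.8, 1.6, 0.0])
        t["N2"] = np.array([13.2, -0.4, 0.0])
        t["N3"] = np.array([16.2, -0.4, 0.0])
    elif spec.name == "pep1b":
        t.update(_indole_ring())
        t["N5"] = np.array([-4.5, 2.5, 0.0])
        t["N6"] = np.array([-3.0, 3.5, 0.0])
        t["N7"] = np.array([4.5, 2.5, 0.0])
        t["N8"] = np.array([3.0, 3.5, 0.0])
        t["O1"] = np.array([-4.5, -2.5, 0.0])
        t["O2"] = np.array([-3.2, -3.3, 0.0])
        t["O3"] = np.array([0.0, -3.5, 0.0])
        t["O4"] = np.array([4.5, -2.5, 0.0])
        t["O5"] = np.array([3.2, -3.3, 0.0])
    else:
        for k, n in enumerate(spec.heavy_atoms):
            t[n] = np.array([1.4 * k, 0.0, 0.5 * (k % 2)])
    for heavy, hs in spec.donor_hydrogens.items():
        for j, h in enumerate(hs):
            t[h] = t[heavy] + np.array([0.0, -1.0, 0.2 * j])
    return t


def _ligand_atom_order(spec: LigandSpec) -> list[str]:
    order = list(spec.heavy_atoms)
    for heavy, hs in spec.donor_hydrogens.items():
        order.extend(hs)
    return order


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def _place_ligand_bound(spec: LigandSpec, template: dict[str, np.ndarray],
                        pep_frame: Frame, pep_topo: Topology,
                        rng: np.random.Generator) -> np.ndarray:
    """Place the rigid ligand so its charged groups hydrogen-bond.

    Representative donors/acceptors are pinned exactly at hydrogen-bond
    range of their targets (guaranteeing at least one peptide-ligand HB
    in every bound frame); the remaining atoms follow via a rigid fit.
    """
    coords = pep_frame.coords
    heavy = [i for i, a in enumerate(pep_topo.atoms)
             if a.segment == "peptide" and a.is_heavy]
    center = coords[heavy].mean(axis=0)

    anchors_t, anchors_x = [], []   # template / target positions
    pinned: dict[str, np.ndarray] = {}

    for group, (resi, acc_name) in zip(spec.basic_groups, _BASIC_TARGETS):
        donor = group[0]
        acc = coords[pep_topo.atom_index(resi, acc_name)]
        u = acc - center
        u /= np.linalg.norm(u)
        h_len = rng.uniform(1.7, 2.2)
        n_pos = acc + (h_len + 1.0) * u
        h_pos = acc + h_len * u
        pinned[donor] = n_pos
        pinned[spec.donor_hydrogens[donor][0]] = h_pos
        anchors_t.append(template[donor])
        anchors_x.append(n_pos)

    for group, (resi, h_name, n_name) in zip(spec.acidic_groups,
                                             _ACIDIC_TARGETS):
        acceptor = group[0]
        hp = coords[pep_topo.atom_index(resi, h_name)]
        npos = coords[pep_topo.atom_index(resi, n_name)]
        v = hp - npos
        v /= np.linalg.norm(v)
        o_pos = hp + rng.uniform(1.7, 2.2) * v
        pinned[acceptor] = o_pos
        anchors_t.append(template[acceptor])
        anchors_x.append(o_pos)

    if spec.nonpolar_atoms:
        t_centroid = np.mean([template[n] for n in spec.nonpolar_atoms],
                             axis=0)
        target_res = spec.nonpolar_target_residue or 18
        cog = sidechain_center_of_geometry(pep_frame, pep_topo, target_res)
        w = cog - center
        w /= np.linalg.norm(w)
        anchors_t.append(t_centroid)
        anchors_x.append(cog + 4.5 * w)

    rot, tr = _kabsch(np.array(anchors_t), np.array(anchors_x))
    order = _ligand_atom_order(spec)
    placed = np.array([template[n] @ rot.T + tr for n in order])
    jitter = rng.normal(0.0, 0.15, size=placed.shape)
    placed = placed + jitter
    for k, n in enumerate(order):
        if n in pinned:
            placed[k] = pinned[n]
    return placed


def _place_ligand_unbound(spec: LigandSpec, template: dict[str, np.ndarray],
                          pep_frame: Frame, pep_topo: Topology,
                          rng: np.random.Generator) -> np.ndarray:
    coords = pep_frame.coords
    center = coords.mean(axis=0)
    d = rng.normal(size=3)
    d /= np.linalg.norm(d)
    span = np.max(np.linalg.norm(coords - center, axis=1))
    offset = center + (span + 25.0) * d
    order = _ligand_atom_order(spec)
    t_center = np.mean([template[n] for n in spec.heavy_atoms], axis=0)
    return np.array([template[n] - t_center + offset for n in order])


# ---------------------------------------------------------------------------
# main generator

def simulate(params: SyntheticParams) -> tuple[Trajectory, GroundTruth]:
    """Generate one trajectory plus its hidden ground truth.

    Reproducible: identical params (including seed) give bitwise-identical
    coordinates.  Frame 0 is the noise-free ideal helix (the stand-in for
    the initial energy-minimized structure) with the ligand bound when a
    binding channel exists.
    """
    rng = np.random.default_rng(params.seed)
    spec = params.resolved_spec()
    n_res = len(params.sequence)
    nf = params.n_frames
    dt_ns = params.stride_ps / 1000.0

    # hidden ligand chain
    bound = np.zeros(nf, dtype=bool)
    if spec is not None:
        bound[0] = params.k_on > 0
        p_unbind = _switch_prob(params.k_off, params.k_on, dt_ns)
        p_bind = _switch_prob(params.k_on, params.k_off, dt_ns)
        u = rng.random(nf - 1) if nf > 1 else np.empty(0)
        for k in range(1, nf):
            p = p_unbind if bound[k - 1] else p_bind
            bound[k] = (not bound[k - 1]) if u[k - 1] < p else bound[k - 1]

    # hidden per-residue helix/coil chains (independent residues)
    helix = np.ones((nf, n_res), dtype=bool)
    if nf > 1:
        uu = rng.random((nf - 1, n_res))
        for k in range(1, nf):
            k_u_eff = params.k_u / params.protection_factor \
                if bound[k - 1] else params.k_u
            p_unfold = _switch_prob(k_u_eff, params.k_f, dt_ns)
            p_fold = _switch_prob(params.k_f, k_u_eff, dt_ns)
            prev = helix[k - 1]
            switch = np.where(prev, uu[k - 1] < p_unfold,
                              uu[k - 1] < p_fold)
            helix[k] = np.where(switch, ~prev, prev)

    # coordinates
    template = _ligand_template(spec) if spec is not None else None
    frames: list[Frame] = []
    base_topo: Topology | None = None
    for k in range(nf):
        if k == 0:
            phi = np.full(n_res, HELIX_PHI_PSI[0])
            psi = np.full(n_res, HELIX_PHI_PSI[1])
        else:
            phi = np.where(helix[k], HELIX_PHI_PSI[0], COIL_PHI_PSI[0])
            psi = np.where(helix[k], HELIX_PHI_PSI[1], COIL_PHI_PSI[1])
            noise = rng.normal(0.0, params.dihedral_noise_deg, (2, n_res))
            phi = phi + noise[0]
            psi = psi + noise[1]
        pep_topo, pep_frame = build_peptide(params.sequence,
                                            params.first_index, phi, psi)
        t = k * params.stride_ps
        if spec is None:
            frames.append(Frame(t, pep_frame.coords))
            base_topo = pep_topo
            continue
        if bound[k]:
            lig = _place_ligand_bound(spec, template, pep_frame, pep_topo,
                                      rng)
        else:
            lig = _place_ligand_unbound(spec, template, pep_frame, pep_topo,
                                        rng)
        frames.append(Frame(t, np.vstack([pep_frame.coords, lig])))
        if base_topo is None:
            full_topo, _ = attach_ligand(
                pep_topo, pep_frame, spec,
                np.zeros((len(spec.heavy_atoms), 3)))
            base_topo = full_topo

    traj = Trajectory(base_topo, frames, params.stride_ps, 0.0)
    truth = GroundTruth(
        expected_occupancy=(stationary_occupancy(params.k_on, params.k_off)
                            if spec is not None else 0.0),
        expected_helicity=expected_helicity(params),
        helix_states=helix,
        bound_states=bound,
    )
    return traj, truth
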