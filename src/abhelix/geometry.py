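"""Superposition, RMSD, radius of gyration, and COG primitives.

Conventions mirror the analysis protocol used throughout the package:
rotation/translation are removed by least-squares (Kabsch) superposition
on all heavy atoms of the peptide (residues 13-26, caps excluded), and
the RMSD is then measured over backbone heavy atoms (N, CA, C, O) of the
middle region 15-24 without re-fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from abhelix.model_io import (
    ATOMIC_MASSES,
    AtomRecord,
    Frame,
    Topology,
)

__all__ = [
    "Selection",
    "RigidTransform",
    "superpose",
    "rmsd",
    "radius_of_gyration",
    "sidechain_center_of_geometry",
    "fit_selection_default",
    "measure_selection_default",
    "rg_selection_default",
]

_BACKBONE_HEAVY = ("N", "CA", "C", "O")


@dataclass(frozen=True)
class Selection:
    """Deterministic atom subset of a Topology.

    A predicate over :class:`AtomRecord`; resolves to an ordered index
    list (topology order) for any given topology.
    """

    predicate: Callable[[AtomRecord], bool]
    label: str = "selection"

    def indices(self, topology: Topology) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(topology.atoms) if self.predicate(a)],
            dtype=int,
        )

    @staticmethod
    def from_spec(segment: str | None = None,
                  residue_range: tuple[int, int] | None = None,
                  backbone_only: bool = False,
                  heavy_only: bool = False,
                  atom_names: tuple[str, ...] | None = None,
                  exclude_caps: bool = True,
                  label: str = "selection") -> "Selection":
        def pred(a: AtomRecord) -> bool:
            if segment is not None and a.segment != segment:
                return False
            if exclude_caps and a.residue_name in ("ACE", "NH2"):
                return False
            if residue_range is not None and not (
                residue_range[0] <= a.residue_index <= residue_range[1]
            ):
                return False
            if backbone_only and not a.is_backbone:
                return False
            if heavy_only and not a.is_heavy:
                return False
            if atom_names is not None and a.atom_name not in atom_names:
                return False
            return True

        return Selection(pred, label)


def fit_selection_default() -> Selection:
    """All heavy atoms of the peptide (residues 13-26, caps excluded)."""
    return Selection.from_spec(segment="peptide", heavy_only=True,
                               label="peptide-heavy")


def measure_selection_default(region: tuple[int, int] = (15, 24)) -> Selection:
    """Backbone heavy atoms (N, CA, C, O) of the middle region."""
    return Selection.from_spec(segment="peptide", residue_range=region,
                               atom_names=_BACKBONE_HEAVY,
                               label=f"backbone-{region[0]}-{region[1]}")


def rg_selection_default(region: tuple[int, int] = (15, 24)) -> Selection:
    """All atoms of the middle region (hydrogens included)."""
    return Selection.from_spec(segment="peptide", residue_range=region,
                               label=f"all-{region[0]}-{region[1]}")


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (Angstrom)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if r.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if abs(np.linalg.det(r) - 1.0) > 1e-8:
            raise ValueError("rotation must be proper (det = +1)")
        if not np.allclose(r.T @ r, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T,
                              -self.rotation.T @ self.translation)


def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError(
            f"superposition needs >= 3 atoms, got {coords.shape[0]}"
        )
    centered = coords - coords.mean(axis=0)
    # collinear (or coincident) point sets have rank < 2
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) fit selection")


def superpose(mobile: Frame, reference: Frame, topology: Topology,
              fit_selection: Selection | None = None,
              ) -> tuple[RigidTransform, Frame]:
    """Least-squares (Kabsch) superposition of mobile onto reference.

    The transform minimizes the sum of squared deviations over the fit
    selection; the returned frame is the transform applied to *all*
    mobile atoms.
    """
    if fit_selection is None:
        fit_selection = fit_selection_default()
    idx = fit_selection.indices(topology)
    if len(idx) == 0:
        raise ValueError("empty fit selection")
    mob = mobile.coords[idx]
    ref = reference.coords[idx]
    if mob.shape != ref.shape:
        raise ValueError("selection resolves to different sizes")
    _check_fit_atoms(mob)
    _check_fit_atoms(ref)
    mc, rc = mob.mean(axis=0), ref.mean(axis=0)
    h = (mob - mc).T @ (ref - rc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, rc - rot @ mc)
    fitted = Frame(mobile.time_ps, transform.apply(mobile.coords))
    return transform, fitted


def rmsd(frame: Frame, reference: Frame, topology: Topology,
         measure_selection: Selection | None = None) -> float:
    """Root-mean-square deviation over a selection (no re-fitting)."""
    if measure_selection is None:
        measure_selection = measure_selection_default()
    idx = measure_selection.indices(topology)
    if len(idx) == 0:
        raise ValueError("empty measure selection")
    diff = frame.coords[idx] - reference.coords[idx]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def radius_of_gyration(frame: Frame, topology: Topology,
                       selection: Selection | None = None,
                       mass_weighted: bool = True) -> float:
    """Radius of gyration sqrt(sum w|r - rbar|^2 / sum w) in Angstrom."""
    if selection is None:
        selection = rg_selection_default()
    idx = selection.indices(topology)
    if len(idx) == 0:
        raise ValueError("empty selection")
    xyz = frame.coords[idx]
    if mass_weighted:
        w = np.array([ATOMIC_MASSES[topology.atoms[i].element] for i in idx])
    else:
        w = np.ones(len(idx))
    center = (w[:, None] * xyz).sum(axis=0) / w.sum()
    sq = np.sum((xyz - center) ** 2, axis=1)
    return float(np.sqrt((w * sq).sum() / w.sum()))


def sidechain_center_of_geometry(frame: Frame, topology: Topology,
                                 residue_index: int) -> np.ndarray:
    """Unweighted mean of sidechain heavy atoms (CA fallback for glycine)."""
    idx = [
        i for i, a in enumerate(topology.atoms)
        if a.segment == "peptide" and a.residue_index == residue_index
        and a.is_heavy and not a.is_backbone
    ]
    if not idx:
        return frame.coords[topology.atom_index(residue_index, "CA")].copy()
    return frame.coords[idx].mean(axis=0)
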