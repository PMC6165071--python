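"""Ensemble stability and flexibility observables.

RMSD, radius of gyration, solvent-accessible surface area (Shrake-Rupley,
via biotite), per-residue RMSF and the derived crystallographic B-factor
B = (8 pi^2 / 3) RMSF^2.  All deviation-based observables assume (or
perform) a least-squares rigid superposition first; the Kabsch rotation is
proper (reflections are never applied).

Summary statistics (mean +/- sd) are reported over the series after
discarding an initial burn-in fraction (default 5%), mirroring the common
practice of excluding the pre-equilibration part of a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc
from scipy.spatial.transform import Rotation

from .structure import Ensemble

__all__ = [
    "ObservableSeries",
    "PerResidueProfile",
    "VDW_RADII",
    "ATOMIC_MASSES",
    "superpose",
    "superpose_to_mean",
    "average_structure",
    "rmsd_series",
    "rg_series",
    "sasa_frame",
    "sasa_series",
    "rmsf_profile",
    "bfactor_profile",
]

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2}
ATOMIC_MASSES = {"C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06, "H": 1.008}
DEFAULT_BURN_IN = 0.05


@dataclass
class ObservableSeries:
    """Per-frame scalar observable with burn-in-aware summary stats."""

    name: str
    values: np.ndarray
    burn_in: float = DEFAULT_BURN_IN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("observable values must be finite")

    def _tail(self) -> np.ndarray:
        start = int(np.floor(self.burn_in * len(self.values)))
        return self.values[start:]

    @property
    def mean(self) -> float:
        return float(np.mean(self._tail()))

    @property
    def sd(self) -> float:
        tail = self._tail()
        return float(np.std(tail, ddof=1)) if len(tail) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.values)), "value": self.values}
        )


@dataclass
class PerResidueProfile:
    """Per-residue scalar profile (RMSF in A or B-factor in A^2)."""

    name: str
    resids: np.ndarray
    values: np.ndarray
    basis: str = "CA"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"resid": self.resids, "value": self.values})


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------

def _check_fit_atoms(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 fit atoms")
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("fit atoms are collinear")


def superpose(
    ens: Ensemble,
    reference_frame: int = 0,
    fit_selection: np.ndarray | list | None = None,
) -> Ensemble:
    """Least-squares fit of every frame onto a reference frame.

    Each frame is rigidly rotated and translated to minimise the RMSD of
    the fit selection to the reference frame; the rotation is constrained
    to be proper (no reflection).  Default fit selection: all atoms.
    """
    sel = (
        np.arange(ens.n_atoms)
        if fit_selection is None
        else np.asarray(fit_selection, dtype=int)
    )
    if sel.size == 0:
        raise ValueError("fit selection is empty")
    ref = ens.coords[reference_frame, sel]
    _check_fit_atoms(ref)
    return _fit_to(ens, ref, sel)


def _fit_to(ens: Ensemble, ref: np.ndarray, sel: np.ndarray) -> Ensemble:
    ref_center = ref.mean(axis=0)
    ref_c = ref - ref_center
    out = np.empty_like(ens.coords)
    for f in range(ens.n_frames):
        mob = ens.coords[f, sel]
        mob_center = mob.mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_c, mob - mob_center)
        out[f] = rot.apply(ens.coords[f] - mob_center) + ref_center
    return Ensemble(ens.topology, out, ens.frame_times)


def superpose_to_mean(
    ens: Ensemble, fit_selection: np.ndarray | list | None = None
) -> Ensemble:
    """Fit to frame 0, then one refinement pass onto the mean structure."""
    sel = (
        np.arange(ens.n_atoms)
        if fit_selection is None
        else np.asarray(fit_selection, dtype=int)
    )
    first = superpose(ens, 0, sel)
    mean_ref = first.coords[:, sel].mean(axis=0)
    _check_fit_atoms(mean_ref)
    return _fit_to(first, mean_ref, sel)


def average_structure(ens: Ensemble) -> Ensemble:
    """Single-frame ensemble holding the per-atom time-mean coordinates."""
    return Ensemble(ens.topology, ens.coords.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# scalar series
# ---------------------------------------------------------------------------

def rmsd_series(
    ens: Ensemble,
    reference_frame: int = 0,
    selection: np.ndarray | list | None = None,
    fit: bool = True,
    burn_in: float = DEFAULT_BURN_IN,
) -> ObservableSeries:
    """Per-frame RMSD (A) over the selection, after optional superposition."""
    sel = (
        np.arange(ens.n_atoms)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    if sel.size == 0:
        raise ValueError("selection is empty")
    work = superpose(ens, reference_frame, sel) if fit else ens
    diff = work.coords[:, sel] - work.coords[reference_frame, sel]
    vals = np.sqrt(np.mean(np.sum(diff**2, axis=2), axis=1))
    return ObservableSeries("RMSD", vals, burn_in)


def rg_series(
    ens: Ensemble,
    selection: np.ndarray | list | None = None,
    masses: np.ndarray | None = None,
    burn_in: float = DEFAULT_BURN_IN,
) -> ObservableSeries:
    """Mass-weighted radius of gyration (A) per frame."""
    sel = (
        np.arange(ens.n_atoms)
        if selection is None
        else np.asarray(selection, dtype=int)
    )
    if masses is None:
        masses = np.array(
            [
                ATOMIC_MASSES.get(ens.topology.atoms[i].element, 12.011)
                for i in sel
            ]
        )
    else:
        masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise ValueError("masses must be positive")
    total = masses.sum()
    if total == 0:
        raise ValueError("zero total mass")
    xyz = ens.coords[:, sel]
    com = np.einsum("fai,a->fi", xyz, masses) / total
    sq = np.sum((xyz - com[:, None, :]) ** 2, axis=2)
    vals = np.sqrt(np.einsum("fa,a->f", sq, masses) / total)
    return ObservableSeries("Rg", vals, burn_in)


def _frame_radii(ens: Ensemble, radii: dict | None) -> np.ndarray:
    table = VDW_RADII if radii is None else radii
    out = np.empty(ens.n_atoms)
    for i, a in enumerate(ens.topology.atoms):
        if a.element not in table:
            raise KeyError(
                f"no van der Waals radius for element {a.element!r}"
            )
        out[i] = table[a.element]
    return out


def sasa_frame(
    ens: Ensemble,
    frame: int = 0,
    radii: dict | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake-Rupley SASA (A^2) of one frame: per-atom array and total."""
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    top = ens.topology
    arr = struc.AtomArray(ens.n_atoms)
    arr.coord = np.asarray(ens.coords[frame], dtype=np.float32)
    arr.chain_id = np.array([a.chain for a in top.atoms], dtype="U4")
    arr.res_id = np.array([a.resid for a in top.atoms], dtype=int)
    arr.res_name = np.array([a.resname for a in top.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in top.atoms], dtype="U6")
    arr.element = np.array([a.element for a in top.atoms], dtype="U2")
    per_atom = struc.sasa(
        arr,
        probe_radius=probe,
        point_number=n_points,
        vdw_radii=_frame_radii(ens, radii),
        ignore_ions=False,
    )
    per_atom = np.nan_to_num(per_atom)
    return per_atom, float(per_atom.sum())


def sasa_series(
    ens: Ensemble,
    radii: dict | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    burn_in: float = DEFAULT_BURN_IN,
) -> ObservableSeries:
    """Total SASA (A^2) per frame."""
    vals = np.array(
        [
            sasa_frame(ens, f, radii, probe, n_points)[1]
            for f in range(ens.n_frames)
        ]
    )
    return ObservableSeries("SASA", vals, burn_in)


# ---------------------------------------------------------------------------
# per-residue profiles
# ---------------------------------------------------------------------------

def rmsf_profile(ens: Ensemble, basis: str = "CA") -> PerResidueProfile:
    """Per-residue RMSF (A) of the basis atom about its time-mean position.

    The ensemble is assumed superposed.  Residues lacking the basis atom
    (e.g. ligands when basis is CA) are omitted from the profile.
    """
    if ens.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = ens.topology
    resids, values = [], []
    for k, (chain, resid, _resname) in enumerate(top.residues):
        idx = [
            i for i in top.atoms_of_residue(k) if top.atoms[i].name == basis
        ]
        if not idx:
            continue
        xyz = ens.coords[:, idx[0]]
        dev = xyz - xyz.mean(axis=0)
        values.append(np.sqrt(np.mean(np.sum(dev**2, axis=1))))
        resids.append(resid)
    return PerResidueProfile(
        "RMSF", np.array(resids), np.array(values), basis
    )


def bfactor_profile(rmsf: PerResidueProfile) -> PerResidueProfile:
    """Crystallographic B-factor: B_i = (8 pi^2 / 3) RMSF_i^2 (A^2)."""
    values = (8.0 * np.pi**2 / 3.0) * rmsf.values**2
    return PerResidueProfile("B-factor", rmsf.resids, values, rmsf.basis)
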