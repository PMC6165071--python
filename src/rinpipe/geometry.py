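"""Catalytic-site geometry tracks and occupancy statistics.

Per-frame scalar series (distances, interior angles, signed dihedrals),
hydrogen-bond occupancy under geometric criteria, a nucleophilic-attack
angle window, and a lightweight phi/psi secondary-structure classifier
("ss-lite") sufficient to score helix-to-turn switches in a cap segment.

The classifier is a deliberate approximation of DSSP: a residue is helical
in a frame iff its (phi, psi) lies within +/-35 deg of the canonical
alpha-helix (-57, -47) and it belongs to a run of at least 4 consecutive
such residues; strand analogously around (-120, +130) with +/-45 deg and
run length 2; everything else (including chain termini, where phi or psi
is undefined) is "other".  "Turn-lite" means simply "not helix".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Ensemble

__all__ = [
    "GeometrySeries",
    "HbondTable",
    "SSTrack",
    "vec_angle",
    "vec_dihedral",
    "distance_series",
    "angle_series",
    "dihedral_series",
    "phi_psi",
    "window_occupancy",
    "hbond_occupancy",
    "assign_ss_lite",
    "turn_occupancy",
]

HELIX_PHI_PSI = (-57.0, -47.0)
HELIX_TOL = 35.0
HELIX_MIN_RUN = 4
STRAND_PHI_PSI = (-120.0, 130.0)
STRAND_TOL = 45.0
STRAND_MIN_RUN = 2


# ---------------------------------------------------------------------------
# vector primitives (frames x 3 arrays)
# ---------------------------------------------------------------------------

def vec_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Interior angle at vertex ``b`` in degrees, per frame."""
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    if np.any(nu == 0) or np.any(nv == 0):
        raise ValueError("coincident atoms give a zero-length vector")
    cosang = np.einsum("...i,...i", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def vec_dihedral(
    p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray
) -> np.ndarray:
    """Signed dihedral p0-p1-p2-p3 in degrees, IUPAC convention (cis = 0)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.einsum("...i,...i", n1, n2)
    y = np.einsum("...i,...i", m, n2)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so dihedrals live in (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class GeometrySeries:
    """Per-frame scalar geometry track."""

    kind: str  # "distance" (A) | "angle" (deg) | "dihedral" (deg)
    atoms: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind == "angle" and (
            np.any(self.values < 0) or np.any(self.values > 180)
        ):
            raise ValueError("interior angles must lie in [0, 180] deg")

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self.values)), "value": self.values}
        )


@dataclass
class HbondTable:
    """Donor/acceptor occupancy table, sorted by occupancy descending."""

    rows: pd.DataFrame  # columns: donor, acceptor, occupancy
    distance_cutoff: float
    angle_cutoff: float


@dataclass
class SSTrack:
    """Per-frame, per-residue class in {helix, strand, other}."""

    classes: np.ndarray  # (n_frames, n_residues) of {"H", "E", "-"}
    resids: np.ndarray

    @property
    def turn_lite(self) -> np.ndarray:
        """Boolean (frame, residue) mask: anything that is not helix."""
        return self.classes != "H"


# ---------------------------------------------------------------------------
# per-frame tracks
# ---------------------------------------------------------------------------

def _resolve(ens: Ensemble, atom) -> int:
    """Atom reference: integer index or (resid, name[, chain]) tuple."""
    if isinstance(atom, (int, np.integer)):
        if not 0 <= atom < ens.n_atoms:
            raise KeyError(f"atom index {atom} out of range")
        return int(atom)
    return ens.topology.index_of(*atom)


def distance_series(ens: Ensemble, atom_a, atom_b) -> GeometrySeries:
    ia, ib = _resolve(ens, atom_a), _resolve(ens, atom_b)
    d = np.linalg.norm(ens.coords[:, ia] - ens.coords[:, ib], axis=1)
    return GeometrySeries("distance", (atom_a, atom_b), d)


def angle_series(ens: Ensemble, a, b, c) -> GeometrySeries:
    ia, ib, ic = (_resolve(ens, x) for x in (a, b, c))
    vals = vec_angle(ens.coords[:, ia], ens.coords[:, ib], ens.coords[:, ic])
    return GeometrySeries("angle", (a, b, c), vals)


def dihedral_series(ens: Ensemble, a, b, c, d) -> GeometrySeries:
    ia, ib, ic, id_ = (_resolve(ens, x) for x in (a, b, c, d))
    vals = vec_dihedral(
        ens.coords[:, ia], ens.coords[:, ib], ens.coords[:, ic], ens.coords[:, id_]
    )
    return GeometrySeries("dihedral", (a, b, c, d), vals)


def phi_psi(
    ens: Ensemble, resid: int, chain: str | None = None
) -> tuple[GeometrySeries, GeometrySeries]:
    """Backbone phi/psi series of one residue.

    phi = C(i-1)-N(i)-CA(i)-C(i);  psi = N(i)-CA(i)-C(i)-N(i+1).
    Raises for chain-terminal residues (no i-1 or i+1 backbone).
    """
    top = ens.topology
    try:
        c_prev = top.index_of(resid - 1, "C", chain)
        n_next = top.index_of(resid + 1, "N", chain)
    except KeyError as exc:
        raise KeyError(
            f"residue {resid} is chain-terminal or neighbors lack backbone"
        ) from exc
    n = top.index_of(resid, "N", chain)
    ca = top.index_of(resid, "CA", chain)
    c = top.index_of(resid, "C", chain)
    phi = dihedral_series(ens, c_prev, n, ca, c)
    psi = dihedral_series(ens, n, ca, c, n_next)
    return phi, psi


# ---------------------------------------------------------------------------
# occupancies
# ---------------------------------------------------------------------------

def window_occupancy(
    series: GeometrySeries, center: float = 110.0, halfwidth: float = 20.0
) -> float:
    """Percentage of frames with |value - center| <= halfwidth (closed)."""
    if len(series.values) == 0:
        raise ValueError("empty series")
    inside = np.abs(series.values - center) <= halfwidth
    return 100.0 * float(np.mean(inside))


def hbond_occupancy(
    ens: Ensemble,
    donors: list,
    acceptors: list,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 30.0,
    allow_any_acceptor: bool = False,
) -> HbondTable:
    """Hydrogen-bond occupancy (%) for every donor/acceptor pair.

    A bond is present in a frame iff donor-acceptor distance <=
    ``distance_cutoff`` and, when a hydrogen bonded to the donor is
    present in the topology, the H-donor-acceptor angle is <=
    ``angle_cutoff``.  Without hydrogens the criterion falls back to the
    distance alone (crystal-structure-derived ensembles).  Acceptors are
    restricted to N/O elements unless ``allow_any_acceptor``.
    """
    if not donors or not acceptors:
        raise ValueError("donor and acceptor lists must be non-empty")
    top = ens.topology
    rows = []
    for d_ref in donors:
        i_d = _resolve(ens, d_ref)
        d_atom = top.atoms[i_d]
        # a hydrogen covalently bonded to the donor: same residue, element H,
        # within 1.25 A of the donor in the first frame
        h_idx = None
        for j in top.atoms_of_residue(int(top.residue_index[i_d])):
            a = top.atoms[j]
            if a.element == "H" and (
                np.linalg.norm(ens.coords[0, j] - ens.coords[0, i_d]) < 1.25
            ):
                h_idx = int(j)
                break
        for a_ref in acceptors:
            i_a = _resolve(ens, a_ref)
            if i_a == i_d:
                continue
            a_atom = top.atoms[i_a]
            if not allow_any_acceptor and a_atom.element not in ("N", "O"):
                continue
            dist = np.linalg.norm(
                ens.coords[:, i_d] - ens.coords[:, i_a], axis=1
            )
            present = dist <= distance_cutoff
            if h_idx is not None:
                ang = vec_angle(
                    ens.coords[:, h_idx], ens.coords[:, i_d], ens.coords[:, i_a]
                )
                present &= ang <= angle_cutoff
            occ = 100.0 * float(np.mean(present))
            rows.append(
                {
                    "donor": f"{d_atom.resname}{d_atom.resid}:{d_atom.name}",
                    "acceptor": f"{a_atom.resname}{a_atom.resid}:{a_atom.name}",
                    "occupancy": occ,
                }
            )
    table = pd.DataFrame(rows, columns=["donor", "acceptor", "occupancy"])
    table = table.sort_values(
        "occupancy", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return HbondTable(table, distance_cutoff, angle_cutoff)


# ---------------------------------------------------------------------------
# ss-lite classifier
# ---------------------------------------------------------------------------

def _near(value: np.ndarray, target: float, tol: float) -> np.ndarray:
    """Angular proximity with wrap-around at +/-180 deg."""
    d = np.abs(value - target) % 360.0
    return np.minimum(d, 360.0 - d) <= tol


def _mark_runs(mask: np.ndarray, min_run: int) -> np.ndarray:
    """Keep only True entries inside runs of >= min_run along axis 1."""
    out = np.zeros_like(mask)
    n = mask.shape[1]
    for f in range(mask.shape[0]):
        i = 0
        row = mask[f]
        while i < n:
            if row[i]:
                j = i
                while j < n and row[j]:
                    j += 1
                if j - i >= min_run:
                    out[f, i:j] = True
                i = j
            else:
                i += 1
    return out


def assign_ss_lite(
    ens: Ensemble, resid_range: tuple[int, int] | None = None
) -> SSTrack:
    """Classify each (frame, residue) as helix/strand/other from phi/psi.

    ``resid_range`` limits the *reported* residues; run conditions are
    evaluated over the full chain so segment borders behave correctly.
    """
    top = ens.topology
    resids = np.array([r[1] for r in top.residues])
    n_res = len(resids)
    n_frames = ens.n_frames
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)
    for k in range(n_res):
        try:
            s_phi, s_psi = phi_psi(ens, int(resids[k]), top.residues[k][0])
        except KeyError:
            continue  # terminal residue: stays "other"
        phi[:, k] = s_phi.values
        psi[:, k] = s_psi.values
    with np.errstate(invalid="ignore"):
        helix_pt = _near(phi, HELIX_PHI_PSI[0], HELIX_TOL) & _near(
            psi, HELIX_PHI_PSI[1], HELIX_TOL
        )
        strand_pt = _near(phi, STRAND_PHI_PSI[0], STRAND_TOL) & _near(
            psi, STRAND_PHI_PSI[1], STRAND_TOL
        )
    helix_pt &= np.isfinite(phi) & np.isfinite(psi)
    strand_pt &= np.isfinite(phi) & np.isfinite(psi)
    helix = _mark_runs(helix_pt, HELIX_MIN_RUN)
    strand = _mark_runs(strand_pt, STRAND_MIN_RUN) & ~helix
    classes = np.full((n_frames, n_res), "-", dtype="U1")
    classes[helix] = "H"
    classes[strand] = "E"
    if resid_range is not None:
        lo, hi = resid_range
        keep = (resids >= lo) & (resids <= hi)
        if not keep.any():
            raise ValueError(f"no residues in range {lo}-{hi}")
        classes = classes[:, keep]
        resids = resids[keep]
    return SSTrack(classes, resids)


def turn_occupancy(track: SSTrack, resid_range: tuple[int, int]) -> float:
    """Percent of (frame, residue) cells in the range that are not helix."""
    lo, hi = resid_range
    keep = (track.resids >= lo) & (track.resids <= hi)
    if not keep.any():
        raise ValueError(f"no residues in range {lo}-{hi}")
    return 100.0 * float(np.mean(track.turn_lite[:, keep]))
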