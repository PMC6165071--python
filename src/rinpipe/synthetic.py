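"""Synthetic conformational ensembles with planted, known structure.

Stand-in for long molecular-dynamics trajectories: every analysis stage in
the package has a generator here that plants the signal the stage is meant
to recover — residue-residue correlation blocks for the network stage, a
helix-to-turn two-state switch in a cap segment for the secondary-structure
stage, donor-acceptor hydrogen-bond occupancies, catalytic-triad
distance/angle distributions, and a dominant collective mode for PCA.

Backbone chains are built from ideal internal coordinates (N-CA 1.458 A,
CA-C 1.525 A, C-N 1.329 A, omega = 180 deg) by sequential
internal-to-Cartesian (NeRF) construction, so the phi/psi dihedrals
measured on the output equal the requested values exactly.  Displacements
are applied rigidly per residue: residue-level correlations are then exact
by construction, matching how the downstream analyses operate (C-alpha
basis).  All generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structure import Atom, Ensemble, Topology

__all__ = [
    "ChainSpec",
    "CovarianceSpec",
    "TwoStateSpec",
    "HbondPlant",
    "DistancePlant",
    "AnglePlant",
    "PlantSpec",
    "HELIX",
    "TURN",
    "build_ideal_chain",
    "sample_gaussian_ensemble",
    "add_correlated_noise",
    "plant_two_state_segment",
    "plant_hbonds",
    "plant_triad_geometry",
    "plant_collective_mode",
    "add_atom",
    "add_ligand",
    "translate_residues",
    "build_hub_system",
]

# ideal backbone internal coordinates (Engh-Huber-like)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELIX = (-57.0, -47.0)
TURN = (-75.0, 150.0)  # turn-like state of the two-state cap switch


@dataclass
class ChainSpec:
    """Backbone chain defined by per-residue (phi, psi) in degrees."""

    n_residues: int
    phi_psi: np.ndarray | None = None  # (n, 2); default: alpha helix
    resnames: dict[int, str] = field(default_factory=dict)  # resid -> name
    chain: str = "A"
    start_resid: int = 1

    def __post_init__(self) -> None:
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.phi_psi is None:
            self.phi_psi = np.tile(HELIX, (self.n_residues, 1)).astype(float)
        self.phi_psi = np.asarray(self.phi_psi, dtype=float)
        if self.phi_psi.shape != (self.n_residues, 2):
            raise ValueError("phi_psi must have shape (n_residues, 2)")
        if np.any(self.phi_psi <= -180.0) or np.any(self.phi_psi > 180.0):
            raise ValueError("dihedrals must lie in (-180, 180] deg")

    def with_segment(
        self, first_resid: int, last_resid: int, phi_psi: tuple[float, float]
    ) -> "ChainSpec":
        lo = first_resid - self.start_resid
        hi = last_resid - self.start_resid
        if lo < 0 or hi >= self.n_residues or lo > hi:
            raise ValueError(
                f"segment {first_resid}-{last_resid} outside chain"
            )
        pp = self.phi_psi.copy()
        pp[lo : hi + 1] = phi_psi
        return ChainSpec(
            self.n_residues, pp, dict(self.resnames), self.chain, self.start_resid
        )


@dataclass
class CovarianceSpec:
    """Residue-level displacement covariance: isotropic scale + blocks.

    ``blocks``: (residue-index set, rho) gives every within-set pair the
    correlation rho.  ``cross_block``: (set A, set B, rho, sign) correlates
    pairs across the two sets with sign * rho (sign -1 plants
    anti-correlated motion).  Indices are 0-based positions in the
    topology's residue list.
    """

    base_sigma: float = 0.5
    blocks: list[tuple[list[int], float]] = field(default_factory=list)
    cross_block: list[tuple[list[int], list[int], float, int]] = field(
        default_factory=list
    )

    def correlation_matrix(self, n_residues: int) -> np.ndarray:
        r = np.eye(n_residues)
        for idx, rho in self.blocks:
            if abs(rho) > 1:
                raise ValueError("|rho| must be <= 1")
            idx = np.asarray(idx, dtype=int)
            r[np.ix_(idx, idx)] = rho
            r[idx, idx] = 1.0
        for ia, ib, rho, sign in self.cross_block:
            if abs(rho) > 1:
                raise ValueError("|rho| must be <= 1")
            ia = np.asarray(ia, dtype=int)
            ib = np.asarray(ib, dtype=int)
            r[np.ix_(ia, ib)] = sign * rho
            r[np.ix_(ib, ia)] = sign * rho
        return r


@dataclass
class TwoStateSpec:
    """Hard two-state switch of a chain segment (helix -> turn-like)."""

    segment: tuple[int, int]  # (first_resid, last_resid), inclusive
    state_a: tuple[float, float] = HELIX
    state_b: tuple[float, float] = TURN
    switch_frame: int = 0


@dataclass
class HbondPlant:
    donor: tuple  # (resid, name[, chain]) atom reference
    acceptor: tuple
    occupancy: float  # target fraction in [0, 1]
    bound_distance: float = 2.9
    unbound_distance: float = 4.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must lie in [0, 1]")


@dataclass
class DistancePlant:
    atom_a: tuple
    atom_b: tuple  # repositioned along the a->b direction
    mean: float
    sd: float = 0.0


@dataclass
class AnglePlant:
    atom_a: tuple  # repositioned around the vertex
    vertex: tuple
    atom_c: tuple
    mean: float  # degrees
    sd: float = 0.0


@dataclass
class PlantSpec:
    hbonds: list[HbondPlant] = field(default_factory=list)
    distances: list[DistancePlant] = field(default_factory=list)
    angles: list[AnglePlant] = field(default_factory=list)


# ---------------------------------------------------------------------------
# internal-to-Cartesian construction
# ---------------------------------------------------------------------------

def _place(a, b, c, bond: float, angle_deg: float, torsion_deg: float):
    """Position atom d from reference atoms a-b-c (NeRF)."""
    ang = np.radians(angle_deg)
    # negated so the measured IUPAC dihedral a-b-c-d equals torsion_deg
    tor = -np.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_chain(spec: ChainSpec) -> Ensemble:
    """Single-frame backbone (N, CA, C, O per residue) from phi/psi.

    The carbonyl O lies in the peptide plane opposite the next residue's N
    (torsion psi + 180 about CA-C); the terminal residue's O uses its
    nominal psi the same way, so every residue carries four atoms.
    """
    n = spec.n_residues
    phi = spec.phi_psi[:, 0]
    psi = spec.phi_psi[:, 1]
    pos_n = np.zeros((n, 3))
    pos_ca = np.zeros((n, 3))
    pos_c = np.zeros((n, 3))
    pos_o = np.zeros((n, 3))

    pos_n[0] = (0.0, 0.0, 0.0)
    pos_ca[0] = (BOND_N_CA, 0.0, 0.0)
    a = np.radians(ANGLE_N_CA_C)
    pos_c[0] = pos_ca[0] + BOND_CA_C * np.array([-np.cos(a), np.sin(a), 0.0])
    for i in range(1, n):
        pos_n[i] = _place(
            pos_n[i - 1], pos_ca[i - 1], pos_c[i - 1],
            BOND_C_N, ANGLE_CA_C_N, psi[i - 1],
        )
        pos_ca[i] = _place(
            pos_ca[i - 1], pos_c[i - 1], pos_n[i],
            BOND_N_CA, ANGLE_C_N_CA, OMEGA,
        )
        pos_c[i] = _place(
            pos_c[i - 1], pos_n[i], pos_ca[i],
            BOND_CA_C, ANGLE_N_CA_C, phi[i],
        )
    for i in range(n):
        tor = psi[i] + 180.0
        if tor > 180.0:
            tor -= 360.0
        pos_o[i] = _place(pos_n[i], pos_ca[i], pos_c[i], BOND_C_O, ANGLE_CA_C_O, tor)

    atoms: list[Atom] = []
    coords = np.empty((1, 4 * n, 3))
    serial = 1
    for i in range(n):
        resid = spec.start_resid + i
        resname = spec.resnames.get(resid, "ALA")
        for name, elem, pos in (
            ("N", "N", pos_n[i]),
            ("CA", "C", pos_ca[i]),
            ("C", "C", pos_c[i]),
            ("O", "O", pos_o[i]),
        ):
            atoms.append(Atom(serial, name, elem, resname, spec.chain, resid))
            coords[0, serial - 1] = pos
            serial += 1
    return Ensemble(Topology(atoms), coords)


# ---------------------------------------------------------------------------
# ensemble sampling
# ---------------------------------------------------------------------------

def _residue_rigid_apply(
    reference: Ensemble, displacements: np.ndarray
) -> Ensemble:
    """Add per-residue 3-vector displacements (frames, n_res, 3) rigidly."""
    ridx = reference.topology.residue_index
    coords = reference.coords[0][None, :, :] + displacements[:, ridx, :]
    out = reference.copy()
    out.coords = coords
    return Ensemble(reference.topology, coords)


def sample_gaussian_ensemble(
    reference: Ensemble,
    cov: CovarianceSpec,
    n_frames: int,
    seed: int,
) -> Ensemble:
    """Frames = reference + correlated Gaussian residue displacements.

    The x, y and z displacement components are independent; across
    residues each component has covariance base_sigma^2 * R with R the
    correlation matrix built from the spec.  Raises for a non-PSD R,
    reporting the smallest eigenvalue.
    """
    if reference.n_frames != 1:
        raise ValueError("reference must be a single-frame ensemble")
    n_res = reference.n_residues
    r = cov.correlation_matrix(n_res)
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-10:
        raise ValueError(
            f"covariance spec is not positive semi-definite "
            f"(smallest eigenvalue {w.min():.3e})"
        )
    sqrt_r = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((n_frames, n_res, 3))
    disp = cov.base_sigma * np.einsum("rs,fsd->frd", sqrt_r, g)
    return _residue_rigid_apply(reference, disp)


def add_correlated_noise(
    ens: Ensemble, cov: CovarianceSpec, seed: int
) -> Ensemble:
    """Add correlated residue-rigid Gaussian displacements to every frame."""
    r = cov.correlation_matrix(ens.n_residues)
    w, v = np.linalg.eigh(r)
    if w.min() < -1e-10:
        raise ValueError(
            f"covariance spec is not positive semi-definite "
            f"(smallest eigenvalue {w.min():.3e})"
        )
    sqrt_r = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    rng = np.random.default_rng(seed)
    g = rng.standard_normal((ens.n_frames, ens.n_residues, 3))
    disp = cov.base_sigma * np.einsum("rs,fsd->frd", sqrt_r, g)
    return Ensemble(
        ens.topology,
        ens.coords + disp[:, ens.topology.residue_index, :],
        ens.frame_times,
    )


def plant_two_state_segment(
    chain: ChainSpec,
    two_state: TwoStateSpec,
    n_frames: int,
    seed: int,
    jitter_sigma: float = 0.0,
) -> Ensemble:
    """Hard helix->turn switch: frames [0, switch) in state A, rest in B."""
    if not 0 <= two_state.switch_frame <= n_frames:
        raise ValueError("switch_frame must lie in [0, n_frames]")
    spec_a = chain.with_segment(*two_state.segment, two_state.state_a)
    spec_b = chain.with_segment(*two_state.segment, two_state.state_b)
    frame_a = build_ideal_chain(spec_a)
    frame_b = build_ideal_chain(spec_b)
    n_a = two_state.switch_frame
    coords = np.concatenate(
        [
            np.repeat(frame_a.coords, n_a, axis=0),
            np.repeat(frame_b.coords, n_frames - n_a, axis=0),
        ]
    )
    ens = Ensemble(frame_a.topology, coords)
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed)
        disp = jitter_sigma * rng.standard_normal(
            (n_frames, ens.n_residues, 3)
        )
        ens = Ensemble(
            ens.topology, ens.coords + disp[:, ens.topology.residue_index, :]
        )
    return ens


def plant_hbonds(ens: Ensemble, plants: PlantSpec, seed: int) -> Ensemble:
    """Reposition acceptor atoms to realise target H-bond occupancies.

    For each plant, a deterministic pseudorandom subset of
    round(occupancy * n_frames) frames puts the acceptor at the bound
    distance from the donor (along the current donor->acceptor direction);
    all other frames use the unbound distance.  The achieved occupancy
    therefore equals the target to the nearest 1/n_frames.
    """
    out = ens.copy()
    rng = np.random.default_rng(seed)
    top = ens.topology
    for plant in plants.hbonds:
        i_d = top.index_of(*plant.donor)
        i_a = top.index_of(*plant.acceptor)
        n_bound = int(round(plant.occupancy * ens.n_frames))
        bound = np.zeros(ens.n_frames, dtype=bool)
        bound[rng.permutation(ens.n_frames)[:n_bound]] = True
        direction = out.coords[:, i_a] - out.coords[:, i_d]
        norms = np.linalg.norm(direction, axis=1, keepdims=True)
        direction = np.where(norms > 1e-9, direction / norms, [1.0, 0.0, 0.0])
        dist = np.where(bound, plant.bound_distance, plant.unbound_distance)
        out.coords[:, i_a] = out.coords[:, i_d] + direction * dist[:, None]
    return out


def plant_triad_geometry(ens: Ensemble, plants: PlantSpec, seed: int) -> Ensemble:
    """Impose target distance/angle distributions on named atom pairs/triples.

    Distance plants move atom_b along the existing a->b direction to a
    N(mean, sd) sample per frame; angle plants rotate atom_a about the
    vertex, in the plane spanned by the current arms, to a N(mean, sd)
    angle while preserving |vertex - atom_a|.
    """
    out = ens.copy()
    rng = np.random.default_rng(seed)
    top = ens.topology
    for dp in plants.distances:
        ia = top.index_of(*dp.atom_a)
        ib = top.index_of(*dp.atom_b)
        direction = out.coords[:, ib] - out.coords[:, ia]
        norms = np.linalg.norm(direction, axis=1, keepdims=True)
        direction = np.where(norms > 1e-9, direction / norms, [1.0, 0.0, 0.0])
        d = rng.normal(dp.mean, dp.sd, ens.n_frames)
        out.coords[:, ib] = out.coords[:, ia] + direction * d[:, None]
    for ap in plants.angles:
        ia = top.index_of(*ap.atom_a)
        ib = top.index_of(*ap.vertex)
        ic = top.index_of(*ap.atom_c)
        u = out.coords[:, ic] - out.coords[:, ib]
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        arm = out.coords[:, ia] - out.coords[:, ib]
        radius = np.linalg.norm(arm, axis=1, keepdims=True)
        perp = arm - (np.einsum("fi,fi->f", arm, u))[:, None] * u
        pn = np.linalg.norm(perp, axis=1, keepdims=True)
        # degenerate (collinear) arms: pick any direction orthogonal to u
        fallback = np.cross(u, [0.0, 0.0, 1.0])
        bad = np.linalg.norm(fallback, axis=1) < 1e-9
        fallback[bad] = np.cross(u[bad], [0.0, 1.0, 0.0])
        fallback /= np.linalg.norm(fallback, axis=1, keepdims=True)
        perp = np.where(pn > 1e-9, perp / np.where(pn > 0, pn, 1.0), fallback)
        theta = np.radians(rng.normal(ap.mean, ap.sd, ens.n_frames))
        new_dir = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * perp
        out.coords[:, ia] = out.coords[:, ib] + radius * new_dir
    return out


def plant_collective_mode(
    reference: Ensemble,
    mode_weights: np.ndarray,
    sigma_mode: float,
    sigma_noise: float,
    n_frames: int,
    seed: int,
) -> Ensemble:
    """One planted collective mode plus isotropic residue noise.

    ``mode_weights`` is (n_res, 3) (or (n_res,), taken along x): the frame
    displacement is z * W + noise with z ~ N(0, sigma_mode^2) and
    independent N(0, sigma_noise^2) noise per residue coordinate.  The
    share of total residue-coordinate variance carried by the mode is
    sigma_mode^2 * ||W||^2 / (sigma_mode^2 * ||W||^2 + 3 n_res sigma_noise^2).
    """
    if reference.n_frames != 1:
        raise ValueError("reference must be a single-frame ensemble")
    n_res = reference.n_residues
    w = np.asarray(mode_weights, dtype=float)
    if w.ndim == 1:
        w = np.stack([w, np.zeros_like(w), np.zeros_like(w)], axis=1)
    if w.shape != (n_res, 3):
        raise ValueError("mode_weights must have shape (n_res,) or (n_res, 3)")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, sigma_mode, n_frames)
    noise = rng.normal(0.0, sigma_noise, (n_frames, n_res, 3))
    disp = z[:, None, None] * w[None, :, :] + noise
    return _residue_rigid_apply(reference, disp)


def translate_residues(
    ens: Ensemble, moves: dict[int, np.ndarray]
) -> Ensemble:
    """Rigidly translate whole residues (keyed by resid) in every frame."""
    out = ens.copy()
    top = ens.topology
    for resid, delta in moves.items():
        k = next(
            (i for i, r in enumerate(top.residues) if r[1] == resid), None
        )
        if k is None:
            raise KeyError(f"residue {resid} not in topology")
        idx = top.atoms_of_residue(k)
        out.coords[:, idx] += np.asarray(delta, dtype=float)
    return out


def build_hub_system(
    n_residues: int = 40,
    hub_resid: int = 20,
    n_spokes: int = 10,
    spoke_distance: float = 4.0,
    rho: float = 0.65,
    base_sigma: float = 0.3,
    n_frames: int = 2000,
    seed: int = 0,
) -> tuple[Ensemble, int]:
    """Ensemble with one planted high-contact, high-correlation residue.

    An extended chain is folded so that ``n_spokes`` sequence-distant
    residues surround the hub residue on two staggered rings at
    ``spoke_distance`` (C-alpha to C-alpha), giving the hub many
    non-neighbour heavy-atom contacts.  Motions follow a single-factor
    model: each spoke correlates with the hub at ``rho`` and spokes
    correlate mutually at rho^2, so with the conventional correlation
    floor of 0.5 only hub-spoke edges survive into the path graph and
    inter-spoke communication is forced through the hub.  Returns the
    ensemble and the hub's resid.
    """
    spec = ChainSpec(
        n_residues, phi_psi=np.tile([180.0, 180.0], (n_residues, 1))
    )
    ref = build_ideal_chain(spec)
    top = ref.topology
    hub_k = hub_resid - spec.start_resid
    ca_hub = ref.coords[0, top.index_of(hub_resid, "CA")]
    # spokes at sequence separation >= 3 on alternating sides of the hub
    offsets = []
    step = 3
    while len(offsets) < n_spokes:
        offsets += [step, -step]
        step += 2
    spokes = [hub_resid + o for o in offsets[:n_spokes]]
    if min(spokes) < spec.start_resid or max(spokes) >= spec.start_resid + n_residues:
        raise ValueError("spokes fall outside the chain")
    # two staggered rings above/below the hub keep the spokes apart from
    # one another while each stays in heavy-atom contact with the hub;
    # every spoke is rotated to point radially outward so spokes diverge
    # instead of touching each other
    half = max(1, (n_spokes + 1) // 2)
    z_off = 0.45 * spoke_distance
    radius = np.sqrt(max(spoke_distance**2 - z_off**2, 1.0))
    coords = ref.coords.copy()
    for k, sr in enumerate(spokes):
        ring = k % 2
        theta = 2.0 * np.pi * (k // 2 + 0.5 * ring + 0.25) / half
        u = np.array(
            [
                radius * np.cos(theta),
                radius * np.sin(theta),
                z_off * (1 if ring == 0 else -1),
            ]
        )
        u = u / np.linalg.norm(u)
        res_k = sr - spec.start_resid
        idx = top.atoms_of_residue(res_k)
        local = coords[0, idx] - coords[0, top.index_of(sr, "N")]
        # rotate the chain axis (x) onto the outward radial direction
        rot, _ = Rotation.align_vectors([u], [[1.0, 0.0, 0.0]])
        coords[0, idx] = ca_hub + spoke_distance * u + rot.apply(local)
    ref = Ensemble(top, coords)
    spoke_k = [sr - spec.start_resid for sr in spokes]
    cov = CovarianceSpec(
        base_sigma=base_sigma,
        blocks=[(spoke_k, rho**2)],
        cross_block=[([hub_k], spoke_k, rho, 1)],
    )
    ens = sample_gaussian_ensemble(ref, cov, n_frames, seed)
    return ens, hub_resid


# ---------------------------------------------------------------------------
# topology editing helpers
# ---------------------------------------------------------------------------

def add_atom(
    ens: Ensemble,
    resid: int,
    name: str,
    element: str,
    anchor: tuple,
    offset: np.ndarray,
    chain: str | None = None,
) -> Ensemble:
    """Append a pseudo atom to an existing residue, at anchor + offset.

    Used to give synthetic backbones addressable side-chain-like atoms
    (e.g. OG on a serine, NE2 on a histidine) that ride rigidly on the
    anchor atom across all frames.
    """
    top = ens.topology
    i_anchor = top.index_of(*anchor)
    a_anchor = top.atoms[i_anchor]
    if chain is None:
        chain = a_anchor.chain
    resname = next(
        (r[2] for r in top.residues if r[0] == chain and r[1] == resid), None
    )
    if resname is None:
        raise KeyError(f"residue {chain}/{resid} not in topology")
    serial = max(a.serial for a in top.atoms) + 1
    atoms = list(top.atoms) + [Atom(serial, name, element, resname, chain, resid)]
    new_coords = ens.coords[:, i_anchor] + np.asarray(offset, dtype=float)
    coords = np.concatenate([ens.coords, new_coords[:, None, :]], axis=1)
    return Ensemble(Topology(atoms), coords)


def add_ligand(
    ens: Ensemble,
    resname: str,
    resid: int,
    atom_specs: list[tuple[str, str, np.ndarray]],
    chain: str = "A",
) -> Ensemble:
    """Append a small-molecule residue with fixed atom positions."""
    top = ens.topology
    serial = max(a.serial for a in top.atoms) + 1
    atoms = list(top.atoms)
    new = np.empty((ens.n_frames, len(atom_specs), 3))
    for k, (name, element, pos) in enumerate(atom_specs):
        atoms.append(Atom(serial + k, name, element, resname, chain, resid))
        new[:, k] = np.asarray(pos, dtype=float)
    coords = np.concatenate([ens.coords, new], axis=1)
    return Ensemble(Topology(atoms), coords)
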