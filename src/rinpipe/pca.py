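"""Essential dynamics: coordinate-covariance PCA and free-energy landscapes.

PCA diagonalises the 3n x 3n covariance of the (superposed) basis-atom
coordinates about their time mean.  The percentage of total positional
variance carried by each principal component, 100 * lambda_k / sum lambda,
is the standard "PC probability" of essential-dynamics reports.  The
free-energy landscape (FEL) is the negative log of the frame density over
the first two projections, Delta G = -k_B T ln(P / P_max), so the most
populated bin sits at exactly zero and basin depth differences recover
population ratios: Delta Delta G = -ln(p_2 / p_1) in k_B T units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import Ensemble

__all__ = ["PCAResult", "FELGrid", "pca", "residue_contribution", "fel"]

KB_KJ_PER_MOL_K = 0.008314462618


@dataclass
class PCAResult:
    """Eigenvalues (A^2, descending), orthonormal modes and projections."""

    eigenvalues: np.ndarray  # (m,)
    eigenvectors: np.ndarray  # (3*n_basis, m), columns are modes
    projections: np.ndarray  # (n_frames, m)
    resids: np.ndarray  # basis residues, length n_basis

    @property
    def percent(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return 100.0 * self.eigenvalues / total if total > 0 else np.zeros_like(
            self.eigenvalues
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "percent": self.percent,
            }
        )


@dataclass
class FELGrid:
    """2-D free-energy surface over (PC1, PC2) in k_BT (or kJ/mol)."""

    delta_g: np.ndarray  # (n_bins, n_bins); NaN marks empty bins
    x_edges: np.ndarray
    y_edges: np.ndarray
    units: str = "kT"

    def __post_init__(self) -> None:
        occupied = self.delta_g[np.isfinite(self.delta_g)]
        if occupied.size == 0:
            raise ValueError("free-energy grid has no occupied bins")
        if occupied.min() < -1e-12:
            raise ValueError("free energies must be >= 0")


def pca(ens: Ensemble, basis: str = "CA") -> PCAResult:
    """PCA of basis-atom coordinates; the ensemble must be superposed."""
    if ens.n_frames < 3:
        raise ValueError("PCA needs at least 3 frames")
    top = ens.topology
    idx, resids = [], []
    for k, (_chain, resid, _resname) in enumerate(top.residues):
        hits = [
            i for i in top.atoms_of_residue(k) if top.atoms[i].name == basis
        ]
        if hits:
            idx.append(hits[0])
            resids.append(resid)
    x = ens.coords[:, idx].reshape(ens.n_frames, -1)  # (F, 3m)
    x = x - x.mean(axis=0)
    cov = (x.T @ x) / (ens.n_frames - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    v = v[:, order]
    # deterministic sign: largest-magnitude component of each mode positive
    for k in range(v.shape[1]):
        peak = np.argmax(np.abs(v[:, k]))
        if v[peak, k] < 0:
            v[:, k] = -v[:, k]
    proj = x @ v
    return PCAResult(w, v, proj, np.array(resids))


def residue_contribution(result: PCAResult, mode: int = 0) -> pd.DataFrame:
    """Per-residue weight of one mode: the norm of its 3 vector components.

    Squared contributions sum to 1 (eigenvector orthonormality).
    """
    if not 0 <= mode < result.eigenvectors.shape[1]:
        raise IndexError(f"mode {mode} out of range")
    comp = result.eigenvectors[:, mode].reshape(-1, 3)
    return pd.DataFrame(
        {
            "resid": result.resids,
            "contribution": np.linalg.norm(comp, axis=1),
        }
    )


def fel(
    proj1: np.ndarray,
    proj2: np.ndarray,
    n_bins: int = 50,
    temperature: float | None = None,
) -> FELGrid:
    """Free-energy landscape over two projection coordinates.

    Delta G = -k_B T ln(P / P_max); empty bins are NaN (masked), the most
    populated bin is exactly 0.  With ``temperature`` given the surface is
    in kJ/mol, otherwise in k_BT units.
    """
    proj1 = np.asarray(proj1, dtype=float)
    proj2 = np.asarray(proj2, dtype=float)
    if proj1.size == 0:
        raise ValueError("empty projections")
    if np.ptp(proj1) == 0 and np.ptp(proj2) == 0:
        # degenerate: all frames in one bin at Delta G = 0
        grid = np.full((1, 1), 0.0)
        return FELGrid(
            grid,
            np.array([proj1[0] - 0.5, proj1[0] + 0.5]),
            np.array([proj2[0] - 0.5, proj2[0] + 0.5]),
        )
    counts, xe, ye = np.histogram2d(proj1, proj2, bins=n_bins)
    with np.errstate(divide="ignore"):
        dg = -np.log(counts / counts.max())
    dg[counts == 0] = np.nan
    scale, units = 1.0, "kT"
    if temperature is not None:
        scale, units = KB_KJ_PER_MOL_K * temperature, "kJ/mol"
    return FELGrid(dg * scale, xe, ye, units)
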