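import numpy as np
import pytest

from rinpipe.structure import Atom, Ensemble, Topology
from rinpipe.synthetic import (
    ChainSpec,
    CovarianceSpec,
    build_ideal_chain,
    sample_gaussian_ensemble,
)


def make_points_ensemble(coords, elements=None, resids=None, names=None):
    """Ensemble from bare point coordinates (frames, atoms, 3).

    Each atom defaults to a carbon named P<i> in its own residue, which is
    convenient for closed-form geometry fixtures.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None, :, :]
    n = coords.shape[1]
    elements = elements or ["C"] * n
    resids = resids or list(range(1, n + 1))
    names = names or [f"P{i}" for i in range(1, n + 1)]
    atoms = [
        Atom(i + 1, names[i], elements[i], "UNK", "A", resids[i])
        for i in range(n)
    ]
    return Ensemble(Topology(atoms), coords)


@pytest.fixture(scope="session")
def helix_chain():
    """12-residue ideal alpha helix, single frame."""
    return build_ideal_chain(ChainSpec(12))


@pytest.fixture(scope="session")
def noisy_helix():
    """Small jittered helix ensemble (20 frames) for oracle comparisons."""
    ref = build_ideal_chain(ChainSpec(8))
    return sample_gaussian_ensemble(
        ref, CovarianceSpec(base_sigma=0.4), 20, seed=42
    )
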